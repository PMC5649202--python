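"""Dose-time network identification: linear-ODE network inference.

Model
-----
Gene expression (as log2 ratio against time-matched controls) is modelled
as a linear time-invariant dynamical system driven by a constant external
perturbation encoding the applied dose::

    dx_i/dt = sum_j a_ij x_j + b_i u(dose)

``a_ij`` is the signed effect of gene j on the rate of change of gene i
(units 1/hour); ``b_i`` is the direct effect of the exposure on gene i; and
``u`` maps the dose to a dimensionless level in [0, 1], constant over time
(continuous exposure). Self-effects ``a_ii`` absorb first-order degradation
and are estimated but never reported as network edges.

Estimation proceeds gene by gene: derivatives dx_i/dt are approximated by
finite differences along each (compound, dose) trajectory, and the
coefficients of one row of (A, b) are fit by regression of the derivative
on the gene states and u. Three estimators are available:

``ols``
    Ordinary least squares with two-sided t-test p-values. Requires more
    observations than predictors.
``lasso_ols``
    L1-penalised support selection (cross-validated penalty, seeded) capped
    at rows - 2 predictors, followed by OLS on the selected support;
    unselected coefficients get weight 0 and p-value 1. The practical
    choice for pathway-sized gene sets, where designs are underdetermined.
``permutation``
    Lightly ridge-regularised fit with permutation p-values: the fraction
    of row-permutations of the response whose coefficient magnitude reaches
    the observed one, with add-one smoothing.

Edges are reported for off-diagonal coefficients with p below ``alpha``
(default 0.05, no multiple-testing correction), signed by the coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataValidationError, InferenceError
from .expression import DoseTimeExpressionSet, validate_design

_ESTIMATORS = ("ols", "lasso_ols", "permutation")
_SCHEMES = ("midpoint", "forward")
_ENCODINGS = ("max_scaled", "log_scaled", "rank_scaled")


@dataclass
class InferenceParams:
    """Tunable parameters of one inference run.

    alpha
        Per-coefficient significance threshold in (0, 1) for reporting an
        edge or a direct-perturbation call.
    derivative_scheme
        ``midpoint`` pairs each finite-difference derivative with the
        interval-midpoint state (trapezoidal collocation, default);
        ``forward`` pairs it with the left endpoint.
    estimator
        One of ``ols``, ``lasso_ols``, ``permutation`` (see module docs).
    dose_encoding
        How a dose maps to the perturbation input u in [0, 1].
    permutation_count
        Number of permutations for the ``permutation`` estimator (>= 100).
    seed
        Seed for every stochastic step (lasso CV folds, permutations).
    """

    alpha: float = 0.05
    derivative_scheme: str = "midpoint"
    estimator: str = "ols"
    dose_encoding: str = "max_scaled"
    permutation_count: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.derivative_scheme not in _SCHEMES:
            raise DataValidationError(f"unknown derivative scheme {self.derivative_scheme!r}")
        if self.estimator not in _ESTIMATORS:
            raise DataValidationError(f"unknown estimator {self.estimator!r}")
        if self.dose_encoding not in _ENCODINGS:
            raise DataValidationError(f"unknown dose encoding {self.dose_encoding!r}")
        if self.estimator == "permutation" and self.permutation_count < 100:
            raise DataValidationError("permutation_count must be >= 100")


def encode_perturbation(dose: float, doses: list[float], encoding: str = "max_scaled") -> float:
    """Map a dose to the perturbation input u in [0, 1].

    ``max_scaled``: dose / max dose; ``rank_scaled``: rank / number of
    levels; ``log_scaled``: log1p(dose) / log1p(max dose). Doses are the
    compound's full tested list, ascending or not.
    """
    doses = sorted(doses)
    if dose not in doses:
        raise DataValidationError(f"dose {dose} not among tested doses {doses}")
    top = doses[-1]
    if encoding == "max_scaled":
        return float(dose / top) if top > 0 else 0.0
    if encoding == "rank_scaled":
        return float((doses.index(dose) + 1) / len(doses))
    if encoding == "log_scaled":
        return float(np.log1p(dose) / np.log1p(top)) if top > 0 else 0.0
    raise DataValidationError(f"unknown dose encoding {encoding!r}")


@dataclass
class DerivativeSet:
    """Collocation observations for the regression stage.

    Each row pairs a per-gene derivative estimate (log2-ratio units/hour)
    with per-gene predictor states and a perturbation value u. Under finite
    differencing there is one row per consecutive time pair within each
    (compound, dose) trajectory; in oracle mode (exact derivatives from a
    simulated system) there is one row per sampled time.
    """

    genes: list[str]
    compound: list[str]
    dose_rank: list[int]
    time: np.ndarray          # interval midpoint (or exact sample time)
    derivatives: np.ndarray   # rows x genes
    predictors: np.ndarray    # rows x genes
    u: np.ndarray             # rows

    @property
    def n_observations(self) -> int:
        return self.derivatives.shape[0]


def estimate_derivatives(ds: DoseTimeExpressionSet, params: InferenceParams) -> DerivativeSet:
    """Finite-difference derivatives along each (compound, dose) trajectory.

    For consecutive time points t_k < t_{k+1}: derivative = (x(t_{k+1}) -
    x(t_k)) / (t_{k+1} - t_k); the paired predictor is the interval midpoint
    state (``midpoint`` scheme) or the left endpoint (``forward``). Unequal
    spacing is handled by construction. Expects replicates to be averaged
    already (one sample per design cell).
    """
    cells = {}
    for j, s in enumerate(ds.samples):
        key = (s.compound, s.dose_rank)
        cells.setdefault(key, []).append((s.time, j, s.dose))
    compound_doses = {c: ds.doses_of(c) for c in ds.compounds}

    comp, rank, mids, derivs, preds, us = [], [], [], [], [], []
    for (compound, dose_rank), entries in cells.items():
        entries.sort()
        if len(entries) < 2:
            raise DataValidationError(
                f"trajectory (compound={compound}, dose_rank={dose_rank}) has "
                f"fewer than 2 time points"
            )
        if len(entries) != len({t for t, _, _ in entries}):
            raise DataValidationError(
                f"trajectory (compound={compound}, dose_rank={dose_rank}) has "
                f"replicated samples; average replicates first"
            )
        dose = entries[0][2]
        u = encode_perturbation(dose, compound_doses[compound], params.dose_encoding)
        for (t0, j0, _), (t1, j1, _) in zip(entries[:-1], entries[1:]):
            x0, x1 = ds.values[:, j0], ds.values[:, j1]
            derivs.append((x1 - x0) / (t1 - t0))
            preds.append((x0 + x1) / 2.0 if params.derivative_scheme == "midpoint" else x0)
            mids.append((t0 + t1) / 2.0)
            comp.append(compound)
            rank.append(dose_rank)
            us.append(u)
    return DerivativeSet(
        genes=list(ds.genes), compound=comp, dose_rank=rank,
        time=np.asarray(mids), derivatives=np.asarray(derivs),
        predictors=np.asarray(preds), u=np.asarray(us),
    )


def assemble_regression(derivs: DerivativeSet, gene_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Response and design matrix for one gene's row of (A, b).

    y = derivative of the gene; X = [states of all n genes, u], no
    intercept (a zero log2 ratio means "at control level", which should
    imply zero drift absent perturbation).
    """
    if derivs.n_observations == 0:
        raise DataValidationError("empty derivative set")
    y = derivs.derivatives[:, gene_index].copy()
    X = np.column_stack([derivs.predictors, derivs.u])
    return y, X


@dataclass
class FitResult:
    coefficients: np.ndarray
    pvalues: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _ols_with_pvalues(y: np.ndarray, X: np.ndarray) -> FitResult:
    """Plain OLS with two-sided t-test p-values; aliased (rank-deficient or
    all-zero) columns are dropped, reported with coefficient 0 and p 1."""
    n, p = X.shape
    notes: list[str] = []
    norms = np.linalg.norm(X, axis=0)
    active = np.flatnonzero(norms > 1e-12)
    if active.size:
        # QR with pivoting exposes aliased columns among the active ones
        q, r, piv = _pivoted_qr(X[:, active])
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(n, active.size) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < active.size:
            notes.append(f"dropped {active.size - rank} aliased column(s)")
        active = active[np.sort(piv[:rank])]
    coef = np.zeros(p)
    pval = np.ones(p)
    k = active.size
    if k == 0:
        return FitResult(coef, pval, notes)
    if n <= k:
        raise InferenceError(
            f"OLS needs more observations than predictors ({n} rows vs {k} "
            f"effective columns); use the lasso_ols or permutation estimator"
        )
    Xa = X[:, active]
    beta, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
    resid = y - Xa @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(Xa.T @ Xa)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.where(np.abs(beta) > 0, np.inf, 0.0))
    pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pv = np.where(np.isnan(pv), 1.0, pv)
    # an exact fit has sigma2 == 0: nonzero coefficients are then certain
    if sigma2 <= np.finfo(float).tiny * max(1.0, float(y @ y)):
        pv = np.where(np.abs(beta) > 1e-12, 0.0, 1.0)
    coef[active] = beta
    pval[active] = pv
    return FitResult(coef, pval, notes)


def _pivoted_qr(M: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(M, mode="economic", pivoting=True)
    return q, r, piv


def _lasso_then_ols(y: np.ndarray, X: np.ndarray, seed: int) -> FitResult:
    """L1 support selection followed by OLS inference on the support.

    The lasso path is cross-validated over a small geometric penalty grid
    with seeded folds; the support is capped at rows - 2 columns (largest
    coefficient magnitudes win) so the post-selection OLS retains at least
    one residual degree of freedom.
    """
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import KFold

    n, p = X.shape
    if n < 4:
        raise InferenceError(f"lasso_ols needs at least 4 observations, got {n}")
    if np.linalg.norm(y) == 0 or np.all(np.linalg.norm(X, axis=0) < 1e-12):
        return FitResult(np.zeros(p), np.ones(p))
    cv = KFold(n_splits=min(5, n), shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(alphas=30, eps=1e-3, fit_intercept=False, cv=cv,
                        max_iter=50_000, tol=1e-6, random_state=seed)
        model.fit(X, y)
    support = np.flatnonzero(np.abs(model.coef_) > 1e-10)
    cap = max(1, n - 2)
    if support.size > cap:
        order = np.argsort(-np.abs(model.coef_[support]))
        support = np.sort(support[order[:cap]])
    coef = np.zeros(p)
    pval = np.ones(p)
    notes: list[str] = []
    if support.size:
        sub = _ols_with_pvalues(y, X[:, support])
        coef[support] = sub.coefficients
        pval[support] = sub.pvalues
        notes = sub.warnings
    return FitResult(coef, pval, notes)


def _ridge_coefficients(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    gram = X.T @ X
    lam = 1e-6 * (np.trace(gram) / p if p else 1.0)
    lam = max(lam, 1e-12)
    return np.linalg.solve(gram + lam * np.eye(p), X.T @ y)


def _permutation_fit(y: np.ndarray, X: np.ndarray, count: int, seed: int) -> FitResult:
    """Ridge point estimates with permutation p-values (add-one smoothed)."""
    rng = np.random.default_rng(seed)
    observed = _ridge_coefficients(y, X)
    exceed = np.zeros(X.shape[1])
    for _ in range(count):
        perm = rng.permutation(len(y))
        exceed += np.abs(_ridge_coefficients(y[perm], X)) >= np.abs(observed)
    pval = (exceed + 1.0) / (count + 1.0)
    return FitResult(observed, pval)


def fit_gene_model(y: np.ndarray, X: np.ndarray, params: InferenceParams) -> FitResult:
    """Fit one gene's coefficient row with the configured estimator."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise InferenceError(f"need at least 3 observations, got {X.shape[0]}")
    if params.estimator == "ols":
        return _ols_with_pvalues(y, X)
    if params.estimator == "lasso_ols":
        return _lasso_then_ols(y, X, seed=params.seed)
    return _permutation_fit(y, X, count=params.permutation_count, seed=params.seed)


@dataclass(frozen=True)
class Edge:
    """A directed signed interaction: source regulates target."""

    source: str
    target: str
    sign: int
    weight: float
    pvalue: float


@dataclass
class InferredNetwork:
    """Estimated interaction matrix, perturbation vector and edge list.

    ``A_hat[i, j]`` is the effect of gene j on the derivative of gene i;
    ``b_hat[i]`` the direct perturbation effect on gene i. The edge list
    keeps off-diagonal entries with p < alpha and nonzero weight.
    """

    genes: list[str]
    A_hat: np.ndarray
    A_pvalues: np.ndarray
    b_hat: np.ndarray
    b_pvalues: np.ndarray
    alpha: float
    warnings: list[str] = field(default_factory=list)

    @property
    def edges(self) -> list[Edge]:
        return self.edges_at(self.alpha)

    def edges_at(self, alpha: float) -> list[Edge]:
        out = []
        n = len(self.genes)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                w = self.A_hat[i, j]
                p = self.A_pvalues[i, j]
                if p < alpha and w != 0.0:
                    out.append(Edge(source=self.genes[j], target=self.genes[i],
                                    sign=1 if w > 0 else -1, weight=float(w),
                                    pvalue=float(p)))
        return out

    @property
    def perturbed_genes(self) -> list[tuple[str, float, float]]:
        """Genes with a significant direct perturbation effect: (gene, b, p)."""
        return [(g, float(self.b_hat[i]), float(self.b_pvalues[i]))
                for i, g in enumerate(self.genes) if self.b_pvalues[i] < self.alpha]

    def summary(self) -> dict:
        return {
            "n_genes": len(self.genes),
            "n_edges": len(self.edges),
            "n_perturbed_genes": len(self.perturbed_genes),
            "alpha": self.alpha,
        }


def fit_from_derivatives(derivs: DerivativeSet, params: InferenceParams) -> InferredNetwork:
    """Regression stage alone: fit every gene's row from prepared
    collocation observations (finite-difference or oracle)."""
    n = len(derivs.genes)
    A = np.zeros((n, n))
    Ap = np.ones((n, n))
    b = np.zeros(n)
    bp = np.ones(n)
    notes: list[str] = []
    for i in range(n):
        y, X = assemble_regression(derivs, i)
        fit = fit_gene_model(y, X, params)
        A[i, :] = fit.coefficients[:n]
        Ap[i, :] = fit.pvalues[:n]
        b[i] = fit.coefficients[n]
        bp[i] = fit.pvalues[n]
        notes.extend(f"gene {derivs.genes[i]}: {w}" for w in fit.warnings)
    return InferredNetwork(genes=list(derivs.genes), A_hat=A, A_pvalues=Ap,
                           b_hat=b, b_pvalues=bp, alpha=params.alpha, warnings=notes)


def infer_network(ds: DoseTimeExpressionSet, params: InferenceParams | None = None) -> InferredNetwork:
    """Full inference on one pooled expression set.

    Validates the design (>= 3 doses, >= 3 times per compound), estimates
    derivatives, and fits each gene's coefficient row. Deterministic given
    ``params.seed``. Gene sets beyond ~100 genes trigger a warning; beyond
    200 an error (identifiability degrades sharply with set size).
    """
    params = params or InferenceParams()
    if ds.n_genes > 200:
        raise DataValidationError(f"{ds.n_genes} genes exceed the hard guard of 200")
    report = validate_design(ds)
    if not report.passed:
        raise DataValidationError("design check failed: " + "; ".join(report.violations))
    if ds.n_genes > 100:
        warnings.warn(f"{ds.n_genes} genes: inference is preferable on sets below 100",
                      stacklevel=2)
    derivs = estimate_derivatives(ds, params)
    return fit_from_derivatives(derivs, params)
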