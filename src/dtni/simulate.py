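"""Ground-truth systems and simulated dose-time expression data.

The generator draws stable sparse linear systems (the ground truth an
inference run should recover), integrates them in closed form under a
constant dose perturbation, and emulates the layout of public dose-time
toxicogenomics repositories: per compound, 3+ doses x 3+ time points x
replicated observations of log2 ratios.

Trajectories start at x(0) = 0 — by definition the log2 ratio of an
untreated culture against its control — and evolve as

    x(t) = A^{-1} (e^{At} - I) b u,

the solution of dx/dt = A x + b u with constant u. Stability is enforced
constructively: the diagonal of A is set to -(off-diagonal row absolute sum
+ margin), making A strictly diagonally dominant with negative diagonal,
hence Hurwitz. Observation noise is additive Gaussian on the log2 scale,
independent per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.linalg import expm

from .consensus import GroupSpec
from .errors import DataValidationError
from .expression import DoseTimeExpressionSet, SampleDescriptor
from .inference import DerivativeSet, InferredNetwork, encode_perturbation


@dataclass
class TrueSystem:
    """A ground-truth interaction matrix A and perturbation vector b."""

    genes: list[str]
    A: np.ndarray
    b: np.ndarray
    margin: float = 0.1

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.genes)
        if self.A.shape != (n, n) or self.b.shape != (n,):
            raise DataValidationError("TrueSystem shapes inconsistent with gene count")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def spectral_abscissa(self) -> float:
        return float(np.max(np.real(np.linalg.eigvals(self.A))))

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        """True directed edges (source, target) from off-diagonal nonzeros."""
        out = set()
        n = self.n_genes
        for i in range(n):
            for j in range(n):
                if i != j and self.A[i, j] != 0.0:
                    out.add((self.genes[j], self.genes[i]))
        return out


@dataclass
class SimulationDesign:
    """Sampling layout for one simulated compound.

    Defaults mirror a typical in vitro dose-time repository design: three
    half-log-spaced doses, time points 2, 8 and 24 h, two replicates.
    ``noise_sd`` is the standard deviation of additive Gaussian observation
    noise on log2 ratios (0.05 is a mild microarray-like level).
    """

    doses: list[float] = field(default_factory=lambda: [10.0, 100.0, 1000.0])
    times: list[float] = field(default_factory=lambda: [2.0, 8.0, 24.0])
    replicates: int = 2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = [float(d) for d in self.doses]
        self.times = [float(t) for t in self.times]
        if len(self.doses) < 3 or any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise DataValidationError("doses must be >= 3 strictly increasing positive values")
        if len(self.times) < 3 or any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DataValidationError("times must be >= 3 strictly increasing positive hours")
        if min(self.doses) <= 0 or min(self.times) <= 0:
            raise DataValidationError("doses and times must be positive")
        if self.replicates < 1:
            raise DataValidationError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be non-negative")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{k:0{width}d}" for k in range(1, n + 1)]


def sample_true_system(n_genes: int, density: float = 0.2, k_perturbed: int = 2,
                       seed: int = 0, margin: float = 0.1) -> TrueSystem:
    """Draw a random stable sparse system.

    Exactly ``round(density * n * (n-1))`` off-diagonal entries are nonzero
    (positions chosen uniformly without replacement), magnitudes uniform in
    [0.2, 1.0] with random sign. The diagonal is set to -(row absolute sum
    + margin). ``k_perturbed`` entries of b are nonzero, magnitudes uniform
    in [0.5, 2.0] with random sign. Deterministic given ``seed``.
    """
    if n_genes < 2:
        raise DataValidationError("need at least 2 genes")
    if not 0.0 < density <= 1.0:
        raise DataValidationError("density must be in (0, 1]")
    if not 1 <= k_perturbed <= n_genes:
        raise DataValidationError("k_perturbed must be in [1, n_genes]")
    if margin <= 0:
        raise DataValidationError("stability margin must be positive")
    rng = np.random.default_rng(seed)
    n = n_genes
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    n_edges = max(1, round(density * len(off)))
    picked = rng.choice(len(off), size=n_edges, replace=False)
    A = np.zeros((n, n))
    for idx in picked:
        i, j = off[idx]
        A[i, j] = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
    _stabilize_diagonal(A, margin)
    b = np.zeros(n)
    hit = rng.choice(n, size=k_perturbed, replace=False)
    b[hit] = rng.uniform(0.5, 2.0, size=k_perturbed) * rng.choice([-1.0, 1.0], size=k_perturbed)
    return TrueSystem(genes=_gene_names(n), A=A, b=b, margin=margin)


def _stabilize_diagonal(A: np.ndarray, margin: float) -> None:
    """Set diag(A) = -(off-diagonal row absolute sum + margin), in place.

    Gershgorin's theorem then confines every eigenvalue to the left
    half-plane with real part <= -margin.
    """
    n = A.shape[0]
    for i in range(n):
        row = np.abs(A[i, :]).sum() - np.abs(A[i, i])
        A[i, i] = -(row + margin)


def trajectory(ts: TrueSystem, times: np.ndarray, u: float) -> np.ndarray:
    """Closed-form states x(t) = A^{-1}(e^{At} - I) b u, genes x times."""
    times = np.asarray(times, dtype=float)
    n = ts.n_genes
    out = np.empty((n, len(times)))
    bu = ts.b * u
    for k, t in enumerate(times):
        out[:, k] = np.linalg.solve(ts.A, (expm(ts.A * t) - np.eye(n)) @ bu)
    return out


def simulate_expression(
    ts: TrueSystem,
    design: SimulationDesign,
    u_encoding: str = "max_scaled",
    compound: str = "synthetic",
    return_derivatives: bool = False,
):
    """Simulate one compound's dose-time expression set.

    Returns a :class:`~dtni.expression.DoseTimeExpressionSet`; with
    ``return_derivatives=True`` additionally returns a noise-free
    :class:`~dtni.inference.DerivativeSet` carrying the exact states and
    analytic derivatives A x(t) + b u at every sampled time — the oracle
    side channel used to validate the regression stage in isolation from
    finite-difference error.
    """
    if ts.spectral_abscissa >= 0:
        raise DataValidationError("true system is not stable; cannot simulate")
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times)
    samples: list[SampleDescriptor] = []
    columns: list[np.ndarray] = []

    o_comp: list[str] = []
    o_rank: list[int] = []
    o_time: list[float] = []
    o_x: list[np.ndarray] = []
    o_dx: list[np.ndarray] = []
    o_u: list[float] = []

    for rank, dose in enumerate(design.doses, start=1):
        u = encode_perturbation(dose, design.doses, u_encoding)
        clean = trajectory(ts, times, u)
        for k, t in enumerate(times):
            for rep in range(1, design.replicates + 1):
                samples.append(SampleDescriptor(compound=compound, dose=dose,
                                                dose_rank=rank, time=float(t),
                                                replicate=rep))
                noise = rng.normal(0.0, design.noise_sd, size=ts.n_genes) \
                    if design.noise_sd > 0 else 0.0
                columns.append(clean[:, k] + noise)
            o_comp.append(compound)
            o_rank.append(rank)
            o_time.append(float(t))
            o_x.append(clean[:, k])
            o_dx.append(ts.A @ clean[:, k] + ts.b * u)
            o_u.append(u)

    ds = DoseTimeExpressionSet(genes=list(ts.genes), samples=samples,
                               values=np.column_stack(columns))
    if not return_derivatives:
        return ds
    oracle = DerivativeSet(
        genes=list(ts.genes), compound=o_comp, dose_rank=o_rank,
        time=np.asarray(o_time), derivatives=np.asarray(o_dx),
        predictors=np.asarray(o_x), u=np.asarray(o_u),
    )
    return ds, oracle


def make_group(
    core: TrueSystem,
    n_compounds: int = 3,
    extra_edges_per_compound: int = 3,
    perturbation_scale_range: tuple[float, float] = (0.8, 1.2),
    seed: int = 0,
    design: SimulationDesign | None = None,
    u_encoding: str = "max_scaled",
    name: str = "synthetic-group",
) -> GroupSpec:
    """Build a synthetic chemical group around a shared core mechanism.

    Every compound's system contains the core's edges plus
    ``extra_edges_per_compound`` additional random off-diagonal edges
    (diagonal re-stabilised afterwards), and a per-compound rescaling of b
    drawn from ``perturbation_scale_range``. Each compound is then
    simulated under the same design, with compound-specific noise draws.
    """
    if n_compounds < 2:
        raise DataValidationError("a group needs >= 2 compounds")
    if extra_edges_per_compound < 0:
        raise DataValidationError("extra_edges_per_compound must be >= 0")
    lo, hi = perturbation_scale_range
    if lo <= 0 or hi < lo:
        raise DataValidationError("perturbation_scale_range must be 0 < lo <= hi")
    design = design or SimulationDesign()
    rng = np.random.default_rng(seed)
    n = core.n_genes
    zero_positions = [(i, j) for i in range(n) for j in range(n)
                      if i != j and core.A[i, j] == 0.0]
    compounds = [f"{name}-C{k}" for k in range(1, n_compounds + 1)]
    data: dict[str, DoseTimeExpressionSet] = {}
    systems: dict[str, TrueSystem] = {}
    for k, compound in enumerate(compounds):
        A = core.A.copy()
        n_extra = min(extra_edges_per_compound, len(zero_positions))
        if n_extra:
            picked = rng.choice(len(zero_positions), size=n_extra, replace=False)
            for idx in picked:
                i, j = zero_positions[idx]
                A[i, j] = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
        _stabilize_diagonal(A, core.margin)
        scale = rng.uniform(lo, hi)
        ts = TrueSystem(genes=list(core.genes), A=A, b=core.b * scale, margin=core.margin)
        sub_design = _dc_replace(design, seed=int(rng.integers(0, 2**31 - 1)))
        data[compound] = simulate_expression(ts, sub_design, u_encoding, compound=compound)
        systems[compound] = ts
    return GroupSpec(name=name, compounds=compounds, data=data, systems=systems)


@dataclass
class RecoveryMetrics:
    """Edge-recovery quality of an inferred network against the truth."""

    auroc: float
    precision: float
    recall: float
    sign_accuracy: float
    n_true_edges: int
    n_called_edges: int
    precision_defined: bool = True
    sign_accuracy_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc, "precision": self.precision, "recall": self.recall,
            "sign_accuracy": self.sign_accuracy, "n_true_edges": self.n_true_edges,
            "n_called_edges": self.n_called_edges,
        }


def recovery_metrics(truth: TrueSystem, inferred: InferredNetwork,
                     score: str = "weight") -> RecoveryMetrics:
    """Score an inferred network against the ground truth.

    Off-diagonal true nonzeros are the positives. AUROC ranks all
    off-diagonal entries by |a_hat| (``score="weight"``) or 1 - p
    (``score="pvalue"``); precision/recall use the significant edge list at
    the network's alpha; sign accuracy is measured among detected true
    edges. Undefined ratios (no calls, no detected true edges) are reported
    as NaN with the matching ``*_defined`` flag cleared.
    """
    if truth.genes != inferred.genes:
        raise DataValidationError("truth and inferred networks have different gene universes")
    from sklearn.metrics import roc_auc_score

    n = truth.n_genes
    mask = ~np.eye(n, dtype=bool)
    labels = (truth.A != 0.0)[mask].astype(int)
    if score == "weight":
        scores = np.abs(inferred.A_hat)[mask]
    elif score == "pvalue":
        scores = (1.0 - inferred.A_pvalues)[mask]
    else:
        raise DataValidationError(f"unknown score {score!r}")
    if labels.min() == labels.max():
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(labels, scores))

    true_edges = truth.edge_set
    called = {(e.source, e.target): e for e in inferred.edges}
    tp = set(called) & true_edges
    precision_defined = len(called) > 0
    precision = len(tp) / len(called) if precision_defined else float("nan")
    recall = len(tp) / len(true_edges) if true_edges else float("nan")
    idx = {g: i for i, g in enumerate(truth.genes)}
    good = sum(
        1 for (s, t) in tp
        if np.sign(truth.A[idx[t], idx[s]]) == np.sign(inferred.A_hat[idx[t], idx[s]])
    )
    sign_defined = len(tp) > 0
    sign_acc = good / len(tp) if sign_defined else float("nan")
    return RecoveryMetrics(auroc=auroc, precision=precision, recall=recall,
                           sign_accuracy=sign_acc, n_true_edges=len(true_edges),
                           n_called_edges=len(called), precision_defined=precision_defined,
                           sign_accuracy_defined=sign_defined)


def write_fixture_bundle(outdir, ts: TrueSystem, group: GroupSpec) -> dict[str, str]:
    """Write a text fixture bundle: per-compound expression TSVs, a GMT with
    the simulated gene set, a truth edge-list TSV, and a truth-derived SIF
    usable as a mock reference network. Returns a name -> path map."""
    import os

    from .expression import write_expression_long
    from .genesets import GeneSet, write_gmt

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for compound in group.compounds:
        p = os.path.join(outdir, f"expression_{compound}.tsv")
        write_expression_long(group.data[compound], p)
        paths[f"expression:{compound}"] = p
    gmt = os.path.join(outdir, "genes.gmt")
    write_gmt([GeneSet(name="simulated", genes=set(ts.genes), source="synthetic truth",
                       order=list(ts.genes))], gmt)
    paths["gmt"] = gmt
    edges = os.path.join(outdir, "truth_edges.tsv")
    idx = {g: i for i, g in enumerate(ts.genes)}
    with open(edges, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for s, t in sorted(ts.edge_set):
            fh.write(f"{s}\t{t}\t{ts.A[idx[t], idx[s]]:.17g}\n")
    paths["truth_edges"] = edges
    sif = os.path.join(outdir, "truth_reference.sif")
    with open(sif, "w", encoding="utf-8") as fh:
        for s, t in sorted(ts.edge_set):
            fh.write(f"{s}\tgene-regulatory\t{t}\n")
    paths["truth_sif"] = sif
    return paths
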