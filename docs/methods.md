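# Methods

## Model and assumptions

Expression is represented as log2 ratios `x(t)` of exposed samples against
time-matched controls, so `x = 0` means "at control level" and, by
definition, `x(0) = 0` at the start of exposure. The package models a gene
set of size *n* as a linear time-invariant dynamical system with a constant
exogenous input:

    dx/dt = A x + b u,        x(0) = 0,

where `A` (n × n, units 1/h) collects signed gene–gene effects, `b` (units
log2-ratio · h⁻¹ per unit input) the direct effects of the exposure, and
`u ∈ [0, 1]` encodes the applied dose, constant over time (continuous
exposure in the medium). The solution is `x(t) = A⁻¹(e^{At} − I) b u`.

Assumptions worth keeping in mind:

- **Linearity** around the control state. Adequate for moderate
  perturbations; saturating or switch-like responses violate it.
- **Time-invariance**: coefficients do not change over the sampled window.
- **Constant input**: `u` depends on dose only, not on time; compound
  uptake/degradation kinetics are not modelled.
- **Determinism**: no intrinsic stochasticity; all randomness is
  observation noise.
- Self-effects `a_ii` absorb first-order mRNA degradation; they are
  estimated but never reported as edges, since reported networks describe
  gene–gene regulation.

## From samples to regressions

Replicates are averaged per (compound, dose, time) cell before inference;
derivative estimation on mean trajectories is less noisy than on
individual replicates. Within each (compound, dose) trajectory, each pair
of consecutive time points `t_k < t_{k+1}` yields one collocation
observation

    (x(t_{k+1}) − x(t_k)) / (t_{k+1} − t_k)  ≈  A x̄ + b u,

with `x̄` the interval-midpoint average (default; implicit-midpoint /
trapezoidal collocation, second-order accurate) or the left endpoint
(`forward` scheme, first-order, available for comparison). Unequal
sampling intervals are handled by construction. Each gene's coefficient
row `(a_i·, b_i)` is then fit independently by regression of its
derivative on all gene states plus `u`, with **no intercept**: a system at
control level with no input should not drift.

### Estimators

- `ols` (default): ordinary least squares, two-sided t-test p-values.
  Columns that are numerically zero or aliased (detected by pivoted QR)
  are dropped and reported with coefficient 0, p = 1. Requires more
  observations than effective predictors. When the residual is exactly
  zero (noise-free data), t-statistics degenerate; nonzero coefficients
  then get p = 0 and zero coefficients p = 1.
- `lasso_ols`: cross-validated lasso (30-point geometric penalty grid,
  seeded 5-fold CV, no intercept) selects a support, capped at
  rows − 2 predictors (largest coefficients kept) so the post-selection
  OLS retains a residual degree of freedom; OLS on the support supplies
  coefficients and p-values, unselected predictors get 0 / 1. This is the
  practical choice for pathway-sized gene sets (tens to ~160 genes) under
  repository-sized designs, where the per-gene regression is strongly
  underdetermined. Post-selection p-values are optimistic (selection and
  inference use the same data) — they are screening scores, not calibrated
  error rates; the leave-one-out intersection downstream is the package's
  actual false-positive control.
- `permutation`: ridge point estimates (penalty 1e−6 × trace-scaled, a
  numerical floor rather than real shrinkage) with p-values from row
  permutations of the response (default 1000, add-one smoothed, so the
  smallest attainable p is 1/(B+1)). Assumption-free and usable at any
  aspect ratio, at ~B× the cost.

Edges are reported for off-diagonal coefficients with p < α; α defaults to
0.05, per-coefficient, **without** multiple-testing correction — the
consensus intersection, not the per-run threshold, is the specificity
mechanism.

### Dose encoding

`max_scaled` (default): `u = dose / max dose`, per compound, keeping `u`
comparable across compounds pooled into one run. `rank_scaled`
(`rank / #levels`) and `log_scaled` (`log1p(dose)/log1p(max)`) are
available; half-log dose series with max_scaled make the lowest dose
nearly inactive (`u = 0.01`), which log or rank scaling avoids when the
biology is closer to log-linear in dose.

## Consensus across a chemical group

For n compounds: one pooled run plus n leave-one-out runs. An edge enters
the consensus iff it is significant in **every** run and (by default)
carries the same sign in every run; sign-conflicting intersections are
biologically contradictory and are excluded unless the flag is lowered.
The same rule applies to direct-perturbation calls on `b`. Per-run weights
and p-values are carried as provenance; no averaged weight is reported,
because averaging across runs that share most of their data would suggest
a precision the design cannot support. Consensus is invariant to run order,
is idempotent on identical runs, and any empty run empties it.

## Network characterisation

- **Starting nodes** (out-degree > 0, in-degree = 0): candidate molecular
  initiating events. **Target genes** (in-degree > 0, out-degree = 0):
  candidate downstream markers. Intermediate and isolated genes complete
  the partition. A looser "any incoming edge" target definition is
  available behind a flag.
- A pathway is **directly perturbed** iff at least one gene keeps a
  significant, sign-consistent `b` across all runs.
- **Cross-group comparison** labels every node and edge with the exact set
  of groups containing it and clusters target genes by group combination.
- Node annotation uses the **maximum response**: the mean log2 ratio at
  the highest dose rank and latest time point over all pooled samples.
  Dose *rank* (not native dose) is used so compounds on different dose
  scales pool coherently.
- The merged multigraph export (GraphML + TSV) keeps one parallel edge per
  group and per-group node attributes; attributes for groups in which a
  node does not appear are absent, not zero-filled.

## Edge validation against prior knowledge

The reference is a SIF edge list; links are undirected by default
(protein-interaction exports carry no direction), with an optional
directed policy per interaction type. Self-links are dropped with a
warning. An inferred edge is `direct` if the reference joins its
endpoints, `indirect` if exactly one intermediary node links them (path
length 2 — a plausible signature of reactions faster than the sampled
timescale collapsing onto one inferred edge), else `potentially_novel`.
Longer paths deliberately count as novel. Labels are mutually exclusive
and exhaustive, and growing the reference can only promote a label
(novel → indirect → direct), never demote it.

## Synthetic data generator

`sample_true_system` draws exactly `round(density · n(n−1))` off-diagonal
entries, magnitudes uniform in [0.2, 1.0] /h with random sign, and sets
the diagonal to −(off-diagonal row absolute sum + margin) — strict
diagonal dominance, so by Gershgorin every eigenvalue has real part
≤ −margin (default 0.1/h) and the system is stable by construction (a
constructive, seed-stable alternative to eigenvalue shifting). `b` has
`k_perturbed` entries uniform in [0.5, 2.0] with random sign. Designs
default to 3 half-log doses × times {2, 8, 24} h × 2 replicates, the
layout of public dose–time hepatocyte repositories, with additive
Gaussian observation noise on log2 ratios (default sd 0.05, a mild
microarray-like level); a 6-point refinement {2, 4, 8, 12, 18, 24} h is
first-class because identifiability with 3 time points is marginal.
`make_group` builds compound families around a shared core: per compound,
extra random edges (diagonal re-stabilised) and a rescaled `b`.

What the generator does **not** emulate: probe-level artefacts,
normalisation residue, biological replicate hierarchies, nonlinear or
saturating dynamics, compound pharmacokinetics. Passing recovery tests on
these fixtures therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not performance on real
microarray data.

In oracle mode the simulator also emits exact states and analytic
derivatives `Ax + bu` at the sampled times, so the regression stage can be
validated in isolation from finite-difference error: with these inputs and
zero noise, OLS reproduces a direct least-squares solve — and the
generating system — to numerical precision.

## Identifiability: what these designs can and cannot support

Two structural facts shape every result on dose–time designs and are easy
to miss:

1. **Doses add signal, not rank.** With `x(0) = 0` and a linear model,
   `x(t, dose) = u(dose) · M(t) b` exactly: trajectories at different
   doses of the same compound are scalar multiples of one another. Every
   regression column has the form `u ⊗ f(interval)`, so the deterministic
   design matrix has rank at most the number of time intervals —
   regardless of how many doses are tested. Six time points give five
   intervals against n + 1 unknowns per gene row; for n = 10 the
   regression is structurally underdetermined, and the surplus columns
   are near-collinear (the `f_j` form a Krylov-type family,
   `x(t) = Σ_k A^k b t^{k+1}/(k+1)!`), which also defeats sparse
   recovery. Full identifiability needs at least n + 1 distinct time
   points — or, in group settings, compounds whose *direct-target
   profiles differ in direction*, since each distinct `b` direction
   contributes its own rank. This is the quantitative argument for
   pooling mechanistically diverse compounds, and the reason per-run edge
   lists must be read as screens rather than reconstructions.
2. **Unexcited genes are invisible.** An edge out of a gene the input
   never reaches (directly or transitively) leaves no trace in any
   trajectory; no estimator can recover it. Complete recovery is only
   meaningful when the perturbation excites every source gene.

Observation noise compounds this: the same noisy values appear in the
response (differenced) and in the predictors (averaged), an
errors-in-variables structure that attenuates estimates, and the
informative singular directions of the design are orders of magnitude
smaller than its leading direction, so even small noise overwhelms them.
Direct-perturbation calls on `b` are far better powered than edge
recovery — the `u` column is exact and uncorrupted — which matches how the
package behaves on its own benchmarks.

Consequently the test suite validates the estimation machinery where it is
identifiable (analytic-derivative oracle; noise-free half-hourly sampling
with all genes perturbed, where edge ranking is perfect) and validates the
*mechanisms* — threshold monotonicity, intersection algebra, consensus
precision gain over the pooled run — at small problem sizes (4–10 genes,
3 compounds, seconds per case). The fixed-seed noisy benchmark at the
6-point design is reported by `scripts/acceptance.py` as measured.

## Numerical choices and degenerate inputs

- Trajectories use `expm` with a linear solve rather than matrix
  inversion; stability of sampled systems guarantees nonsingular `A`.
- Aliased/zero regression columns: dropped via pivoted QR with a
  max(n, p)·eps·|R₁₁| tolerance; dropped columns report coefficient 0,
  p = 1, and a warning is recorded on the network object.
- Constant (all-zero) genes stay in the design but can never source a
  significant edge: their column is dropped as zero.
- Exact-fit p-values (zero residual) are 0 for nonzero coefficients —
  meaningful only for noise-free synthetic data.
- Long-format TSV values are written with 17 significant digits and parsed
  with Python's correctly rounded `float()`, so write → read round-trips
  are bit-exact.
- Gene sets above 100 genes trigger a warning (identifiability), above
  200 a hard error.
- Recovery metrics report NaN with an explicit flag when undefined (no
  called edges, no detected true edges) rather than coercing to 0.

## Configuration

The pipeline runs from a single YAML/TOML file:

```yaml
outdir: results
genesets: {gmt: pathways.gmt, names: [NRF2, NFKB]}
reference: interactions.sif          # optional
params: {alpha: 0.05, estimator: lasso_ols, seed: 42}
groups:
  - name: DILI
    compounds:
      - {compound: diclofenac, path: expr_diclofenac.tsv}
      - {compound: nitrofurantoin, path: expr_nitrofurantoin.tsv}
```

Every artifact is listed in `manifest.json` with a SHA-256 content hash;
identical inputs and seed reproduce identical hashes. Exit codes: 0
success, 2 configuration error, 3 data/format error, 4 inference error.

## Known limitations

- Linear, time-invariant, deterministic dynamics; no spline smoothing of
  trajectories, no stochastic or time-varying models.
- Post-selection p-values are not calibrated (see above).
- The indirect/direct edge labels depend entirely on the coverage of the
  supplied reference network; sparsely annotated pathways will show
  inflated "potentially novel" fractions.
- Identifier mapping is out of scope: gene identifiers are opaque strings
  and must already agree between expression, gene sets and reference.
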