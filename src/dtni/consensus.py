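"""Group-wise inference with leave-one-out cross validation and consensus.

A chemical group (e.g. a set of hepatotoxicants sharing an adverse-outcome
class) is analysed by pooling the log2 ratios of all its compounds into one
inference run, then repeating the run with each compound left out in turn.
A group of n compounds therefore yields n + 1 runs. The consensus network
is the *intersection* of the runs: an edge (or a direct-perturbation call)
survives only if it is significant in every run — and, by default, carries
the same sign in every run. Per-run weights and p-values are retained as
provenance rather than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, InferenceError
from .expression import (DoseTimeExpressionSet, average_replicates, subset_genes,
                         validate_design)
from .genesets import GeneSet
from .inference import InferenceParams, InferredNetwork, infer_network


@dataclass
class GroupSpec:
    """A chemical group: >= 2 compounds sharing one gene universe, each with
    its own expression set. Synthetic groups additionally carry the
    per-compound ground-truth systems."""

    name: str
    compounds: list[str]
    data: dict[str, DoseTimeExpressionSet]
    systems: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.compounds) < 2:
            raise DataValidationError(f"group {self.name!r} needs >= 2 compounds")
        if len(set(self.compounds)) != len(self.compounds):
            raise DataValidationError(f"group {self.name!r} has duplicate compounds")
        missing = [c for c in self.compounds if c not in self.data]
        if missing:
            raise DataValidationError(f"group {self.name!r} lacks data for {missing}")


def enumerate_runs(compounds: list[str]) -> list[tuple[str, ...]]:
    """The pooled run followed by one leave-one-out run per compound.

    For compounds [A, B, C]: (A,B,C), (B,C), (A,C), (A,B) — n + 1 subsets.
    """
    compounds = list(compounds)
    if len(compounds) < 2:
        raise DataValidationError("leave-one-out needs >= 2 compounds")
    if len(set(compounds)) != len(compounds):
        raise DataValidationError("duplicate compound identifiers")
    runs = [tuple(compounds)]
    for c in compounds:
        runs.append(tuple(x for x in compounds if x != c))
    return runs


def pool_group(data: dict[str, DoseTimeExpressionSet],
               subset: tuple[str, ...] | list[str]) -> DoseTimeExpressionSet:
    """Concatenate the samples of the subset's compounds into one set.

    All compounds must share the same gene universe; gene order follows the
    first compound in the subset, others are re-indexed to match.
    """
    subset = list(subset)
    if not subset:
        raise DataValidationError("empty compound subset")
    missing = [c for c in subset if c not in data]
    if missing:
        raise DataValidationError(f"no data for compound(s) {missing}")
    first = data[subset[0]]
    ref_genes = list(first.genes)
    ref_set = set(ref_genes)
    blocks = []
    samples = []
    for c in subset:
        ds = data[c]
        if set(ds.genes) != ref_set:
            disjoint = sorted(set(ds.genes) ^ ref_set)
            raise DataValidationError(
                f"gene lists of {subset[0]} and {c} are not reconcilable; "
                f"non-shared genes: {disjoint}"
            )
        order = [ds.genes.index(g) for g in ref_genes]
        blocks.append(ds.values[order, :])
        samples.extend(ds.samples)
    return DoseTimeExpressionSet(genes=ref_genes, samples=samples,
                                 values=np.hstack(blocks))


@dataclass
class Run:
    included: tuple[str, ...]
    network: InferredNetwork

    @property
    def label(self) -> str:
        return "+".join(self.included)


@dataclass
class RunSet:
    """All inference runs of one group: the pooled run first, then the
    leave-one-out runs in compound order."""

    group: str
    compounds: list[str]
    runs: list[Run]

    def __post_init__(self) -> None:
        if len(self.runs) != len(self.compounds) + 1:
            raise DataValidationError(
                f"run count {len(self.runs)} != compounds + 1 ({len(self.compounds) + 1})"
            )

    def __len__(self) -> int:
        return len(self.runs)


def run_group_dtni(group, geneset: GeneSet | None,
                   params: InferenceParams | None = None) -> RunSet:
    """Pooled + leave-one-out inference for a whole group.

    For each enumerated compound subset: pool the expression sets, restrict
    to the gene set (when given), average replicates, infer. Any failing
    run aborts with the run identified.
    """
    params = params or InferenceParams()
    for c in group.compounds:
        report = validate_design(group.data[c])
        if not report.passed:
            raise DataValidationError(
                f"group {group.name!r}, compound {c}: " + "; ".join(report.violations)
            )
    runs = []
    for included in enumerate_runs(group.compounds):
        try:
            pooled = pool_group(group.data, included)
            if geneset is not None:
                pooled, _ = subset_genes(pooled, geneset)
            pooled = average_replicates(pooled)
            net = infer_network(pooled, params)
        except (DataValidationError, InferenceError) as exc:
            raise type(exc)(
                f"group {group.name!r}, run {'+'.join(included)}: {exc}"
            ) from exc
        runs.append(Run(included=included, network=net))
    return RunSet(group=group.name, compounds=list(group.compounds), runs=runs)


@dataclass(frozen=True)
class ConsensusEdge:
    """An edge present (p < alpha) in every run of the group."""

    source: str
    target: str
    sign: int                    # sign in the pooled run
    weights: tuple[float, ...]   # one per run, pooled first
    pvalues: tuple[float, ...]


@dataclass
class ConsensusNetwork:
    group: str
    genes: list[str]
    edges: list[ConsensusEdge]
    perturbation_calls: dict[str, dict] = field(default_factory=dict)
    run_labels: list[str] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def edge_keys(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def summary(self) -> dict:
        return {
            "group": self.group,
            "n_genes": len(self.genes),
            "n_edges": len(self.edges),
            "n_perturbed_genes": len(self.perturbation_calls),
            "runs": list(self.run_labels),
            "alpha": self.alpha,
        }


def intersect_networks(runs: RunSet, require_sign_consistency: bool = True) -> ConsensusNetwork:
    """Intersect the edge sets (and perturbation calls) of all runs.

    A consensus edge must be significant in every run; with
    ``require_sign_consistency`` (default) its sign must also agree across
    runs. Same rule for direct-perturbation calls on b. The result is
    invariant to run order up to edge bookkeeping (pooled-run values are
    reported first as stored).
    """
    if len(runs.runs) == 0:
        raise DataValidationError("empty run set")
    nets = [r.network for r in runs.runs]
    genes = nets[0].genes
    for net in nets[1:]:
        if set(net.genes) != set(genes):
            raise DataValidationError("runs do not share a gene universe")
    per_run_edges = [{(e.source, e.target): e for e in net.edges} for net in nets]
    common = set(per_run_edges[0])
    for d in per_run_edges[1:]:
        common &= set(d)
    edges = []
    for key in sorted(common):
        signs = {d[key].sign for d in per_run_edges}
        if require_sign_consistency and len(signs) > 1:
            continue
        edges.append(ConsensusEdge(
            source=key[0], target=key[1], sign=per_run_edges[0][key].sign,
            weights=tuple(d[key].weight for d in per_run_edges),
            pvalues=tuple(d[key].pvalue for d in per_run_edges),
        ))

    calls: dict[str, dict] = {}
    for gene in genes:
        entries = []
        ok = True
        for net in nets:
            i = net.genes.index(gene)
            if net.b_pvalues[i] >= net.alpha:
                ok = False
                break
            entries.append((float(net.b_hat[i]), float(net.b_pvalues[i])))
        if ok and entries:
            if require_sign_consistency and len({np.sign(b) for b, _ in entries}) > 1:
                continue
            calls[gene] = {"b": [b for b, _ in entries], "p": [p for _, p in entries]}

    return ConsensusNetwork(group=runs.group, genes=list(genes), edges=edges,
                            perturbation_calls=calls,
                            run_labels=[r.label for r in runs.runs],
                            alpha=nets[0].alpha)
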