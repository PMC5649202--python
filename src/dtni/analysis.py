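"""Characterisation and cross-group comparison of consensus networks.

Node roles follow the degree-based reading used throughout network
toxicology: *starting nodes* (outgoing edges only) are candidate molecular
initiating events, *target genes* (incoming edges only) candidate
downstream effect markers, *intermediate* nodes carry both, and *isolated*
genes belong to the analysed gene set but to no inferred edge. Networks
from several chemical groups are compared by labelling every node and edge
with the exact set of groups containing it, and nodes are annotated with a
maximum-response expression value: the mean log2 ratio at the highest dose
and latest time point across the group's pooled samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

import pandas as pd

from .consensus import ConsensusNetwork
from .errors import DataValidationError
from .expression import DoseTimeExpressionSet
from .genesets import GeneSet


@dataclass
class NodeRoleReport:
    """Partition of the gene universe by connectivity role."""

    starting: set[str]
    targets: set[str]
    intermediate: set[str]
    isolated: set[str]

    @property
    def universe(self) -> set[str]:
        return self.starting | self.targets | self.intermediate | self.isolated


def node_roles(net: ConsensusNetwork, geneset: GeneSet | None = None,
               loose_targets: bool = False) -> NodeRoleReport:
    """Classify every gene by in/out degree in the consensus network.

    starting: out > 0, in = 0; target: in > 0, out = 0 (or simply in > 0
    when ``loose_targets``); intermediate: both; isolated: no edges. Genes
    of ``geneset`` absent from the network count as isolated.
    """
    universe = set(net.genes)
    if geneset is not None:
        universe |= set(geneset.genes)
    indeg: dict[str, int] = {g: 0 for g in universe}
    outdeg: dict[str, int] = {g: 0 for g in universe}
    for e in net.edges:
        if e.source not in universe or e.target not in universe:
            raise DataValidationError(
                f"edge {e.source}->{e.target} references a gene outside the gene set"
            )
        outdeg[e.source] += 1
        indeg[e.target] += 1
    starting, targets, intermediate, isolated = set(), set(), set(), set()
    for g in universe:
        i, o = indeg[g], outdeg[g]
        if i == 0 and o == 0:
            isolated.add(g)
        elif i == 0:
            starting.add(g)
        elif o == 0:
            targets.add(g)
        else:
            intermediate.add(g)
    if loose_targets:
        targets = targets | intermediate
    return NodeRoleReport(starting=starting, targets=targets,
                          intermediate=intermediate if not loose_targets else set(),
                          isolated=isolated)


def is_directly_perturbed(net: ConsensusNetwork) -> tuple[bool, dict[str, dict]]:
    """Whether the exposure directly affects the pathway: at least one gene
    with a consensus direct-perturbation call. Returns the called genes
    with their per-run b values and p-values."""
    return bool(net.perturbation_calls), dict(net.perturbation_calls)


@dataclass
class GroupOverlapPartition:
    """Exact-group-combination labels for nodes and edges across networks."""

    node_groups: dict[str, frozenset[str]]
    edge_groups: dict[tuple[str, str], frozenset[str]]
    target_clusters: dict[frozenset[str], set[str]] = field(default_factory=dict)

    def nodes_in(self, combination: frozenset[str] | set[str]) -> set[str]:
        combination = frozenset(combination)
        return {n for n, g in self.node_groups.items() if g == combination}

    def edges_in(self, combination: frozenset[str] | set[str]) -> set[tuple[str, str]]:
        combination = frozenset(combination)
        return {e for e, g in self.edge_groups.items() if g == combination}


def cross_group_partition(nets: dict[str, ConsensusNetwork]) -> GroupOverlapPartition:
    """Label each node and edge with the exact set of groups containing it.

    Nodes are counted as present in a group when they touch at least one
    consensus edge there. ``target_clusters`` additionally groups target
    genes (sink nodes) by their exact group combination — the layout used
    to compare downstream effects across adverse-outcome classes.
    """
    if len(nets) < 2:
        raise DataValidationError("cross-group comparison needs >= 2 groups")
    node_groups: dict[str, set[str]] = {}
    edge_groups: dict[tuple[str, str], set[str]] = {}
    target_membership: dict[str, set[str]] = {}
    for group, net in nets.items():
        connected: set[str] = set()
        for e in net.edges:
            edge_groups.setdefault((e.source, e.target), set()).add(group)
            connected |= {e.source, e.target}
        for n in connected:
            node_groups.setdefault(n, set()).add(group)
        roles = node_roles(net)
        for t in roles.targets:
            target_membership.setdefault(t, set()).add(group)
    clusters: dict[frozenset[str], set[str]] = {}
    for gene, groups in target_membership.items():
        clusters.setdefault(frozenset(groups), set()).add(gene)
    return GroupOverlapPartition(
        node_groups={n: frozenset(g) for n, g in node_groups.items()},
        edge_groups={e: frozenset(g) for e, g in edge_groups.items()},
        target_clusters=clusters,
    )


def max_response(ds: DoseTimeExpressionSet, gene: str) -> float:
    """Mean log2 ratio of a gene at the highest dose rank and latest time
    point, over all replicates and pooled compounds — the maximum-response
    summary used to colour network nodes."""
    i = ds.gene_index(gene)
    top_rank = max(s.dose_rank for s in ds.samples)
    top_time = max(s.time for s in ds.samples)
    cols = [j for j, s in enumerate(ds.samples)
            if s.dose_rank == top_rank and s.time == top_time]
    if not cols:
        raise DataValidationError("no sample at the top (dose_rank, time) cell")
    return float(ds.values[i, cols].mean())


def max_response_table(ds: DoseTimeExpressionSet) -> dict[str, float]:
    return {g: max_response(ds, g) for g in ds.genes}


def annotate_and_export(
    nets: dict[str, ConsensusNetwork],
    expression_summaries: dict[str, dict[str, float]],
    graphml_path=None,
    node_table_path=None,
    edge_table_path=None,
) -> nx.MultiDiGraph:
    """Merge group networks into one annotated multigraph.

    Each consensus edge becomes a parallel edge keyed and attributed by its
    group; nodes carry per-group ``max_response.<group>`` attributes (only
    for groups in which the node appears) and a per-group role string.
    Optionally writes GraphML plus node/edge TSV attribute tables.
    """
    graph = nx.MultiDiGraph()
    roles_by_group = {g: node_roles(net) for g, net in nets.items()}
    for group, net in nets.items():
        summary = expression_summaries.get(group, {})
        present: set[str] = set()
        for e in net.edges:
            present |= {e.source, e.target}
        for n in sorted(present):
            if n not in summary:
                raise DataValidationError(
                    f"gene {n} of group {group!r} has no expression summary"
                )
            graph.add_node(n)
            graph.nodes[n][f"max_response.{group}"] = float(summary[n])
            roles = roles_by_group[group]
            role = ("starting" if n in roles.starting else
                    "target" if n in roles.targets else
                    "intermediate" if n in roles.intermediate else "isolated")
            graph.nodes[n][f"role.{group}"] = role
        for e in net.edges:
            graph.add_edge(e.source, e.target, key=group, group=group,
                           sign=e.sign, weight=float(e.weights[0]),
                           p_value=float(e.pvalues[0]))
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if node_table_path is not None:
        rows = [{"gene": n, **attrs} for n, attrs in graph.nodes(data=True)]
        pd.DataFrame(rows).to_csv(node_table_path, sep="\t", index=False)
    if edge_table_path is not None:
        rows = [{"source": u, "target": v, **attrs}
                for u, v, attrs in graph.edges(data=True)]
        pd.DataFrame(rows).to_csv(edge_table_path, sep="\t", index=False)
    return graph
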