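"""Classification of inferred edges against a prior-knowledge network.

The reference is a SIF edge list (as exported from interaction
meta-databases such as ConsensusPathDB): ``nodeA <tab> interaction-type
<tab> nodeB``. An inferred edge is *direct* when the reference contains
the same pair, *indirect* when exactly one intermediary node links the two
endpoints (a path of length 2), and *potentially novel* otherwise.
Indirect hits typically reflect reactions faster than the sampled
timescale collapsing onto a single inferred edge.

Reference links are treated as undirected by default — protein
interactions carry no direction — but a per-interaction-type directed
policy can be supplied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .consensus import ConsensusNetwork
from .errors import FormatError

DIRECT = "direct"
INDIRECT = "indirect"
NOVEL = "potentially_novel"


@dataclass
class ReferenceNetwork:
    """Prior-knowledge interaction network, undirected unless a link's
    interaction type is listed in ``directed_types``."""

    nodes: set[str] = field(default_factory=set)
    links: set[tuple[str, str, str]] = field(default_factory=set)  # (a, type, b)
    directed_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        dropped = {(a, t, b) for (a, t, b) in self.links if a == b}
        if dropped:
            warnings.warn(f"dropped {len(dropped)} self-link(s) from reference network",
                          stacklevel=2)
            self.links -= dropped
        self._successors: dict[str, set[str]] = {}
        self._predecessors: dict[str, set[str]] = {}
        for a, t, b in self.links:
            self.nodes |= {a, b}
            self._successors.setdefault(a, set()).add(b)
            self._predecessors.setdefault(b, set()).add(a)
            if t not in self.directed_types:
                self._successors.setdefault(b, set()).add(a)
                self._predecessors.setdefault(a, set()).add(b)

    def __len__(self) -> int:
        return len(self.links)

    def successors(self, node: str) -> set[str]:
        return self._successors.get(node, set())

    def predecessors(self, node: str) -> set[str]:
        return self._predecessors.get(node, set())

    def has_link(self, source: str, target: str) -> bool:
        return target in self.successors(source)


def read_sif(path, directed_types: set[str] | None = None) -> ReferenceNetwork:
    """Parse a SIF file. Lines are ``node type node [node ...]`` — the
    standard dialect allows several targets per line — split on tabs when
    present, otherwise on whitespace. Self-links are dropped with a
    warning; duplicates collapse."""
    links: set[tuple[str, str, str]] = set()
    nodes: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) == 1:
                # bare node line: a node with no interactions (legal SIF)
                nodes.add(fields[0])
                continue
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: SIF line needs node, interaction type, "
                    f"node ({len(fields)} field(s) found)"
                )
            a, itype = fields[0], fields[1]
            for b in fields[2:]:
                links.add((a, itype, b))
    return ReferenceNetwork(nodes=nodes, links=links,
                            directed_types=set(directed_types or ()))


def classify_edge(source: str, target: str,
                  ref: ReferenceNetwork) -> tuple[str, str | None]:
    """Label one inferred edge; returns (label, witness-intermediary).

    direct: the reference joins source and target (respecting the directed
    policy); indirect: some third node w has links source-w and w-target;
    otherwise potentially novel. The witness is the lexicographically first
    intermediary, None unless indirect.
    """
    if ref.has_link(source, target):
        return DIRECT, None
    middle = (ref.successors(source) & ref.predecessors(target)) - {source, target}
    if middle:
        return INDIRECT, min(middle)
    return NOVEL, None


@dataclass
class ValidationSummary:
    """Per-edge labels against the reference, with counts and fractions."""

    labels: list[dict]  # {source, target, label, witness}
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {DIRECT: 0, INDIRECT: 0, NOVEL: 0}
            for row in self.labels:
                self.counts[row["label"]] += 1
        total = sum(self.counts.values())
        self.fractions = (
            {k: v / total for k, v in self.counts.items()} if total
            else {k: float("nan") for k in self.counts}
        )

    @property
    def n_edges(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, columns=["source", "target", "label", "witness"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"counts": self.counts, "fractions": self.fractions,
                       "n_edges": self.n_edges}, fh, indent=2)


def classify_network(net: ConsensusNetwork | list[tuple[str, str]],
                     ref: ReferenceNetwork) -> ValidationSummary:
    """Classify every edge of a network (or a bare (source, target) list)."""
    if isinstance(net, ConsensusNetwork):
        pairs = [(e.source, e.target) for e in net.edges]
    else:
        pairs = [(s, t) for s, t in net]
    rows = []
    for source, target in pairs:
        label, witness = classify_edge(source, target, ref)
        rows.append({"source": source, "target": target, "label": label,
                     "witness": witness})
    return ValidationSummary(labels=rows)
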