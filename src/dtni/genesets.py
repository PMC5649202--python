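"""Pathway gene sets and the GMT reader.

A GMT line is ``name <tab> description <tab> gene1 <tab> gene2 ...``; this
is the export format of MSigDB, KEGG and WikiPathways gene-set dumps.
Duplicate identifiers within a line are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataValidationError, FormatError


@dataclass
class GeneSet:
    name: str
    genes: set[str]
    source: str = ""
    order: list[str] = field(default_factory=list)  # first-appearance order

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise DataValidationError(f"gene set {self.name!r} is empty")
        if not self.order:
            self.order = sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file into a list of :class:`GeneSet`, in file order."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name, description = fields[0], fields[1]
            order: list[str] = []
            for g in fields[2:]:
                if g and g not in order:
                    order.append(g)
            if not order:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=set(order), source=description, order=order))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, gs.source or gs.name, *gs.order]) + "\n")
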