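"""Dose x time expression containers and long-format TSV I/O.

Expression values are log2 ratios of exposed samples against the mean of
time-matched controls. The canonical interchange format is a tab-separated
long table with columns ``gene, compound, dose, dose_rank, time, replicate,
value`` — one row per (gene, sample) measurement.

Designs are required to be *balanced*: every compound must carry every
(dose_rank, time) cell, possibly with several replicates. Inference further
requires at least three distinct doses and three distinct time points per
compound (see :func:`validate_design`), the minimum under which the
dose-time ODE model is identifiable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError, FormatError

EXPRESSION_COLUMNS = ["gene", "compound", "dose", "dose_rank", "time", "replicate", "value"]


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """One exposed sample: a (compound, dose, time, replicate) coordinate.

    ``dose`` is in native units (e.g. uM); ``dose_rank`` orders the tested
    doses within a compound, 1 = lowest. ``time`` is hours post exposure.
    """

    compound: str
    dose: float
    dose_rank: int
    time: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DataValidationError(f"negative dose {self.dose} for {self.compound}")
        if self.dose_rank < 1:
            raise DataValidationError(f"dose_rank must be >= 1, got {self.dose_rank}")
        if self.time <= 0:
            raise DataValidationError(f"time must be positive hours, got {self.time}")
        if self.replicate < 1:
            raise DataValidationError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def cell(self) -> tuple[str, int, float]:
        """The design cell this sample occupies, ignoring the replicate."""
        return (self.compound, self.dose_rank, self.time)


@dataclass
class DoseTimeExpressionSet:
    """Gene x sample matrix of log2 ratios over a dose-time design.

    ``values[i, s]`` is the log2 ratio of gene ``genes[i]`` in sample
    ``samples[s]``. Construction checks finiteness, uniqueness of sample
    coordinates, dose/dose_rank consistency, and balance of the design.
    """

    genes: list[str]
    samples: list[SampleDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) == 0:
            raise DataValidationError("expression set has no genes")
        if len(self.samples) == 0:
            raise DataValidationError("expression set has no samples")
        if len(set(self.genes)) != len(self.genes):
            raise DataValidationError("duplicate gene identifiers")
        if any(g == "" or g is None for g in self.genes):
            raise DataValidationError("missing gene identifier")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression values must be finite")
        keys = [(s.compound, s.dose_rank, s.time, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise DataValidationError("duplicate (compound, dose_rank, time, replicate) sample")
        self._check_dose_rank_consistency()
        self._check_balanced()

    def _check_dose_rank_consistency(self) -> None:
        for compound in self.compounds:
            pairs = sorted({(s.dose_rank, s.dose) for s in self.samples if s.compound == compound})
            ranks = [r for r, _ in pairs]
            doses = [d for _, d in pairs]
            if len(set(ranks)) != len(ranks):
                raise DataValidationError(
                    f"compound {compound}: one dose_rank maps to several doses"
                )
            if doses != sorted(doses) or len(set(doses)) != len(doses):
                raise DataValidationError(
                    f"compound {compound}: dose_rank order inconsistent with dose order"
                )

    def _check_balanced(self) -> None:
        """Every (dose_rank, time) cell must exist for every compound, with a
        common replicate count per compound."""
        for compound in self.compounds:
            mine = [s for s in self.samples if s.compound == compound]
            ranks = sorted({s.dose_rank for s in mine})
            times = sorted({s.time for s in mine})
            counts: dict[tuple[int, float], int] = {}
            for s in mine:
                counts[(s.dose_rank, s.time)] = counts.get((s.dose_rank, s.time), 0) + 1
            for r in ranks:
                for t in times:
                    if (r, t) not in counts:
                        raise DataValidationError(
                            f"unbalanced design: compound {compound} is missing the "
                            f"(dose_rank={r}, time={t}) cell"
                        )
            if len(set(counts.values())) > 1:
                raise DataValidationError(
                    f"unbalanced design: compound {compound} has uneven replicate "
                    f"counts across (dose, time) cells"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.compound, None)
        return list(seen)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in expression set") from None

    def doses_of(self, compound: str) -> list[float]:
        """Tested doses of a compound, in increasing order."""
        return sorted({s.dose for s in self.samples if s.compound == compound})

    def times_of(self, compound: str) -> list[float]:
        return sorted({s.time for s in self.samples if s.compound == compound})

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with the canonical columns."""
        records = []
        for j, s in enumerate(self.samples):
            for i, g in enumerate(self.genes):
                records.append((g, s.compound, s.dose, s.dose_rank, s.time, s.replicate,
                                self.values[i, j]))
        return pd.DataFrame.from_records(records, columns=EXPRESSION_COLUMNS)


def read_expression_long(path) -> DoseTimeExpressionSet:
    """Read the canonical long-format TSV into a :class:`DoseTimeExpressionSet`.

    Gene order is first-appearance order; sample order is first-appearance
    order of the (compound, dose_rank, time, replicate) coordinate.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    def numeric(column: str, caster) -> np.ndarray:
        # element-wise float(): pandas' fast parser is not correctly rounded,
        # which would break bit-exact round-trips
        out = np.empty(len(table), dtype=float)
        for row, text in enumerate(table[column]):
            try:
                out[row] = float(text)
            except ValueError:
                # +2: header line plus 1-based numbering
                raise FormatError(
                    f"{path}: non-numeric {column} value {text!r} on line {row + 2}"
                ) from None
        return out.astype(caster)

    dose = numeric("dose", float)
    dose_rank = numeric("dose_rank", int)
    time = numeric("time", float)
    replicate = numeric("replicate", int)
    value = numeric("value", float)

    genes: dict[str, int] = {}
    samples: dict[tuple, int] = {}
    descriptors: list[SampleDescriptor] = []
    for k in range(len(table)):
        g = table["gene"].iloc[k]
        if g not in genes:
            genes[g] = len(genes)
        key = (table["compound"].iloc[k], dose_rank[k], time[k], replicate[k])
        if key not in samples:
            samples[key] = len(samples)
            descriptors.append(
                SampleDescriptor(compound=key[0], dose=float(dose[k]), dose_rank=int(key[1]),
                                 time=float(key[2]), replicate=int(key[3]))
            )
    values = np.full((len(genes), len(descriptors)), np.nan)
    for k in range(len(table)):
        i = genes[table["gene"].iloc[k]]
        j = samples[(table["compound"].iloc[k], dose_rank[k], time[k], replicate[k])]
        values[i, j] = value[k]
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        d = descriptors[j]
        raise DataValidationError(
            f"{path}: missing value for gene {list(genes)[i]} in sample "
            f"(compound={d.compound}, dose_rank={d.dose_rank}, time={d.time}, "
            f"replicate={d.replicate})"
        )
    return DoseTimeExpressionSet(genes=list(genes), samples=descriptors, values=values)


def write_expression_long(ds: DoseTimeExpressionSet, path) -> None:
    """Write the exact dialect :func:`read_expression_long` consumes.

    Values are printed with 17 significant digits, enough to round-trip an
    IEEE double exactly.
    """
    if not isinstance(ds, DoseTimeExpressionSet):
        raise DataValidationError("write_expression_long expects a DoseTimeExpressionSet")
    frame = ds.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def compute_log_ratios(
    exposed: DoseTimeExpressionSet,
    control_times: list[float],
    control_values: np.ndarray,
    control_genes: list[str] | None = None,
) -> DoseTimeExpressionSet:
    """Turn log2 intensities into log2 ratios against time-matched controls.

    Parameters
    ----------
    exposed
        Log2-scale intensities of exposed samples, in the usual container
        (its ``values`` are intensities, not yet ratios).
    control_times
        Time point (hours) of each control sample, one entry per control
        column; several replicates per time are expected.
    control_values
        Gene x control-sample matrix of log2 intensities, gene order matching
        ``exposed.genes`` (or ``control_genes`` when given).
    control_genes
        Optional gene order of ``control_values``; defaults to the exposed
        gene order.

    Returns
    -------
    DoseTimeExpressionSet
        value(g, s) = intensity(g, s) - mean over control replicates at the
        same time point.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_genes is not None:
        order = [control_genes.index(g) for g in exposed.genes]
        control_values = control_values[order, :]
    if control_values.shape != (exposed.n_genes, len(control_times)):
        raise DataValidationError("control matrix shape does not match genes x control samples")
    control_times = [float(t) for t in control_times]
    means: dict[float, np.ndarray] = {}
    for t in set(control_times):
        cols = [j for j, ct in enumerate(control_times) if ct == t]
        means[t] = control_values[:, cols].mean(axis=1)
    ratios = np.empty_like(exposed.values)
    for j, s in enumerate(exposed.samples):
        if s.time not in means:
            raise DataValidationError(
                f"no time-matched control for time point {s.time} h (compound {s.compound})"
            )
        ratios[:, j] = exposed.values[:, j] - means[s.time]
    return DoseTimeExpressionSet(genes=list(exposed.genes), samples=list(exposed.samples),
                                 values=ratios)


def average_replicates(ds: DoseTimeExpressionSet) -> DoseTimeExpressionSet:
    """Collapse replicates to their arithmetic mean, one sample per
    (compound, dose_rank, time) cell. Idempotent."""
    cells: dict[tuple[str, int, float], list[int]] = {}
    order: list[tuple[str, int, float]] = []
    for j, s in enumerate(ds.samples):
        if s.cell not in cells:
            cells[s.cell] = []
            order.append(s.cell)
        cells[s.cell].append(j)
    samples = []
    values = np.empty((ds.n_genes, len(order)))
    for k, cell in enumerate(order):
        cols = cells[cell]
        first = ds.samples[cols[0]]
        samples.append(replace(first, replicate=1))
        values[:, k] = ds.values[:, cols].mean(axis=1)
    return DoseTimeExpressionSet(genes=list(ds.genes), samples=samples, values=values)


@dataclass
class SubsetReport:
    requested: int
    found: int
    missing: list[str] = field(default_factory=list)


def subset_genes(ds: DoseTimeExpressionSet, geneset) -> tuple[DoseTimeExpressionSet, SubsetReport]:
    """Restrict the expression set to genes in ``geneset`` (a GeneSet or any
    iterable of identifiers), preserving the set's gene order.

    Returns the restricted set and a (requested, found) report. Raises
    :class:`DataValidationError` when no requested gene is present.
    """
    wanted = set(geneset.genes) if hasattr(geneset, "genes") else set(geneset)
    keep = [i for i, g in enumerate(ds.genes) if g in wanted]
    if not keep:
        raise DataValidationError("no gene of the requested set is present in the data")
    found = [ds.genes[i] for i in keep]
    report = SubsetReport(requested=len(wanted), found=len(keep),
                          missing=sorted(wanted - set(found)))
    sub = DoseTimeExpressionSet(genes=found, samples=list(ds.samples),
                                values=ds.values[keep, :])
    return sub, report


@dataclass
class DesignReport:
    """Outcome of the minimum-design check (>=3 doses and >=3 time points
    per compound)."""

    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_design(ds: DoseTimeExpressionSet, min_doses: int = 3,
                    min_times: int = 3) -> DesignReport:
    """Check each compound for at least ``min_doses`` distinct dose ranks and
    ``min_times`` distinct time points. Report-style: never raises."""
    violations = []
    for compound in ds.compounds:
        ranks = {s.dose_rank for s in ds.samples if s.compound == compound}
        times = {s.time for s in ds.samples if s.compound == compound}
        if len(ranks) < min_doses:
            violations.append(
                f"compound {compound}: {len(ranks)} dose level(s), need >= {min_doses}"
            )
        if len(times) < min_times:
            violations.append(
                f"compound {compound}: {len(times)} time point(s), need >= {min_times}"
            )
    return DesignReport(passed=not violations, violations=violations)
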