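"""Mappability coverage and the statistical comparison of mapping rates.

For a source-model class C mapped against target model i the mappability
rate is

    P(C, i) = m(C, i) / (t(C) - e(C))

where m is the number of distinct mapped properties, t the total property
count of the class and e the count removed by the exclusion rules.
Forward class means average P(C, i) over the target models; backward
model means average P(C, i) over the included classes of each related
model.  Rate independence from the compared model is tested with a
Pearson chi-squared test on mapped/unmapped counts; differences between
harmonized "standard classes" (Study, Sample source, Experiment,
Analysis) with a Kruskal-Wallis test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .crosswalk import MappingSet, PropertyRef, mapped_property_set
from .exceptions import ConfigError, FormatError, IntegrityError
from .rules_filter import FilterOutcome

STANDARD_CLASSES = ("Study", "Sample source", "Experiment", "Analysis")


@dataclass(frozen=True)
class CoverageCell:
    """m, t, e counts and the mappability rate for one (class, model)."""

    class_name: str
    model: str
    m: int
    t: int
    e: int

    def __post_init__(self):
        if not 0 <= self.m <= self.t - self.e:
            raise IntegrityError(
                f"coverage cell {self.class_name}/{self.model}: "
                f"m={self.m} outside [0, t-e={self.t - self.e}]"
            )

    @property
    def included(self) -> int:
        return self.t - self.e

    @property
    def P(self) -> float:
        return self.m / self.included


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: int
    p_value: float
    warnings: tuple[str, ...] = ()
    group_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise IntegrityError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class StandardClassMap:
    """Assignment of model classes to harmonized standard classes."""

    assignments: dict[str, tuple[tuple[str, str], ...]]

    def classes_for(self, standard_class: str, model: str) -> tuple[str, ...]:
        return tuple(
            c for (m, c) in self.assignments.get(standard_class, ()) if m == model
        )

    def validate_against(self, tables: dict) -> None:
        """Every assigned (model, class) must exist in that model's table."""
        for std, pairs in self.assignments.items():
            for model, cls in pairs:
                if model not in tables or cls not in tables[model].classes:
                    raise IntegrityError(
                        f"standard class {std!r} assigns unknown class "
                        f"{model}:{cls}"
                    )


def load_standard_class_map(path) -> StandardClassMap:
    """Read a standard-class map YAML: {standard class: [[model, class], ...]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: standard-class map must be a YAML mapping")
    return StandardClassMap(
        assignments={
            std: tuple((str(m), str(c)) for m, c in pairs)
            for std, pairs in doc.items()
        }
    )


def class_coverage(
    mset: MappingSet, source_filter: FilterOutcome
) -> list[CoverageCell]:
    """One coverage cell per source class with a non-empty denominator.

    Classes whose every property was excluded are omitted (with a
    warning).  Mapped subjects must come from the included table.
    """
    mapped = mapped_property_set(mset).subjects
    included_keys = source_filter.included.keys
    for ref in mapped:
        if (ref.model, ref.class_name, ref.property_name) not in included_keys:
            raise IntegrityError(
                f"mapped subject {ref.curie()} is not in the included "
                f"property set of model {source_filter.model!r}"
            )
    t_by_class = source_filter.t_by_class
    e_by_class = source_filter.e_by_class
    m_by_class: dict[str, int] = {}
    for ref in mapped:
        m_by_class[ref.class_name] = m_by_class.get(ref.class_name, 0) + 1
    cells = []
    for cls in sorted(t_by_class):
        t = t_by_class[cls]
        e = e_by_class.get(cls, 0)
        if t - e <= 0:
            warnings.warn(
                f"class {cls!r} of {source_filter.model!r} fully excluded; "
                f"omitted from coverage",
                stacklevel=2,
            )
            continue
        cells.append(
            CoverageCell(
                class_name=cls,
                model=mset.target_model if mset.direction == "forward" else mset.source_model,
                m=m_by_class.get(cls, 0),
                t=t,
                e=e,
            )
        )
    return cells


def forward_class_means(
    coverage_lists: list[list[CoverageCell]],
) -> dict[str, float]:
    """Mean mappability per source class over all target models.

    Every target list must cover the same class set: the mean has one
    term per target model.
    """
    class_sets = [frozenset(c.class_name for c in lst) for lst in coverage_lists]
    if len(set(class_sets)) != 1:
        raise IntegrityError(
            "target coverage lists disagree on the source class set: "
            + "; ".join(str(sorted(s)) for s in set(class_sets))
        )
    n = len(coverage_lists)
    sums: dict[str, float] = {}
    for lst in coverage_lists:
        for cell in lst:
            sums[cell.class_name] = sums.get(cell.class_name, 0.0) + cell.P
    return {cls: total / n for cls, total in sorted(sums.items())}


def backward_model_means(
    cells_by_model: dict[str, list[CoverageCell]],
) -> dict[str, tuple[float, int]]:
    """Mean mappability per related model over its included classes.

    Returns ``{model: (mean rate, number of included classes)}``.
    """
    out = {}
    for model, cells in cells_by_model.items():
        if not cells:
            raise IntegrityError(f"model {model!r} has no included classes")
        out[model] = (float(np.mean([c.P for c in cells])), len(cells))
    return out


def mappability_contingency(
    cells_by_model: dict[str, list[CoverageCell]],
) -> pd.DataFrame:
    """Property-level mapped/unmapped counts per model (rows = models)."""
    rows = {}
    for model, cells in cells_by_model.items():
        mapped = sum(c.m for c in cells)
        total = sum(c.included for c in cells)
        rows[model] = {"mapped": mapped, "unmapped": total - mapped}
    return pd.DataFrame.from_dict(rows, orient="index")


def chi_squared_mappability(contingency, correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on a models x
    {mapped, unmapped} table.  Continuity correction is off by default."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ConfigError("contingency table needs >= 2 rows and 2 columns")
    if (table < 0).any():
        raise ConfigError("contingency counts must be non-negative")
    if table.sum() == 0:
        raise ConfigError("contingency table has zero total")
    res = stats.chi2_contingency(table, correction=correction)
    warn = ()
    if (res.expected_freq < 5).any():
        warn = ("expected count < 5 in at least one cell",)
    return TestResult(
        method="pearson_chi_squared",
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        warnings=warn,
    )


def standard_class_rates(
    cells_by_model: dict[str, list[CoverageCell]],
    scm: StandardClassMap,
    aggregation: str = "pooled",
) -> dict[str, dict[str, float]]:
    """Mappability per (model, standard class).

    ``pooled`` divides pooled counts sum(m)/sum(t-e) over the assigned
    classes (weights classes by size); ``mean`` averages the class rates.
    """
    if aggregation not in ("pooled", "mean"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    out: dict[str, dict[str, float]] = {}
    for model, cells in cells_by_model.items():
        by_class = {c.class_name: c for c in cells}
        rates: dict[str, float] = {}
        for std in scm.assignments:
            assigned = [by_class[c] for c in scm.classes_for(std, model) if c in by_class]
            if not assigned:
                continue
            if aggregation == "pooled":
                rates[std] = sum(c.m for c in assigned) / sum(c.included for c in assigned)
            else:
                rates[std] = float(np.mean([c.P for c in assigned]))
        out[model] = rates
    return out


def kruskal_wallis_classes(
    rates_by_model: dict[str, list[float]],
) -> TestResult:
    """Tie-corrected Kruskal-Wallis test across model groups of
    standard-class mappability rates.  Degenerate input in which every
    observation is identical yields H = 0, p = 1."""
    groups = {m: list(v) for m, v in rates_by_model.items()}
    if len(groups) < 2:
        raise ConfigError("Kruskal-Wallis needs >= 2 groups")
    empty = [m for m, v in groups.items() if not v]
    if empty:
        raise ConfigError(f"empty group(s): {empty}")
    values = list(groups.values())
    flat = [x for v in values for x in v]
    medians = {m: float(np.median(v)) for m, v in groups.items()}
    if len(set(flat)) == 1:
        return TestResult(
            method="kruskal_wallis",
            statistic=0.0,
            df=len(groups) - 1,
            p_value=1.0,
            group_medians=medians,
        )
    stat, p = stats.kruskal(*values)
    return TestResult(
        method="kruskal_wallis",
        statistic=float(stat),
        df=len(groups) - 1,
        p_value=float(p),
        group_medians=medians,
    )


@dataclass(frozen=True)
class CoverageTable:
    """All coverage cells of one run plus the aggregate means."""

    cells: tuple[CoverageCell, ...]
    class_means: dict[str, float] = field(default_factory=dict)
    model_means: dict[str, tuple[float, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [c.class_name for c in self.cells],
                "model": [c.model for c in self.cells],
                "m": [c.m for c in self.cells],
                "t": [c.t for c in self.cells],
                "e": [c.e for c in self.cells],
                "P": [c.P for c in self.cells],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def brute_force_cell(
    mset: MappingSet, source_filter: FilterOutcome, class_name: str
) -> tuple[int, int, int]:
    """Independent record-by-record recount of (m, t, e) for one class.

    Used as an oracle in tests: walks the raw records without any of the
    set-based machinery above.
    """
    t = e = 0
    for rec in source_filter.included:
        if rec.class_name == class_name:
            t += 1
    for rec in source_filter.excluded:
        if rec.class_name == class_name:
            t += 1
            e += 1
    seen: set[PropertyRef] = set()
    for rec in mset:
        if rec.is_match and rec.subject.class_name == class_name:
            seen.add(rec.subject)
    return len(seen), t, e
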