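"""Presence-absence matrix over source properties and consensus detection.

Each included source-model property becomes one row; each target model a
boolean column that is true when the property has at least one curated
match into that model.  A property is a *consensus* field when it is
present in at least ``threshold`` of the target models (default 3 of 4,
i.e. at least 4 of the 5 frameworks counting the source itself).
Consensus fields are further split into *controllable* (values can be
validated against vocabularies, ontologies, patterns or primitive types)
and *descriptive* (free-text names, titles and descriptions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .crosswalk import MappingSet, PropertyRef, mapped_property_set
from .exceptions import ConfigError, IntegrityError
from .rules_filter import FilterOutcome
from .schema_ingest import CONTROLLABLE_RANGE_KINDS

DESCRIPTIVE_RANGE_KINDS = frozenset({"free_text", "not_controllable"})

ANNOTATION_COLUMNS = ("class", "property", "requirement", "range_kind")


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Included source properties x target models, with row annotations."""

    source_model: str
    target_models: tuple[str, ...]
    frame: pd.DataFrame  # annotation columns + one bool column per target

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def presence_counts(self) -> pd.Series:
        return self.frame[list(self.target_models)].sum(axis=1)

    def column_sums(self) -> dict[str, int]:
        return {m: int(self.frame[m].sum()) for m in self.target_models}

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConsensusReport:
    """Consensus rows plus the bookkeeping the analysis reports."""

    threshold: int
    n_targets: int
    consensus: pd.DataFrame  # consensus rows incl. 'presence' column
    per_class: dict[str, int] = field(default_factory=dict)
    per_model_missing: dict[str, int] = field(default_factory=dict)
    requirement_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def n_consensus(self) -> int:
        return len(self.consensus)

    @property
    def n_in_all_targets(self) -> int:
        """Rows present in every target model (hence in all frameworks,
        source included)."""
        return int((self.consensus["presence"] == self.n_targets).sum())


def build_presence_absence(
    sets: list[MappingSet], source_filter: FilterOutcome
) -> PresenceAbsenceMatrix:
    """Derive the presence-absence matrix from forward mapping sets.

    Rows are ordered by class then property name.  All sets must share
    the source model; duplicate target models are rejected.
    """
    if not sets:
        raise ConfigError("need at least one mapping set")
    source_model = source_filter.model
    targets = []
    for s in sets:
        if s.source_model != source_model:
            raise IntegrityError(
                f"mapping set {s.source_model}->{s.target_model} does not "
                f"start from source model {source_model!r}"
            )
        if s.target_model in targets:
            raise IntegrityError(f"duplicate target model {s.target_model!r}")
        targets.append(s.target_model)

    mapped = {s.target_model: mapped_property_set(s).subjects for s in sets}
    rows = sorted(
        source_filter.included,
        key=lambda r: (r.class_name, r.property_name),
    )
    data = {
        "class": [r.class_name for r in rows],
        "property": [r.property_name for r in rows],
        "requirement": [r.requirement for r in rows],
        "range_kind": [r.range_kind for r in rows],
    }
    for t in targets:
        data[t] = [
            PropertyRef(r.model, r.class_name, r.property_name) in mapped[t]
            for r in rows
        ]
    return PresenceAbsenceMatrix(
        source_model=source_model,
        target_models=tuple(targets),
        frame=pd.DataFrame(data),
    )


def find_consensus(
    matrix: PresenceAbsenceMatrix, threshold: int = 3
) -> ConsensusReport:
    """Rows present in at least ``threshold`` target models."""
    n_targets = len(matrix.target_models)
    if not 1 <= threshold <= n_targets:
        raise ConfigError(
            f"threshold {threshold} outside 1..{n_targets}"
        )
    frame = matrix.frame.copy()
    frame["presence"] = matrix.presence_counts()
    consensus = frame[frame["presence"] >= threshold].reset_index(drop=True)
    per_model_missing = {
        m: int((~consensus[m].astype(bool)).sum()) for m in matrix.target_models
    }
    return ConsensusReport(
        threshold=threshold,
        n_targets=n_targets,
        consensus=consensus,
        per_class=dict(Counter(consensus["class"])),
        per_model_missing=per_model_missing,
        requirement_breakdown=dict(Counter(consensus["requirement"])),
    )


def classify_consensus(report: ConsensusReport) -> dict[str, list[tuple[str, str]]]:
    """Partition consensus fields into controllable vs descriptive.

    Controllable fields accept values checkable against a vocabulary,
    ontology, pattern, boolean or integer; descriptive fields are
    free-text identification/description properties.  Rows whose range
    kind is unspecified are listed separately, never silently binned.
    """
    out: dict[str, list[tuple[str, str]]] = {
        "controllable": [],
        "descriptive": [],
        "unspecified": [],
    }
    cols = report.consensus
    for cls, prop, kind in zip(cols["class"], cols["property"], cols["range_kind"]):
        key = (cls, prop)
        if kind in CONTROLLABLE_RANGE_KINDS:
            out["controllable"].append(key)
        elif kind in DESCRIPTIVE_RANGE_KINDS:
            out["descriptive"].append(key)
        else:
            out["unspecified"].append(key)
    return out


def plot_presence_absence(matrix: PresenceAbsenceMatrix, path, threshold: int = 3):
    """Optional heatmap rendering of the presence-absence matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = matrix.frame
    data = frame[list(matrix.target_models)].astype(int).to_numpy()
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * len(matrix.target_models), 1 + 0.18 * len(frame))
    )
    ax.imshow(data, aspect="auto", cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.target_models)))
    ax.set_xticklabels(matrix.target_models, rotation=45, ha="right")
    ax.set_yticks(range(len(frame)))
    labels = [
        f"{c}.{p}" + (" *" if n >= threshold else "")
        for c, p, n in zip(frame["class"], frame["property"], matrix.presence_counts())
    ]
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_title(f"Presence-absence matrix ({matrix.source_model})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
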