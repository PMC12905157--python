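"""Ingest metadata-schema definitions into validated long property tables.

A metadata model (a schema describing, e.g., studies, samples, experiments
and analyses in a genomics archive) is represented as a *long table*: one
row per (model, class, property) with a requirement level and a description
of how the property's values are constrained (its *range kind*).  Two
dialects are supported:

* a canonical tab-delimited table (the exchange format every downstream
  stage consumes), and
* a LinkML-flavoured YAML schema (classes, slots, mixins, enums), which is
  flattened into the canonical form.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .exceptions import FormatError, IntegrityError, SchemaError

REQUIREMENT_LEVELS = ("required", "recommended", "optional", "unspecified")
RANGE_KINDS = (
    "controlled_vocabulary",
    "ontology",
    "pattern",
    "boolean",
    "integer",
    "free_text",
    "not_controllable",
    "unspecified",
)

#: range kinds whose values can be machine-validated (vocabularies,
#: ontologies, regular expressions, primitive types)
CONTROLLABLE_RANGE_KINDS = frozenset(
    {"controlled_vocabulary", "ontology", "pattern", "boolean", "integer"}
)

CANONICAL_COLUMNS = ("model", "class", "property")
OPTIONAL_COLUMNS = ("description", "requirement", "range_kind", "vocabulary")


@dataclass(frozen=True)
class PropertyRecord:
    """One schema property: a named slot of a class in a metadata model."""

    model: str
    class_name: str
    property_name: str
    description: str = ""
    requirement: str = "unspecified"
    range_kind: str = "unspecified"
    vocabulary: tuple[str, ...] = ()

    def __post_init__(self):
        if self.requirement not in REQUIREMENT_LEVELS:
            raise FormatError(
                f"unknown requirement {self.requirement!r} for "
                f"{self.model}:{self.class_name}.{self.property_name}; "
                f"expected one of {REQUIREMENT_LEVELS}"
            )
        if self.range_kind not in RANGE_KINDS:
            raise FormatError(
                f"unknown range_kind {self.range_kind!r} for "
                f"{self.model}:{self.class_name}.{self.property_name}; "
                f"expected one of {RANGE_KINDS}"
            )
        if "." in self.property_name:
            raise FormatError(
                f"property names must not contain '.': {self.property_name!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.model, self.class_name, self.property_name)


@dataclass(frozen=True)
class SchemaTable:
    """A validated collection of :class:`PropertyRecord` for one model."""

    model: str
    records: tuple[PropertyRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        foreign = [r for r in self.records if r.model != self.model]
        if foreign:
            raise IntegrityError(
                f"records for foreign model(s) in table {self.model!r}: "
                f"{sorted({r.model for r in foreign})}"
            )
        seen = Counter(r.key for r in self.records)
        dups = sorted(k for k, n in seen.items() if n > 1)
        if dups:
            raise IntegrityError(
                f"duplicate (model, class, property) keys: {dups}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def classes(self) -> tuple[str, ...]:
        out, seen = [], set()
        for r in self.records:
            if r.class_name not in seen:
                seen.add(r.class_name)
                out.append(r.class_name)
        return tuple(out)

    @property
    def keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(r.key for r in self.records)

    def get(self, class_name: str, property_name: str) -> PropertyRecord | None:
        for r in self.records:
            if r.class_name == class_name and r.property_name == property_name:
                return r
        return None

    def subset(self, records) -> "SchemaTable":
        return replace(self, records=tuple(records))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r.model for r in self.records],
                "class": [r.class_name for r in self.records],
                "property": [r.property_name for r in self.records],
                "description": [r.description for r in self.records],
                "requirement": [r.requirement for r in self.records],
                "range_kind": [r.range_kind for r in self.records],
                "vocabulary": ["|".join(r.vocabulary) for r in self.records],
            }
        )


@dataclass(frozen=True)
class SchemaSummary:
    """Record counts by class, requirement level and range kind."""

    n_records: int
    by_class: dict[str, int] = field(default_factory=dict)
    by_requirement: dict[str, int] = field(default_factory=dict)
    by_range_kind: dict[str, int] = field(default_factory=dict)

    @property
    def n_controlled(self) -> int:
        """Properties whose values can be machine-validated."""
        return sum(
            n for k, n in self.by_range_kind.items() if k in CONTROLLABLE_RANGE_KINDS
        )


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def load_canonical_table(path, model_id: str) -> SchemaTable:
    """Read a canonical long-table TSV and return the rows of one model.

    Mandatory columns: ``model``, ``class``, ``property``.  Optional:
    ``description``, ``requirement``, ``range_kind``, ``vocabulary``
    (pipe-joined permitted values).  Empty requirement/range cells become
    ``"unspecified"``; all cells are whitespace-trimmed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )
    records = []
    for d in df.to_dict("records"):
        if _clean(d["model"]) != model_id:
            continue
        vocab = tuple(
            v.strip() for v in _clean(d.get("vocabulary", "")).split("|") if v.strip()
        )
        records.append(
            PropertyRecord(
                model=model_id,
                class_name=_clean(d["class"]),
                property_name=_clean(d["property"]),
                description=_clean(d.get("description", "")),
                requirement=_clean(d.get("requirement", "")) or "unspecified",
                range_kind=_clean(d.get("range_kind", "")) or "unspecified",
                vocabulary=vocab,
            )
        )
    return SchemaTable(
        model=model_id,
        records=tuple(records),
        provenance=f"{path} [canonical-tsv]",
    )


def write_canonical(table: SchemaTable, path) -> None:
    """Write a SchemaTable in the canonical TSV dialect (lossless)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def _slot_range_kind(slot_def: dict, enums: dict, classes: dict) -> tuple[str, tuple[str, ...]]:
    annotations = slot_def.get("annotations") or {}
    rng = slot_def.get("range")
    if annotations.get("ontology"):
        return "ontology", ()
    if slot_def.get("pattern"):
        return "pattern", ()
    if rng in enums:
        values = tuple((enums[rng].get("permissible_values") or {}).keys())
        return "controlled_vocabulary", values
    if rng == "boolean":
        return "boolean", ()
    if rng == "integer":
        return "integer", ()
    if rng in classes:
        # inlined object reference: not a value a submitter could control
        return "not_controllable", ()
    return "free_text", ()


def _resolve_slots(cname: str, classes: dict, _stack=()) -> list[str]:
    """Own slots plus slots inherited via mixins / is_a, depth-first,
    parents first, duplicates removed keeping first occurrence."""
    if cname in _stack:
        raise SchemaError(f"circular mixin/is_a reference through {cname!r}")
    if cname not in classes:
        raise SchemaError(f"dangling class reference: {cname!r}")
    cdef = classes[cname] or {}
    slots: list[str] = []
    parents = list(cdef.get("mixins") or [])
    if cdef.get("is_a"):
        parents.insert(0, cdef["is_a"])
    for parent in parents:
        slots.extend(_resolve_slots(parent, classes, _stack + (cname,)))
    slots.extend(cdef.get("slots") or [])
    seen, out = set(), []
    for s in slots:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def flatten_linkml(path, model_id: str | None = None) -> SchemaTable:
    """Flatten a LinkML-flavoured YAML schema into a SchemaTable.

    One record per (class, slot) pair after mixin / is_a resolution.
    Mixin-only classes and the root container class (``tree_root: true``)
    are excluded: they model packaging, not information content.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    model = model_id or doc.get("name")
    if not model:
        raise SchemaError(f"{path}: schema has no 'name' and no model_id given")
    classes = doc.get("classes") or {}
    slot_defs = doc.get("slots") or {}
    enums = doc.get("enums") or {}

    records = []
    for cname, cdef in classes.items():
        cdef = cdef or {}
        if cdef.get("mixin") or cdef.get("tree_root"):
            continue
        slot_usage = cdef.get("slot_usage") or {}
        for slot in _resolve_slots(cname, classes):
            if slot not in slot_defs:
                raise SchemaError(
                    f"class {cname!r} references undefined slot {slot!r}"
                )
            sdef = dict(slot_defs[slot] or {})
            sdef.update(slot_usage.get(slot) or {})
            if sdef.get("required"):
                requirement = "required"
            elif sdef.get("recommended"):
                requirement = "recommended"
            else:
                requirement = "optional"
            range_kind, vocab = _slot_range_kind(sdef, enums, classes)
            records.append(
                PropertyRecord(
                    model=model,
                    class_name=cname,
                    property_name=slot.replace(".", " "),
                    description=_clean(sdef.get("description", "")),
                    requirement=requirement,
                    range_kind=range_kind,
                    vocabulary=vocab,
                )
            )
    return SchemaTable(
        model=model,
        records=tuple(records),
        provenance=f"{path} [linkml-yaml {doc.get('version', '')}]".rstrip(),
    )


def summarize_schema(table: SchemaTable) -> SchemaSummary:
    """Counts of records by class, requirement level and range kind."""
    return SchemaSummary(
        n_records=len(table),
        by_class=dict(Counter(r.class_name for r in table)),
        by_requirement=dict(Counter(r.requirement for r in table)),
        by_range_kind=dict(Counter(r.range_kind for r in table)),
    )


def load_schema(path, dialect: str, model_id: str) -> SchemaTable:
    """Dispatch on dialect: ``canonical`` (TSV) or ``linkml`` (YAML)."""
    if dialect == "canonical":
        return load_canonical_table(path, model_id)
    if dialect == "linkml":
        return flatten_linkml(path, model_id)
    raise FormatError(f"unknown schema dialect {dialect!r}")
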