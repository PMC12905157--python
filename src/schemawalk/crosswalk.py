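"""Curated property mapping sets in SSSOM TSV form.

A crosswalk between two metadata models is a set of human-curated
correspondences between their properties, labelled with SKOS mapping
predicates (``exactMatch`` > ``closeMatch`` > ``broadMatch`` >
``narrowMatch``) and semapv mapping justifications (lexical match vs
background-knowledge-based matching).  A source property with no
counterpart is recorded explicitly as a ``noMatch`` row whose object is
the ``sssom:NoTermFound`` sentinel, so coverage denominators stay
auditable inside one file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .exceptions import IntegrityError, ParseError, VocabularyError
from .rules_filter import FilterOutcome

PREDICATES = ("exactMatch", "closeMatch", "broadMatch", "narrowMatch", "noMatch")
#: precedence used when one subject has several match records
PREDICATE_ORDER = {p: i for i, p in enumerate(PREDICATES)}
JUSTIFICATIONS = ("lexicalMatch", "background_knowledge", "none")
DIRECTIONS = ("forward", "backward", "cross")

NO_TERM_FOUND = "sssom:NoTermFound"

_PREDICATE_ALIASES = {
    **{p: p for p in PREDICATES},
    **{f"skos:{p}": p for p in PREDICATES},
}
_JUSTIFICATION_ALIASES = {
    "lexicalMatch": "lexicalMatch",
    "semapv:LexicalMatching": "lexicalMatch",
    "background_knowledge": "background_knowledge",
    "BKBM": "background_knowledge",
    "semapv:BackgroundKnowledgeBasedMatching": "background_knowledge",
    "none": "none",
    "": "none",
}
_PREDICATE_OUT = {p: f"skos:{p}" for p in PREDICATES}
_JUSTIFICATION_OUT = {
    "lexicalMatch": "semapv:LexicalMatching",
    "background_knowledge": "semapv:BackgroundKnowledgeBasedMatching",
    "none": "none",
}

SSSOM_COLUMNS = ("subject_id", "predicate_id", "object_id", "mapping_justification", "comment")


@dataclass(frozen=True, order=True)
class PropertyRef:
    """Reference to one property: ``model:Class.property``."""

    model: str
    class_name: str
    property_name: str

    def curie(self) -> str:
        return f"{self.model}:{self.class_name}.{self.property_name}"

    @classmethod
    def parse(cls, token: str, line: int | None = None) -> "PropertyRef":
        if ":" not in token:
            raise ParseError(f"no model prefix in id {token!r}", line)
        model, rest = token.split(":", 1)
        # property names never contain dots, so the last dot separates
        # the class from the property
        if "." not in rest:
            raise ParseError(f"no class/property separator in id {token!r}", line)
        cls_name, prop = rest.rsplit(".", 1)
        if not model or not cls_name:
            raise ParseError(f"empty model or class in id {token!r}", line)
        return cls(model=model, class_name=cls_name, property_name=prop)


@dataclass(frozen=True)
class MappingRecord:
    """One curated correspondence (or an explicit noMatch)."""

    subject: PropertyRef
    object: PropertyRef | None
    predicate: str
    justification: str = "none"
    comment: str = ""

    def __post_init__(self):
        if self.predicate not in PREDICATES:
            raise VocabularyError(f"unknown predicate {self.predicate!r}")
        if self.justification not in JUSTIFICATIONS:
            raise VocabularyError(f"unknown justification {self.justification!r}")
        if (self.predicate == "noMatch") != (self.object is None):
            raise IntegrityError(
                f"predicate noMatch requires the NoTermFound sentinel object "
                f"and vice versa (subject {self.subject.curie()})"
            )
        if self.predicate == "noMatch" and self.justification != "none":
            raise IntegrityError(
                f"noMatch records carry justification 'none' "
                f"(subject {self.subject.curie()})"
            )

    @property
    def is_match(self) -> bool:
        return self.predicate != "noMatch"


@dataclass(frozen=True)
class MappingSet:
    """A directed collection of mapping records between two models.

    For ``direction="cross"`` subjects and objects may span several
    models (cross-mapping among unmapped related-model properties);
    otherwise every subject belongs to ``source_model`` and every
    matched object to ``target_model``.
    """

    source_model: str
    target_model: str
    direction: str
    records: tuple[MappingRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if self.direction not in DIRECTIONS:
            raise VocabularyError(f"unknown direction {self.direction!r}")
        if self.direction != "cross":
            bad_subj = [r for r in self.records if r.subject.model != self.source_model]
            bad_obj = [
                r
                for r in self.records
                if r.object is not None and r.object.model != self.target_model
            ]
            if bad_subj or bad_obj:
                offenders = [r.subject.curie() for r in bad_subj] + [
                    r.object.curie() for r in bad_obj
                ]
                raise IntegrityError(
                    f"records outside {self.source_model}->{self.target_model}: "
                    f"{offenders[:5]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def subjects(self) -> frozenset[PropertyRef]:
        return frozenset(r.subject for r in self.records)


class MappedProperties(NamedTuple):
    """Subjects with at least one match, deduplicated for counting."""

    subjects: frozenset[PropertyRef]
    representatives: dict[PropertyRef, MappingRecord]


def mapped_property_set(mset: MappingSet) -> MappedProperties:
    """Subjects with >= 1 non-noMatch record, each counted once.

    One property may correspond to multiple fields in the target model;
    for counting and plotting a single representative is kept, chosen by
    predicate precedence (exactMatch first) and then by object id.
    """
    best: dict[PropertyRef, MappingRecord] = {}
    for rec in mset:
        if not rec.is_match:
            continue
        cur = best.get(rec.subject)
        if cur is None or (
            PREDICATE_ORDER[rec.predicate],
            rec.object.curie(),
        ) < (PREDICATE_ORDER[cur.predicate], cur.object.curie()):
            best[rec.subject] = rec
    return MappedProperties(subjects=frozenset(best), representatives=best)


@dataclass(frozen=True)
class ValidationReport:
    """Report-only validation of a mapping set against filter outcomes."""

    unknown_subjects: tuple[PropertyRef, ...] = ()
    unknown_objects: tuple[PropertyRef, ...] = ()
    excluded_subjects: tuple[PropertyRef, ...] = ()
    excluded_objects: tuple[PropertyRef, ...] = ()
    uncovered_source_properties: tuple[PropertyRef, ...] = ()
    class_level_objects: tuple[PropertyRef, ...] = ()

    @property
    def ok(self) -> bool:
        return not any(
            (
                self.unknown_subjects,
                self.unknown_objects,
                self.excluded_subjects,
                self.excluded_objects,
                self.uncovered_source_properties,
                self.class_level_objects,
            )
        )


def _ref_in(ref: PropertyRef, keys: frozenset) -> bool:
    return (ref.model, ref.class_name, ref.property_name) in keys


def validate_mapping_set(
    mset: MappingSet, source: FilterOutcome, target: FilterOutcome
) -> ValidationReport:
    """Check a mapping set against the filtered source/target schemas.

    Flags (a) subjects/objects resolving to neither the included nor the
    excluded table, (b) subjects/objects hitting the excluded table,
    (c) included source properties with no record at all, and (d)
    class-level objects (empty property name).
    """
    src_inc, src_exc = source.included.keys, source.excluded.keys
    tgt_inc, tgt_exc = target.included.keys, target.excluded.keys
    unknown_subj, unknown_obj = [], []
    excl_subj, excl_obj, class_level = [], [], []
    for rec in mset:
        s = rec.subject
        if _ref_in(s, src_exc):
            excl_subj.append(s)
        elif not _ref_in(s, src_inc):
            unknown_subj.append(s)
        o = rec.object
        if o is None:
            continue
        if not o.property_name:
            class_level.append(o)
        elif _ref_in(o, tgt_exc):
            excl_obj.append(o)
        elif not _ref_in(o, tgt_inc):
            unknown_obj.append(o)
    covered = mset.subjects
    uncovered = [
        PropertyRef(r.model, r.class_name, r.property_name)
        for r in source.included
        if PropertyRef(r.model, r.class_name, r.property_name) not in covered
    ]
    return ValidationReport(
        unknown_subjects=tuple(dict.fromkeys(unknown_subj)),
        unknown_objects=tuple(dict.fromkeys(unknown_obj)),
        excluded_subjects=tuple(dict.fromkeys(excl_subj)),
        excluded_objects=tuple(dict.fromkeys(excl_obj)),
        uncovered_source_properties=tuple(sorted(uncovered)),
        class_level_objects=tuple(dict.fromkeys(class_level)),
    )


def read_sssom(path) -> MappingSet:
    """Read an SSSOM TSV.  Leading ``#key: value`` lines carry the set
    metadata (source_model, target_model, direction, provenance)."""
    meta: dict[str, str] = {}
    records: list[MappingRecord] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("#"):
            body = raw.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if header is None:
            header = cells
            missing = [c for c in SSSOM_COLUMNS[:4] if c not in header]
            if missing:
                raise ParseError(f"missing SSSOM column(s) {missing}", lineno)
            continue
        row = dict(zip(header, cells))
        predicate_token = row.get("predicate_id", "").strip()
        if predicate_token not in _PREDICATE_ALIASES:
            raise VocabularyError(
                f"line {lineno}: unknown predicate {predicate_token!r}"
            )
        predicate = _PREDICATE_ALIASES[predicate_token]
        just_token = row.get("mapping_justification", "").strip()
        if just_token not in _JUSTIFICATION_ALIASES:
            raise VocabularyError(
                f"line {lineno}: unknown justification {just_token!r}"
            )
        subject = PropertyRef.parse(row.get("subject_id", "").strip(), lineno)
        object_token = row.get("object_id", "").strip()
        if predicate == "noMatch" or object_token == NO_TERM_FOUND:
            if predicate != "noMatch" or object_token != NO_TERM_FOUND:
                raise ParseError(
                    f"noMatch predicate and {NO_TERM_FOUND} object must co-occur",
                    lineno,
                )
            obj = None
        else:
            obj = PropertyRef.parse(object_token, lineno)
        records.append(
            MappingRecord(
                subject=subject,
                object=obj,
                predicate=predicate,
                justification=_JUSTIFICATION_ALIASES[just_token],
                comment=row.get("comment", ""),
            )
        )
    return MappingSet(
        source_model=meta.get("source_model", ""),
        target_model=meta.get("target_model", ""),
        direction=meta.get("direction", "forward"),
        records=tuple(records),
        provenance=meta.get("provenance", ""),
    )


def write_sssom(mset: MappingSet, path) -> None:
    """Write an SSSOM TSV.  The record block round-trips bit-exactly
    through :func:`read_sssom` (canonical prefixed tokens, stored record
    order preserved)."""
    lines = [
        f"#source_model: {mset.source_model}",
        f"#target_model: {mset.target_model}",
        f"#direction: {mset.direction}",
    ]
    if mset.provenance:
        lines.append(f"#provenance: {mset.provenance}")
    lines.append("\t".join(SSSOM_COLUMNS))
    for rec in mset:
        object_id = NO_TERM_FOUND if rec.object is None else rec.object.curie()
        lines.append(
            "\t".join(
                (
                    rec.subject.curie(),
                    _PREDICATE_OUT[rec.predicate],
                    object_id,
                    _JUSTIFICATION_OUT[rec.justification],
                    rec.comment,
                )
            )
        )
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
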