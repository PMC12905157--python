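"""Property-exclusion rules applied before any mapping analysis.

Crosswalks compare *information content*, so properties that exist for
model mechanics are removed first: non-defined catch-alls (``attributes``,
``comments``, ``extra attributes``), linking properties (``alias`` and
entity-ID slots) and framework-specific plumbing (archive accessions,
ontology-term-ID companions, provisional IDs).  The per-class excluded
count e(C) feeds the mappability denominator t(C) - e(C).
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass

import yaml

from .exceptions import FormatError
from .schema_ingest import PropertyRecord, SchemaTable

RULE_CATEGORIES = ("non_defined", "linking", "framework_specific")


@dataclass(frozen=True)
class ExclusionRule:
    """One exclusion rule.

    ``match`` is an exact property name, a glob pattern (``* ids``), or a
    ``Class.property`` pair (exact class, glob on the property part).
    ``scope`` restricts the rule to one model; ``"any"`` applies always.
    """

    category: str
    match: str
    scope: str = "any"

    def __post_init__(self):
        if self.category not in RULE_CATEGORIES:
            raise FormatError(
                f"unknown rule category {self.category!r}; "
                f"expected one of {RULE_CATEGORIES}"
            )
        if not self.match:
            raise FormatError("exclusion rule with empty matcher")

    def matches(self, record: PropertyRecord) -> bool:
        if self.scope not in ("any", record.model):
            return False
        if "." in self.match:
            cls, prop = self.match.split(".", 1)
            return record.class_name == cls and fnmatch.fnmatchcase(
                record.property_name, prop
            )
        return fnmatch.fnmatchcase(record.property_name, self.match)


@dataclass(frozen=True)
class FilterOutcome:
    """Disjoint partition of a SchemaTable into included and excluded rows."""

    included: SchemaTable
    excluded: SchemaTable
    e_by_class: dict[str, int]
    rule_hits: dict[ExclusionRule, tuple[tuple[str, str], ...]]

    @property
    def model(self) -> str:
        return self.included.model

    @property
    def t_by_class(self) -> dict[str, int]:
        """Total property count t(C) per class, before exclusion."""
        totals: dict[str, int] = {}
        for table in (self.included, self.excluded):
            for r in table:
                totals[r.class_name] = totals.get(r.class_name, 0) + 1
        return totals


def apply_exclusion_rules(
    table: SchemaTable, rules: list[ExclusionRule]
) -> FilterOutcome:
    """Partition ``table`` by the first matching rule (rule order decides
    which rule is credited; the partition itself is order-independent)."""
    for rule in rules:
        if rule.scope not in ("any", table.model):
            warnings.warn(
                f"rule {rule.category}/{rule.match!r} is scoped to model "
                f"{rule.scope!r}, absent from table {table.model!r}",
                stacklevel=2,
            )
    included, excluded = [], []
    hits: dict[ExclusionRule, list[tuple[str, str]]] = {}
    e_by_class = {c: 0 for c in table.classes}
    for record in table:
        winner = next((r for r in rules if r.matches(record)), None)
        if winner is None:
            included.append(record)
        else:
            excluded.append(record)
            e_by_class[record.class_name] += 1
            hits.setdefault(winner, []).append(
                (record.class_name, record.property_name)
            )
    return FilterOutcome(
        included=table.subset(included),
        excluded=table.subset(excluded),
        e_by_class=e_by_class,
        rule_hits={r: tuple(v) for r, v in hits.items()},
    )


def load_ruleset(path) -> list[ExclusionRule]:
    """Read a ruleset YAML: a list of {category, match, scope} entries."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or []
    if not isinstance(doc, list):
        raise FormatError(f"{path}: ruleset must be a YAML list of rules")
    rules = []
    for i, entry in enumerate(doc):
        if not isinstance(entry, dict) or "category" not in entry or "match" not in entry:
            raise FormatError(
                f"{path}: rule #{i} must be a mapping with 'category' and 'match'"
            )
        rules.append(
            ExclusionRule(
                category=str(entry["category"]),
                match=str(entry["match"]),
                scope=str(entry.get("scope", "any")),
            )
        )
    return rules
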