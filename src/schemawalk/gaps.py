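"""Information-gap identification via cross-mapping of unmapped properties.

Backward crosswalks (related models -> source model) leave a residue of
related-model properties with no counterpart in the source.  These are
cross-mapped *among* the related models; connected groups of such
properties form *information complexes* — coherent types of information
the source model does not capture.  A complex spanning many models whose
members are all required would indicate a serious gap; singleton
complexes are model idiosyncrasies.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .crosswalk import MappingSet, PropertyRef
from .exceptions import IntegrityError
from .rules_filter import FilterOutcome


@dataclass(frozen=True)
class UnmappedProperties:
    """Included related-model properties with no match into the source."""

    properties: tuple[PropertyRef, ...]
    by_model: dict[str, int]
    n_analyzed: int
    requirement_of: dict[PropertyRef, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties)


@dataclass(frozen=True)
class GapComplex:
    """A connected group of unmapped properties (one information type)."""

    id: str
    members: tuple[tuple[PropertyRef, str], ...]  # (ref, requirement)
    label: str
    self_referential: tuple[PropertyRef, ...] = ()

    def __post_init__(self):
        if not self.members:
            raise IntegrityError("empty gap complex")

    @property
    def span(self) -> int:
        """Distinct models among the members."""
        return len({ref.model for ref, _ in self.members})

    @property
    def all_required(self) -> bool:
        """True iff every member with a specified requirement is required."""
        return all(
            req == "required"
            for _, req in self.members
            if req != "unspecified"
        )


def collect_unmapped(
    backward_sets: list[MappingSet],
    filters: dict[str, FilterOutcome],
) -> UnmappedProperties:
    """Collect included related-model properties whose records are all
    noMatch.  A property with both a match and a noMatch record is
    treated as mapped (with an integrity warning); an included property
    with no record at all is treated as unmapped (with a warning)."""
    unmapped: list[PropertyRef] = []
    by_model: dict[str, int] = {}
    req_of: dict[PropertyRef, str] = {}
    n_analyzed = 0
    for mset in backward_sets:
        model = mset.source_model
        if model not in filters:
            raise IntegrityError(f"no filter outcome for model {model!r}")
        matched = {r.subject for r in mset if r.is_match}
        nomatched = {r.subject for r in mset if not r.is_match}
        both = matched & nomatched
        if both:
            warnings.warn(
                f"{model}: properties with both match and noMatch records "
                f"treated as mapped: {sorted(p.curie() for p in both)[:5]}",
                stacklevel=2,
            )
        covered = matched | nomatched
        count = 0
        for rec in filters[model].included:
            ref = PropertyRef(rec.model, rec.class_name, rec.property_name)
            n_analyzed += 1
            if ref in matched:
                continue
            if ref not in covered:
                warnings.warn(
                    f"{model}: included property {ref.curie()} has no mapping "
                    f"record; treated as unmapped",
                    stacklevel=2,
                )
            unmapped.append(ref)
            req_of[ref] = rec.requirement
            count += 1
        by_model[model] = count
    return UnmappedProperties(
        properties=tuple(unmapped),
        by_model=by_model,
        n_analyzed=n_analyzed,
        requirement_of=req_of,
    )


def build_complexes(
    unmapped: UnmappedProperties, cross_set: MappingSet
) -> list[GapComplex]:
    """Group unmapped properties into connected components of the
    cross-mapping graph.

    Edges are non-noMatch cross-mapping records; self-referential
    mappings are recorded but never create edges, so a member connected
    to only one other member still joins the whole component (transitive
    closure, not clique).  Properties untouched by any record form
    singleton complexes.
    """
    nodes = set(unmapped.properties)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    self_refs: set[PropertyRef] = set()
    labels: dict[PropertyRef, str] = {}
    for rec in cross_set:
        if not rec.is_match:
            continue
        for ref in (rec.subject, rec.object):
            if ref not in nodes:
                raise IntegrityError(
                    f"cross-mapping record touches a property outside the "
                    f"unmapped set: {ref.curie()}"
                )
        if rec.subject == rec.object:
            self_refs.add(rec.subject)
            continue
        graph.add_edge(rec.subject, rec.object)
        if rec.comment:
            labels.setdefault(rec.subject, rec.comment)
            labels.setdefault(rec.object, rec.comment)
    complexes = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components):
        members = tuple(
            (ref, unmapped.requirement_of.get(ref, "unspecified"))
            for ref in sorted(comp)
        )
        curated = sorted({labels[ref] for ref in comp if ref in labels})
        label = curated[0] if curated else min(r.property_name for r, _ in members)
        complexes.append(
            GapComplex(
                id=f"complex_{i:03d}",
                members=members,
                label=label,
                self_referential=tuple(sorted(r for r in comp if r in self_refs)),
            )
        )
    return complexes


@dataclass(frozen=True)
class GapReport:
    """Membership table, span histogram and the headline boolean."""

    membership: pd.DataFrame
    span_histogram: dict[int, int]
    any_full_span_all_required: bool
    n_complexes: int

    def write_tsv(self, path) -> None:
        self.membership.to_csv(path, sep="\t", index=False)


def summarize_gaps(complexes: list[GapComplex], n_related_models: int = 4) -> GapReport:
    """Per-complex membership plus the check whether any complex spans
    every related model with all members required."""
    rows = []
    for cx in complexes:
        for ref, req in cx.members:
            rows.append(
                {
                    "complex": cx.id,
                    "label": cx.label,
                    "span": cx.span,
                    "all_required": cx.all_required,
                    "model": ref.model,
                    "class": ref.class_name,
                    "property": ref.property_name,
                    "requirement": req,
                }
            )
    membership = pd.DataFrame(
        rows,
        columns=[
            "complex",
            "label",
            "span",
            "all_required",
            "model",
            "class",
            "property",
            "requirement",
        ],
    )
    span_hist = dict(Counter(cx.span for cx in complexes))
    return GapReport(
        membership=membership,
        span_histogram=span_hist,
        any_full_span_all_required=any(
            cx.span == n_related_models and cx.all_required for cx in complexes
        ),
        n_complexes=len(complexes),
    )
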