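"""Synthetic schema ensembles with ground-truth crosswalks.

Several metadata models are generated from a shared latent pool of
*information concepts*: each model includes a concept with a per-model
sharing probability and renders it as one property in one of its
classes, optionally under a model-specific lexical variant of the
concept name (so lexical vs background-knowledge justifications occur).
Excluded-category properties (aliases, catch-all attributes, archive
accessions) are injected per class and are matched by the default
synthetic ruleset.  Curated mapping sets are derived from the latent
structure: a match record for every concept shared between source and
target (minus a configurable curation dropout), an explicit noMatch row
otherwise, and a cross-mapping set linking related-model properties
whose concept is absent from the source model.

Because the generator knows the latent concepts, every pipeline stage
has an exact recovery target: consensus detection must return the
concepts planted in enough targets, and gap complexes must equal the
concept groupings of the unmapped properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coverage import STANDARD_CLASSES, StandardClassMap
from .crosswalk import MappingRecord, MappingSet, PropertyRef
from .exceptions import ConfigError
from .rules_filter import ExclusionRule
from .schema_ingest import PropertyRecord, SchemaTable

#: canonical excluded-category property names, matched by the default ruleset
EXCLUDED_NAMES = (
    ("alias", "linking", "required"),
    ("attributes", "non_defined", "unspecified"),
    ("ega accession", "framework_specific", "optional"),
)

DEFAULT_REQUIREMENT_DISTRIBUTION = {
    "required": 0.45,
    "recommended": 0.20,
    "optional": 0.25,
    "unspecified": 0.10,
}
DEFAULT_RANGE_KIND_DISTRIBUTION = {
    "controlled_vocabulary": 0.25,
    "ontology": 0.10,
    "pattern": 0.05,
    "boolean": 0.05,
    "integer": 0.05,
    "free_text": 0.40,
    "not_controllable": 0.05,
    "unspecified": 0.05,
}
DEFAULT_PREDICATE_DISTRIBUTION = {
    "exactMatch": 0.70,
    "closeMatch": 0.20,
    "broadMatch": 0.05,
    "narrowMatch": 0.05,
}


def _check_distribution(name: str, dist: dict) -> None:
    if any(not 0.0 <= p <= 1.0 for p in dist.values()):
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
        raise ConfigError(f"{name}: probabilities must sum to 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; identical seed + config => identical ensemble."""

    seed: int = 0
    n_models: int = 5
    concept_pool_size: int = 120
    classes_per_model: tuple[int, int] = (8, 12)
    #: scalar, or one probability per model (source model first)
    sharing_probability: float | tuple[float, ...] = 0.55
    requirement_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REQUIREMENT_DISTRIBUTION)
    )
    range_kind_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_KIND_DISTRIBUTION)
    )
    excluded_injection_rate: float = 0.25
    predicate_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREDICATE_DISTRIBUTION)
    )
    #: probability a true correspondence is curated as noMatch; scalar or
    #: per-model dict keyed by the subject's model
    dropout_rate: float | dict[str, float] = 0.05
    #: probability a concept gets a model-specific lexical variant name
    lexical_variant_rate: float = 0.3

    def __post_init__(self):
        if self.n_models < 2:
            raise ConfigError("need at least 2 models")
        lo, hi = self.classes_per_model
        if not 1 <= lo <= hi:
            raise ConfigError(f"invalid classes_per_model range {self.classes_per_model}")
        if self.concept_pool_size < hi:
            raise ConfigError(
                f"concept_pool_size {self.concept_pool_size} smaller than the "
                f"number of classes demanded ({hi})"
            )
        _check_distribution("requirement_distribution", self.requirement_distribution)
        _check_distribution("range_kind_distribution", self.range_kind_distribution)
        _check_distribution("predicate_distribution", self.predicate_distribution)
        for p in self.sharing_per_model() + tuple(self._dropout_values()):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.excluded_injection_rate <= 1.0:
            raise ConfigError("excluded_injection_rate outside [0, 1]")
        if not 0.0 <= self.lexical_variant_rate <= 1.0:
            raise ConfigError("lexical_variant_rate outside [0, 1]")

    @property
    def models(self) -> tuple[str, ...]:
        return tuple(f"model{i}" for i in range(self.n_models))

    @property
    def source_model(self) -> str:
        return self.models[0]

    def sharing_per_model(self) -> tuple[float, ...]:
        if isinstance(self.sharing_probability, (int, float)):
            return (float(self.sharing_probability),) * self.n_models
        probs = tuple(float(p) for p in self.sharing_probability)
        if len(probs) != self.n_models:
            raise ConfigError(
                f"sharing_probability needs {self.n_models} entries, got {len(probs)}"
            )
        return probs

    def _dropout_values(self):
        if isinstance(self.dropout_rate, dict):
            return tuple(float(v) for v in self.dropout_rate.values())
        return (float(self.dropout_rate),)

    def dropout_for(self, model: str) -> float:
        if isinstance(self.dropout_rate, dict):
            return float(self.dropout_rate.get(model, 0.0))
        return float(self.dropout_rate)


@dataclass(frozen=True)
class GroundTruth:
    """Latent concept assignments behind a generated ensemble."""

    source_model: str
    related_models: tuple[str, ...]
    concept_of: dict[PropertyRef, int]
    #: concept -> models containing it
    incidence: dict[int, frozenset[str]]
    #: (model, concept) -> the property rendering that concept
    prop_of: dict[tuple[str, int], PropertyRef]


@dataclass(frozen=True)
class SyntheticEnsemble:
    config: SyntheticConfig
    tables: dict[str, SchemaTable]
    forward_sets: dict[str, MappingSet]  # keyed by target model
    backward_sets: dict[str, MappingSet]  # keyed by related model
    cross_set: MappingSet
    truth: GroundTruth


def default_synthetic_ruleset() -> list[ExclusionRule]:
    """Rules matching exactly the injected excluded-category properties."""
    return [
        ExclusionRule(category=cat, match=name)
        for name, cat, _ in EXCLUDED_NAMES
    ]


def _sample(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    return keys[rng.choice(len(keys), p=[dist[k] for k in keys])]


def generate_ensemble(config: SyntheticConfig) -> SyntheticEnsemble:
    """Generate schema tables, mapping sets and ground truth from one
    explicitly seeded pseudo-random stream."""
    rng = np.random.default_rng(config.seed)
    models = config.models
    sharing = config.sharing_per_model()
    lo, hi = config.classes_per_model

    concept_of: dict[PropertyRef, int] = {}
    prop_of: dict[tuple[str, int], PropertyRef] = {}
    incidence: dict[int, set[str]] = {c: set() for c in range(config.concept_pool_size)}
    tables: dict[str, SchemaTable] = {}

    for idx, model in enumerate(models):
        n_classes = int(rng.integers(lo, hi + 1))
        classes = [f"Entity{k:02d}" for k in range(n_classes)]
        records: list[PropertyRecord] = []
        for c in range(config.concept_pool_size):
            if rng.random() >= sharing[idx]:
                continue
            cls = classes[int(rng.integers(n_classes))]
            base = f"concept {c:03d}"
            if rng.random() < config.lexical_variant_rate:
                name = f"{base} ({model} term)"
            else:
                name = base
            ref = PropertyRef(model, cls, name)
            concept_of[ref] = c
            prop_of[(model, c)] = ref
            incidence[c].add(model)
            records.append(
                PropertyRecord(
                    model=model,
                    class_name=cls,
                    property_name=name,
                    description=f"information concept {c}",
                    requirement=_sample(rng, config.requirement_distribution),
                    range_kind=_sample(rng, config.range_kind_distribution),
                )
            )
        for cls in classes:
            for name, _cat, req in EXCLUDED_NAMES:
                if rng.random() < config.excluded_injection_rate:
                    records.append(
                        PropertyRecord(
                            model=model,
                            class_name=cls,
                            property_name=name,
                            description="model-mechanics property",
                            requirement=req,
                            range_kind="free_text",
                        )
                    )
        tables[model] = SchemaTable(
            model=model,
            records=tuple(records),
            provenance=f"synthetic seed={config.seed}",
        )

    truth = GroundTruth(
        source_model=config.source_model,
        related_models=models[1:],
        concept_of=concept_of,
        incidence={c: frozenset(m) for c, m in incidence.items()},
        prop_of=prop_of,
    )

    def curate(src: str, tgt: str, direction: str) -> MappingSet:
        dropout = config.dropout_for(src)
        records = []
        for c in range(config.concept_pool_size):
            subj = prop_of.get((src, c))
            if subj is None:
                continue
            obj = prop_of.get((tgt, c))
            if obj is None or rng.random() < dropout:
                records.append(
                    MappingRecord(subject=subj, object=None, predicate="noMatch")
                )
                continue
            records.append(
                MappingRecord(
                    subject=subj,
                    object=obj,
                    predicate=_sample(rng, config.predicate_distribution),
                    justification=(
                        "lexicalMatch"
                        if subj.property_name == obj.property_name
                        else "background_knowledge"
                    ),
                )
            )
        return MappingSet(
            source_model=src,
            target_model=tgt,
            direction=direction,
            records=tuple(records),
            provenance=f"synthetic seed={config.seed}",
        )

    forward_sets = {t: curate(config.source_model, t, "forward") for t in models[1:]}
    backward_sets = {m: curate(m, config.source_model, "backward") for m in models[1:]}

    cross_records = []
    for c in range(config.concept_pool_size):
        if config.source_model in incidence[c]:
            continue
        group = [prop_of[(m, c)] for m in models[1:] if m in incidence[c]]
        for a, b in zip(group, group[1:]):
            cross_records.append(
                MappingRecord(
                    subject=a,
                    object=b,
                    predicate="closeMatch",
                    justification="background_knowledge",
                    comment=f"concept {c:03d}",
                )
            )
    cross_set = MappingSet(
        source_model="*",
        target_model="*",
        direction="cross",
        records=tuple(cross_records),
        provenance=f"synthetic seed={config.seed}",
    )
    return SyntheticEnsemble(
        config=config,
        tables=tables,
        forward_sets=forward_sets,
        backward_sets=backward_sets,
        cross_set=cross_set,
        truth=truth,
    )


def expected_consensus(truth: GroundTruth, threshold: int) -> frozenset[PropertyRef]:
    """Consensus set implied by the latent concept incidence, ignoring
    curation dropout: source properties whose concept is present in at
    least ``threshold`` related models."""
    out = []
    for (model, c), ref in truth.prop_of.items():
        if model != truth.source_model:
            continue
        n_related = len(truth.incidence[c] & set(truth.related_models))
        if n_related >= threshold:
            out.append(ref)
    return frozenset(out)


def expected_gap_groups(truth: GroundTruth) -> dict[int, frozenset[PropertyRef]]:
    """Ground-truth information complexes: related-model properties whose
    concept is absent from the source model, grouped by concept."""
    groups: dict[int, frozenset[PropertyRef]] = {}
    for c, present in truth.incidence.items():
        if truth.source_model in present or not present:
            continue
        groups[c] = frozenset(
            truth.prop_of[(m, c)] for m in present
        )
    return groups


def synthetic_standard_class_map(tables: dict[str, SchemaTable]) -> StandardClassMap:
    """Round-robin assignment of each model's classes to the four
    standard classes, so the Kruskal-Wallis comparison is exercisable on
    synthetic ensembles."""
    assignments: dict[str, list[tuple[str, str]]] = {s: [] for s in STANDARD_CLASSES}
    for model in sorted(tables):
        for j, cls in enumerate(sorted(tables[model].classes)):
            assignments[STANDARD_CLASSES[j % len(STANDARD_CLASSES)]].append((model, cls))
    return StandardClassMap(
        assignments={s: tuple(v) for s, v in assignments.items()}
    )


def reference_scenario_config(seed: int) -> SyntheticConfig:
    """A study-scale scenario: one richly populated source model mapped
    against four related models that share comparable fractions of the
    concept pool (homogeneous forward mappability) but differ strongly in
    how completely their own concepts are curated into the source
    (heterogeneous backward mappability, mean coverages ~0.97/0.79/0.71/0.40)."""
    return SyntheticConfig(
        seed=seed,
        n_models=5,
        concept_pool_size=120,
        classes_per_model=(8, 12),
        sharing_probability=(1.0, 0.45, 0.45, 0.45, 0.45),
        dropout_rate={
            "model0": 0.0,
            "model1": 0.03,
            "model2": 0.21,
            "model3": 0.29,
            "model4": 0.60,
        },
    )
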