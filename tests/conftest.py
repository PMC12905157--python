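import pytest

from schemawalk import (
    ExclusionRule,
    PropertyRecord,
    SchemaTable,
    SyntheticConfig,
    apply_exclusion_rules,
    generate_ensemble,
)


def make_table(model, triples, **kwargs):
    """Build a SchemaTable from (class, property[, requirement]) triples."""
    records = []
    for t in triples:
        cls, prop = t[0], t[1]
        req = t[2] if len(t) > 2 else "unspecified"
        records.append(
            PropertyRecord(
                model=model, class_name=cls, property_name=prop, requirement=req
            )
        )
    return SchemaTable(model=model, records=tuple(records), **kwargs)


@pytest.fixture
def toy_table():
    return make_table(
        "ghga",
        [
            ("Study", "title", "required"),
            ("Study", "alias", "required"),
            ("Study", "attributes"),
            ("Sample", "name", "required"),
            ("Sample", "alias", "required"),
        ],
    )


@pytest.fixture
def default_rules():
    return [
        ExclusionRule(category="linking", match="alias"),
        ExclusionRule(category="non_defined", match="attributes"),
    ]


@pytest.fixture
def small_ensemble():
    """A compact deterministic ensemble used across modules."""
    return generate_ensemble(
        SyntheticConfig(
            seed=11, n_models=4, concept_pool_size=40, classes_per_model=(3, 5)
        )
    )


def filtered(ensemble):
    from schemawalk import default_synthetic_ruleset

    rules = default_synthetic_ruleset()
    return {m: apply_exclusion_rules(t, rules) for m, t in ensemble.tables.items()}
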