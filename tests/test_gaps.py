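"""Information-gap complexes: unmapped collection and graph grouping."""

import itertools

import pytest

from schemawalk import (
    IntegrityError,
    MappingSet,
    SyntheticConfig,
    build_complexes,
    collect_unmapped,
    generate_ensemble,
    summarize_gaps,
)
from schemawalk.crosswalk import MappingRecord, PropertyRef
from schemawalk.gaps import UnmappedProperties

from conftest import filtered


def ref(model, prop, cls="C"):
    return PropertyRef(model=model, class_name=cls, property_name=prop)


def edge(a, b, comment=""):
    return MappingRecord(
        subject=a, object=b, predicate="closeMatch",
        justification="background_knowledge", comment=comment,
    )


def cross(records):
    return MappingSet("*", "*", "cross", tuple(records))


def unmapped_of(refs, requirements=None):
    return UnmappedProperties(
        properties=tuple(refs),
        by_model={},
        n_analyzed=len(refs),
        requirement_of=requirements or {},
    )


class TestCollectUnmapped:
    def test_no_nomatch_rows_gives_empty_list(self):
        ens = generate_ensemble(
            SyntheticConfig(
                seed=5, n_models=3, sharing_probability=1.0, dropout_rate=0.0,
                concept_pool_size=15, classes_per_model=(2, 3),
            )
        )
        flt = filtered(ens)
        out = collect_unmapped(list(ens.backward_sets.values()), flt)
        assert len(out) == 0

    def test_counts_against_ground_truth(self):
        # at zero dropout the unmapped set is exactly the concepts absent
        # from the source model
        ens = generate_ensemble(
            SyntheticConfig(seed=13, n_models=4, dropout_rate=0.0, concept_pool_size=30, classes_per_model=(3, 4))
        )
        flt = filtered(ens)
        out = collect_unmapped(list(ens.backward_sets.values()), flt)
        truth_unmapped = {
            r
            for r, c in ens.truth.concept_of.items()
            if r.model != ens.config.source_model
            and ens.config.source_model not in ens.truth.incidence[c]
        }
        assert set(out.properties) == truth_unmapped

    def test_mixed_match_and_nomatch_treated_as_mapped(self):
        a = ref("m1", "x")
        mset = MappingSet(
            "m1",
            "m0",
            "backward",
            (
                MappingRecord(subject=a, object=ref("m0", "y"), predicate="exactMatch"),
                MappingRecord(subject=a, object=None, predicate="noMatch"),
            ),
        )
        from conftest import make_table
        from schemawalk import apply_exclusion_rules

        flt = {"m1": apply_exclusion_rules(make_table("m1", [("C", "x")]), [])}
        with pytest.warns(UserWarning, match="both match and noMatch"):
            out = collect_unmapped([mset], flt)
        assert len(out) == 0


class TestBuildComplexes:
    def test_no_cross_records_gives_singletons(self):
        refs = [ref("m1", "a"), ref("m2", "b"), ref("m3", "c")]
        complexes = build_complexes(unmapped_of(refs), cross([]))
        assert len(complexes) == 3
        assert all(cx.span == 1 for cx in complexes)

    def test_chain_forms_one_complex_without_full_clique(self):
        # A-B and B-C connect A, B, C even though A-C is absent
        a, b, c = ref("m1", "a"), ref("m2", "b"), ref("m3", "c")
        complexes = build_complexes(unmapped_of([a, b, c]), cross([edge(a, b), edge(b, c)]))
        assert len(complexes) == 1
        assert complexes[0].span == 3
        assert {r for r, _ in complexes[0].members} == {a, b, c}

    def test_self_loops_never_create_edges(self):
        a, b = ref("m1", "a"), ref("m2", "b")
        complexes = build_complexes(unmapped_of([a, b]), cross([edge(a, a)]))
        assert len(complexes) == 2
        flagged = [cx for cx in complexes if cx.self_referential]
        assert len(flagged) == 1 and flagged[0].self_referential == (a,)

    def test_record_touching_mapped_property_is_error(self):
        a, b = ref("m1", "a"), ref("m2", "b")
        with pytest.raises(IntegrityError, match="outside the"):
            build_complexes(unmapped_of([a]), cross([edge(a, b)]))

    def test_agrees_with_brute_force_transitive_closure(self):
        # oracle: repeated pairwise merging of overlapping groups
        import random

        rng = random.Random(0)
        for trial in range(20):
            n = rng.randrange(5, 31)
            nodes = [ref(f"m{idx % 4}", f"p{idx}") for idx in range(n)]
            edges = [
                tuple(rng.sample(range(n), 2)) for _ in range(rng.randrange(0, n))
            ]
            complexes = build_complexes(
                unmapped_of(nodes), cross([edge(nodes[i], nodes[j]) for i, j in edges])
            )
            groups = [{i} for i in range(n)]
            for i, j in edges:
                gi = next(g for g in groups if i in g)
                gj = next(g for g in groups if j in g)
                if gi is not gj:
                    groups.remove(gi)
                    groups.remove(gj)
                    groups.append(gi | gj)
            expected = {frozenset(nodes[i] for i in g) for g in groups}
            got = {frozenset(r for r, _ in cx.members) for cx in complexes}
            assert got == expected

    def test_partition_and_edge_monotonicity(self):
        nodes = [ref(f"m{i % 3}", f"p{i}") for i in range(6)]
        base_edges = [edge(nodes[0], nodes[1]), edge(nodes[2], nodes[3])]
        base = build_complexes(unmapped_of(nodes), cross(base_edges))
        assert sorted(r for cx in base for r, _ in cx.members) == sorted(nodes)
        more = build_complexes(
            unmapped_of(nodes), cross(base_edges + [edge(nodes[1], nodes[2])])
        )
        assert len(more) <= len(base)

    def test_curated_label_and_auto_label(self):
        a, b = ref("m1", "zzz"), ref("m2", "aaa")
        labelled = build_complexes(
            unmapped_of([a, b]), cross([edge(a, b, comment="sampling time")])
        )
        assert labelled[0].label == "sampling time"
        auto = build_complexes(unmapped_of([a, b]), cross([edge(a, b)]))
        assert auto[0].label == "aaa"  # lexicographically first member


class TestSummarize:
    def test_empty_input(self):
        report = summarize_gaps([])
        assert report.n_complexes == 0
        assert report.span_histogram == {}
        assert not report.any_full_span_all_required

    def test_all_required_logic(self):
        a, b = ref("m1", "a"), ref("m2", "b")
        reqs = {a: "required", b: "optional"}
        complexes = build_complexes(unmapped_of([a, b], reqs), cross([edge(a, b)]))
        assert not complexes[0].all_required
        reqs_required = {a: "required", b: "unspecified"}
        complexes = build_complexes(
            unmapped_of([a, b], reqs_required), cross([edge(a, b)])
        )
        # only members with a specified requirement count
        assert complexes[0].all_required

    def test_span_histogram_and_global_boolean(self):
        n_models = 4
        nodes = [ref(f"m{i}", f"p{i}") for i in range(n_models)]
        reqs = {r: "required" for r in nodes}
        chain = [edge(x, y) for x, y in itertools.pairwise(nodes)]
        complexes = build_complexes(unmapped_of(nodes, reqs), cross(chain))
        report = summarize_gaps(complexes, n_related_models=n_models)
        assert report.span_histogram == {n_models: 1}
        assert report.any_full_span_all_required

    def test_recovery_against_ground_truth(self):
        from schemawalk import expected_gap_groups

        for seed in range(1, 11):
            ens = generate_ensemble(
                SyntheticConfig(seed=seed, n_models=4, dropout_rate=0.0, concept_pool_size=25, classes_per_model=(2, 4))
            )
            flt = filtered(ens)
            unmapped = collect_unmapped(list(ens.backward_sets.values()), flt)
            complexes = build_complexes(unmapped, ens.cross_set)
            got = {frozenset(r for r, _ in cx.members) for cx in complexes}
            expected = set(expected_gap_groups(ens.truth).values())
            assert got == expected
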