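"""SSSOM mapping sets: parsing, round trips, dedup and validation."""

import random

import pytest

from schemawalk import (
    IntegrityError,
    MappingRecord,
    MappingSet,
    ParseError,
    PropertyRef,
    VocabularyError,
    apply_exclusion_rules,
    mapped_property_set,
    read_sssom,
    validate_mapping_set,
    write_sssom,
)

from conftest import make_table


def ref(model, cls, prop):
    return PropertyRef(model=model, class_name=cls, property_name=prop)


def match(s, o, predicate="exactMatch", justification="lexicalMatch", comment=""):
    return MappingRecord(
        subject=s, object=o, predicate=predicate, justification=justification, comment=comment
    )


def nomatch(s):
    return MappingRecord(subject=s, object=None, predicate="noMatch")


class TestParsing:
    def test_empty_mapping_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(
            "#source_model: a\n#target_model: b\n#direction: forward\n"
            "subject_id\tpredicate_id\tobject_id\tmapping_justification\tcomment\n"
        )
        mset = read_sssom(p)
        assert len(mset) == 0
        assert (mset.source_model, mset.target_model, mset.direction) == ("a", "b", "forward")

    def test_one_exact_match_row(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text(
            "#source_model: GHGA\n#target_model: EGA\n#direction: forward\n"
            "subject_id\tpredicate_id\tobject_id\tmapping_justification\n"
            "GHGA:Study.title\tskos:exactMatch\tEGA:Study.title\tsemapv:LexicalMatching\n"
        )
        mset = read_sssom(p)
        assert len(mset) == 1
        rec = mset.records[0]
        assert rec.predicate == "exactMatch"
        assert rec.justification == "lexicalMatch"
        assert rec.subject == ref("GHGA", "Study", "title")
        assert rec.object == ref("EGA", "Study", "title")

    def test_shorthand_justifications_normalized(self, tmp_path):
        p = tmp_path / "short.tsv"
        p.write_text(
            "#source_model: a\n#target_model: b\n#direction: forward\n"
            "subject_id\tpredicate_id\tobject_id\tmapping_justification\n"
            "a:C.x\tcloseMatch\tb:C.y\tBKBM\n"
            "a:C.z\tnoMatch\tsssom:NoTermFound\tnone\n"
        )
        mset = read_sssom(p)
        assert mset.records[0].justification == "background_knowledge"
        assert mset.records[1].object is None

    def test_unknown_predicate_is_vocabulary_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#source_model: a\n#target_model: b\n#direction: forward\n"
            "subject_id\tpredicate_id\tobject_id\tmapping_justification\n"
            "a:C.x\tskos:related\tb:C.y\tnone\n"
        )
        with pytest.raises(VocabularyError, match="related"):
            read_sssom(p)

    def test_malformed_id_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#source_model: a\n#target_model: b\n#direction: forward\n"
            "subject_id\tpredicate_id\tobject_id\tmapping_justification\n"
            "noseparator\tskos:exactMatch\tb:C.y\tnone\n"
        )
        with pytest.raises(ParseError, match="line 5"):
            read_sssom(p)


class TestRecordInvariants:
    def test_nomatch_requires_sentinel_object(self):
        with pytest.raises(IntegrityError):
            MappingRecord(subject=ref("a", "C", "x"), object=None, predicate="exactMatch")
        with pytest.raises(IntegrityError):
            MappingRecord(
                subject=ref("a", "C", "x"), object=ref("b", "C", "y"), predicate="noMatch"
            )

    def test_nomatch_justification_must_be_none(self):
        with pytest.raises(IntegrityError):
            MappingRecord(
                subject=ref("a", "C", "x"),
                object=None,
                predicate="noMatch",
                justification="lexicalMatch",
            )

    def test_set_rejects_foreign_subjects(self):
        with pytest.raises(IntegrityError):
            MappingSet(
                source_model="a",
                target_model="b",
                direction="forward",
                records=(match(ref("zzz", "C", "x"), ref("b", "C", "y")),),
            )


class TestRoundTrip:
    def random_set(self, n=50, seed=4):
        rng = random.Random(seed)
        records = []
        for i in range(n):
            s = ref("a", f"C{rng.randrange(4)}", f"prop {i}")
            if rng.random() < 0.2:
                records.append(nomatch(s))
            else:
                records.append(
                    match(
                        s,
                        ref("b", f"K{rng.randrange(3)}", f"field {rng.randrange(40)}"),
                        predicate=rng.choice(
                            ["exactMatch", "closeMatch", "broadMatch", "narrowMatch"]
                        ),
                        justification=rng.choice(["lexicalMatch", "background_knowledge"]),
                        comment=rng.choice(["", "curator note"]),
                    )
                )
        return MappingSet(
            source_model="a", target_model="b", direction="forward", records=tuple(records)
        )

    def test_write_read_identical_records(self, tmp_path):
        mset = self.random_set()
        p = tmp_path / "set.tsv"
        write_sssom(mset, p)
        back = read_sssom(p)
        assert back.records == mset.records
        assert (back.source_model, back.target_model, back.direction) == ("a", "b", "forward")

    def test_round_trip_byte_stable(self, tmp_path):
        mset = self.random_set(seed=9)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sssom(mset, p1)
        write_sssom(read_sssom(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestMappedPropertySet:
    def test_predicate_precedence_picks_exact(self):
        s = ref("a", "C", "x")
        mset = MappingSet(
            source_model="a",
            target_model="b",
            direction="forward",
            records=(
                match(s, ref("b", "C", "y"), predicate="closeMatch"),
                match(s, ref("b", "C", "z"), predicate="exactMatch"),
            ),
        )
        out = mapped_property_set(mset)
        assert out.subjects == frozenset({s})
        assert out.representatives[s].predicate == "exactMatch"

    def test_representative_stable_under_reordering(self):
        s = ref("a", "C", "x")
        recs = [
            match(s, ref("b", "C", "m"), predicate="exactMatch"),
            match(s, ref("b", "C", "k"), predicate="exactMatch"),
            match(s, ref("b", "C", "z"), predicate="closeMatch"),
        ]
        reps = set()
        for order in (recs, recs[::-1], [recs[1], recs[2], recs[0]]):
            mset = MappingSet("a", "b", "forward", tuple(order))
            reps.add(mapped_property_set(mset).representatives[s].object.curie())
        assert reps == {"b:C.k"}

    def test_only_nomatch_gives_empty_result(self):
        mset = MappingSet(
            "a", "b", "forward", (nomatch(ref("a", "C", "x")), nomatch(ref("a", "C", "y")))
        )
        assert mapped_property_set(mset).subjects == frozenset()

    def test_counting_identity(self, small_ensemble):
        # |mapped| + |noMatch-only subjects| = covered source properties
        for mset in small_ensemble.forward_sets.values():
            mapped = mapped_property_set(mset).subjects
            nomatch_only = {
                r.subject for r in mset if not r.is_match
            } - mapped
            assert len(mapped) + len(nomatch_only) == len(mset.subjects)


class TestValidation:
    def build(self):
        src = make_table("a", [("C", "x"), ("C", "alias"), ("C", "y")])
        tgt = make_table("b", [("K", "z"), ("K", "alias")])
        from schemawalk import ExclusionRule

        rules = [ExclusionRule(category="linking", match="alias")]
        return apply_exclusion_rules(src, rules), apply_exclusion_rules(tgt, rules)

    def test_clean_set_gives_empty_report(self):
        sf, tf = self.build()
        mset = MappingSet(
            "a",
            "b",
            "forward",
            (match(ref("a", "C", "x"), ref("b", "K", "z")), nomatch(ref("a", "C", "y"))),
        )
        assert validate_mapping_set(mset, sf, tf).ok

    def test_excluded_target_flagged(self):
        sf, tf = self.build()
        mset = MappingSet(
            "a",
            "b",
            "forward",
            (
                match(ref("a", "C", "x"), ref("b", "K", "alias")),
                nomatch(ref("a", "C", "y")),
            ),
        )
        report = validate_mapping_set(mset, sf, tf)
        assert report.excluded_objects == (ref("b", "K", "alias"),)

    def test_class_level_object_flagged(self):
        sf, tf = self.build()
        mset = MappingSet(
            "a",
            "b",
            "forward",
            (
                match(ref("a", "C", "x"), ref("b", "K", "")),
                nomatch(ref("a", "C", "y")),
            ),
        )
        report = validate_mapping_set(mset, sf, tf)
        assert report.class_level_objects == (ref("b", "K", ""),)

    def test_uncovered_source_property_flagged(self):
        sf, tf = self.build()
        mset = MappingSet("a", "b", "forward", (nomatch(ref("a", "C", "y")),))
        report = validate_mapping_set(mset, sf, tf)
        assert ref("a", "C", "x") in report.uncovered_source_properties
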