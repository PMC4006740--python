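"""Filter cascade semantics, predictor consensus, and the audit report."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdmap.cascade import (
    Candidate,
    CandidateSet,
    CascadeReport,
    PredictorRule,
    annotate,
    control_filter,
    cross_family_intersection,
    effect_filter,
    frequency_filter,
    predictor_consensus,
    proband_homozygous_filter,
    region_filter,
    trio_ibd_filter,
)
from ibdmap.pedigree import Trio
from ibdmap.variantstore import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotatedVariant,
    ExclusionDatabase,
    GenotypeMatrix,
    VariantKey,
)


def _matrix(rows, samples=("kid", "dad", "mom")):
    keys = [VariantKey("1", 100 + i, "A", "G") for i in range(len(rows))]
    return GenotypeMatrix(keys, list(samples), np.array(rows, dtype="int8"))


TRIO = Trio("kid", "dad", "mom")


class TestGenotypeFilters:
    @pytest.mark.parametrize(
        "states,kept",
        [
            ((HOM_ALT, HET, HET), True),  # the defining recessive pattern
            ((HOM_ALT, HOM_ALT, HET), False),
            ((HET, HET, HET), False),
            ((HOM_ALT, MISSING, HET), False),  # missing disqualifies
        ],
    )
    def test_trio_ibd_pattern(self, states, kept):
        out = trio_ibd_filter(_matrix([states]), TRIO)
        assert (len(out) == 1) is kept

    def test_absent_sample_raises_naming_it(self):
        m = _matrix([(HOM_ALT, HET, HET)], samples=("kid", "dad", "other"))
        with pytest.raises(KeyError, match="mom"):
            trio_ibd_filter(m, TRIO)

    @pytest.mark.parametrize(
        "state,kept", [(HOM_ALT, True), (HET, False), (HOM_REF, False)]
    )
    def test_proband_only_mode(self, state, kept):
        out = proband_homozygous_filter(_matrix([(state, 0, 0)]), "kid")
        assert (len(out) == 1) is kept


def _cands(*specs):
    """specs: (pos, region, effect) or (pos, region, effect, scores)."""
    out = []
    for spec in specs:
        pos, region, effect = spec[:3]
        scores = spec[3] if len(spec) > 3 else {}
        key = VariantKey("1", pos, "A", "G")
        out.append(
            Candidate(
                key,
                AnnotatedVariant(key, f"G{pos}", region, effect, 1, scores),
            )
        )
    return CandidateSet(out)


class TestAnnotationFilters:
    def test_region_filter_keeps_exonic_and_splice(self):
        cs = _cands(
            (1, "exonic", "synonymous"),
            (2, "intronic", "other"),
            (3, "splice", "other"),
        )
        assert [c.key.pos for c in region_filter(cs).variants] == [1, 3]

    def test_effect_filter_keeps_protein_changing_and_splice(self):
        cs = _cands(
            (1, "exonic", "synonymous"),
            (2, "exonic", "stopgain"),
            (3, "exonic", "nonframeshift_indel"),
            (4, "exonic", "frameshift_indel"),
            (5, "splice", "other"),
        )
        assert [c.key.pos for c in effect_filter(cs).variants] == [2, 4, 5]

    def test_frequency_filter_drops_members(self):
        cs = _cands((1, "exonic", "stopgain"), (2, "exonic", "stopgain"))
        db = ExclusionDatabase([VariantKey("1", 1, "A", "G")])
        assert [c.key.pos for c in frequency_filter(cs, db).variants] == [2]
        assert len(frequency_filter(cs, ExclusionDatabase())) == 2  # empty db = identity

    def test_control_filter_symmetric(self):
        cs = _cands((1, "exonic", "stopgain"), (2, "exonic", "stopgain"))
        panel = {VariantKey("1", 2, "A", "G")}
        assert [c.key.pos for c in control_filter(cs, panel).variants] == [1]


class TestIntersection:
    def test_disjoint_sets_empty(self):
        a = _cands((1, "exonic", "stopgain"))
        b = _cands((2, "exonic", "stopgain"))
        assert len(cross_family_intersection(a, b)) == 0

    def test_identical_sets_unchanged(self):
        a = _cands((1, "exonic", "stopgain"), (2, "exonic", "stopgain"))
        out = cross_family_intersection(a, a)
        assert out.keys() == a.keys()


class TestPredictorConsensus:
    def test_unanimous_damaging_scores_prioritize(self):
        # four-tool profile of a convincingly damaging missense variant
        cs = _cands(
            (
                1,
                "exonic",
                "nonsynonymous_SNV",
                {
                    "sift": 0.006,
                    "polyphen2": 0.728,
                    "provean": -4.021,
                    "mutation_taster": "disease_causing",
                },
            )
        )
        (c,) = predictor_consensus(cs).variants
        assert c.damaging_calls == 4 and c.tools_scored == 4
        assert c.prioritized

    def test_no_scores_never_prioritized(self):
        cs = _cands((1, "exonic", "nonsynonymous_SNV", {}))
        (c,) = predictor_consensus(cs).variants
        assert c.damaging_calls == 0 and not c.prioritized

    def test_sift_boundary_is_strict(self):
        cs = _cands((1, "exonic", "nonsynonymous_SNV", {"sift": 0.05}))
        (c,) = predictor_consensus(cs).variants
        assert c.damaging_calls == 0

    def test_ranking_by_damaging_count(self):
        cs = _cands(
            (1, "exonic", "nonsynonymous_SNV", {"sift": 0.5}),
            (2, "exonic", "nonsynonymous_SNV", {"sift": 0.001, "polyphen2": 0.99}),
        )
        out = predictor_consensus(cs)
        assert [c.key.pos for c in out.variants] == [2, 1]

    def test_unknown_tool_name_is_configuration_error(self):
        cs = _cands((1, "exonic", "nonsynonymous_SNV", {"sift": 0.5}))
        rules = {"sifft_typo": PredictorRule("lt", 0.05)}
        with pytest.raises(ValueError, match="sifft_typo"):
            predictor_consensus(cs, rules=rules)

    def test_configurable_k(self):
        cs = _cands(
            (1, "exonic", "nonsynonymous_SNV", {"sift": 0.01, "polyphen2": 0.1})
        )
        assert not predictor_consensus(cs).variants[0].prioritized  # 1 of 2
        assert predictor_consensus(cs, min_damaging=1).variants[0].prioritized


def test_report_arithmetic_enforced():
    rep = CascadeReport()
    rep.record("stage", 5, 3, [VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "A", "G")])
    assert rep.count("stage") == 3
    with pytest.raises(ValueError):
        rep.record("bad", 5, 3, [])


def test_empty_matrix_gives_empty_set():
    m = GenotypeMatrix([], ["kid", "dad", "mom"], np.empty((0, 3), dtype="int8"))
    rep = CascadeReport()
    out = trio_ibd_filter(m, TRIO, rep)
    assert len(out) == 0
    assert rep.rows[0]["n_input"] == 0 and rep.rows[0]["n_output"] == 0


# -- algebraic filter properties -------------------------------------

REGIONS = ["exonic", "splice", "intronic", "UTR", "intergenic", "other"]
EFFECTS = [
    "nonsynonymous_SNV",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "synonymous",
    "other",
]


@st.composite
def candidate_sets(draw):
    n = draw(st.integers(0, 20))
    positions = draw(
        st.lists(st.integers(1, 10_000), min_size=n, max_size=n, unique=True)
    )
    cands = []
    for pos in positions:
        key = VariantKey("7", pos, "A", "G")
        ann = AnnotatedVariant(
            key,
            "G",
            draw(st.sampled_from(REGIONS)),
            draw(st.sampled_from(EFFECTS)),
            1,
        )
        cands.append(Candidate(key, ann))
    db = ExclusionDatabase([c.key for c in cands if draw(st.booleans())])
    return CandidateSet(cands), db


@settings(max_examples=60, derandomize=True)
@given(candidate_sets())
def test_filters_contractive_idempotent_commutative(cs_db):
    cs, db = cs_db
    for f in (region_filter, effect_filter, lambda c: frequency_filter(c, db)):
        once = f(cs)
        assert set(once.keys()) <= set(cs.keys())  # contractive
        assert f(once).keys() == once.keys()  # idempotent
    # frequency and effect filters commute
    a = frequency_filter(effect_filter(cs), db)
    b = effect_filter(frequency_filter(cs, db))
    assert a.keys() == b.keys()
    # region-then-effect equals the combined predicate
    combined = [
        c.key
        for c in cs.variants
        if c.annotation.region_class in ("exonic", "splice")
        and (
            c.annotation.region_class == "splice"
            or c.annotation.effect_class
            in ("nonsynonymous_SNV", "stopgain", "stoploss", "frameshift_indel")
        )
    ]
    assert effect_filter(region_filter(cs)).keys() == combined
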