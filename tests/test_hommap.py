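"""ROH calling vs exhaustive oracle, shared regions, STR phasing, lengths."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdmap.hommap import (
    GenomicRegion,
    RohParams,
    STRGenotype,
    call_roh,
    format_mb,
    minimal_shared_haplotype,
    phase_str_trio,
    region_length,
    shared_regions,
)
from ibdmap.variantstore import HET, HOM_ALT, HOM_REF, MISSING

from .oracles import roh_oracle


class TestCallRoh:
    def test_long_homozygous_run_called(self):
        pos = np.arange(12) * 13_637 + 1  # spans ~150 kb
        regions = call_roh(pos, [HOM_ALT] * 12, RohParams(), chrom="16")
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_variants) == (1, int(pos[-1]), 12)

    def test_short_span_fails_length_rule(self):
        pos = np.arange(12) * 4_500 + 1  # ~50 kb
        assert call_roh(pos, [HOM_REF] * 12, RohParams(), chrom="16") == []

    def test_het_breaks_run_at_default(self):
        pos = np.arange(24) * 13_637 + 1
        states = [HOM_ALT] * 12 + [HET] + [HOM_ALT] * 11
        regions = call_roh(pos, states, RohParams(min_variants=10), chrom="16")
        assert [r.n_variants for r in regions] == [12, 11]  # het splits the tract

    def test_missing_calls_skipped_without_breaking(self):
        pos = np.arange(13) * 13_637 + 1
        states = [HOM_ALT] * 6 + [MISSING] + [HOM_ALT] * 6
        regions = call_roh(pos, states, RohParams(), chrom="16")
        assert len(regions) == 1 and regions[0].n_variants == 12

    def test_unsorted_positions_raise(self):
        with pytest.raises(ValueError, match="not sorted"):
            call_roh([5, 1], [HOM_ALT, HOM_ALT], RohParams())

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        states=st.lists(
            st.sampled_from([HOM_REF, HET, HOM_ALT, MISSING]), min_size=0, max_size=30
        ),
        gaps=st.lists(st.integers(1, 60_000), min_size=30, max_size=30),
        min_variants=st.integers(1, 6),
        min_length=st.sampled_from([0, 50_000, 100_000]),
        max_het=st.integers(0, 2),
    )
    def test_matches_exhaustive_window_oracle(
        self, states, gaps, min_variants, min_length, max_het
    ):
        positions = np.cumsum(gaps[: len(states)])
        params = RohParams(min_variants=min_variants, min_length_bp=min_length, max_het=max_het)
        got = sorted(
            (r.start, r.end, r.n_variants)
            for r in call_roh(positions, states, params, chrom="1")
        )
        assert got == roh_oracle(list(positions), states, params)


class TestSharedRegions:
    def _r(self, start, end, sample):
        return GenomicRegion("16", start, end, 10, frozenset([sample]))

    def test_overlap_arithmetic(self):
        shared = shared_regions(
            {"a": [self._r(100_000, 500_000, "a")], "b": [self._r(300_000, 900_000, "b")]}
        )
        (r,) = shared
        assert (r.start, r.end, r.length) == (300_000, 500_000, 200_000)
        assert r.samples == {"a", "b"}

    def test_short_overlap_dropped_at_default_threshold(self):
        shared = shared_regions(
            {"a": [self._r(100_000, 190_000, "a")], "b": [self._r(150_000, 260_000, "b")]}
        )
        assert shared == []

    def test_disjoint_regions_empty(self):
        shared = shared_regions(
            {"a": [self._r(1, 200_000, "a")], "b": [self._r(400_000, 900_000, "b")]}
        )
        assert shared == []

    def test_raising_threshold_never_adds_regions(self):
        per = {
            "a": [self._r(1, 400_000, "a"), self._r(600_000, 780_000, "a")],
            "b": [self._r(100_000, 700_000, "b")],
        }
        lo = {(r.start, r.end) for r in shared_regions(per, 100_000)}
        hi = {(r.start, r.end) for r in shared_regions(per, 250_000)}
        assert hi <= lo

    def test_shared_region_within_each_contributors_roh(self, sim_dataset):
        from ibdmap.variantstore import write_vcf  # noqa: F401  (fixture dependency)

        per = {}
        for fid, proband in (("F1", "F1-IV.3"), ("F2", "F2-IV.3")):
            m = sim_dataset.matrices[fid]
            states = m.sample_states(proband)
            regs = []
            for chrom in ("1", "16"):
                idx = [i for i, k in enumerate(m.keys) if k.chrom == chrom]
                regs += call_roh(
                    [m.keys[i].pos for i in idx],
                    [states[i] for i in idx],
                    RohParams(),
                    chrom=chrom,
                    sample=proband,
                )
            per[proband] = regs
        for r in shared_regions(per):
            for sample, regs in per.items():
                assert any(
                    q.chrom == r.chrom and q.start <= r.start and r.end <= q.end
                    for q in regs
                )


class TestRegionLength:
    def test_plink_shared_region_renders_3_6_mb(self):
        r = GenomicRegion("16", 4_057_603, 7_657_432)
        assert region_length(r) == 3_599_829
        assert format_mb(r.length) == "3.6 Mb"

    def test_first_large_exome_region_renders_3_1_mb(self):
        r = GenomicRegion("16", 4_015_729, 7_102_036)
        assert region_length(r) == 3_086_307
        assert format_mb(r.length) == "3.1 Mb"
        assert format_mb(r.length, decimals=0) == "∼3 Mb"

    def test_degenerate_point_region(self):
        assert region_length(GenomicRegion("16", 42, 42)) == 0


def _g(marker, pos, sample, a, b):
    return STRGenotype(marker, "16", pos, sample, (a, b))


class TestPhaseStrTrio:
    def test_unique_assignment(self):
        hap = phase_str_trio(
            [_g("m1", 100, "kid", 150, 154)],
            [_g("m1", 100, "dad", 150, 150)],
            [_g("m1", 100, "mom", 154, 158)],
        )
        (pm,) = hap.markers
        assert (pm.paternal, pm.maternal, pm.resolved) == (150, 154, True)

    def test_homozygous_child_resolves_trivially(self):
        hap = phase_str_trio(
            [_g("m1", 100, "kid", 150, 150)],
            [_g("m1", 100, "dad", 150, 152)],
            [_g("m1", 100, "mom", 150, 152)],
        )
        (pm,) = hap.markers
        assert (pm.paternal, pm.maternal) == (150, 150)

    def test_fully_ambiguous_stays_unresolved(self):
        hap = phase_str_trio(
            [_g("m1", 100, "kid", 150, 154)],
            [_g("m1", 100, "dad", 150, 154)],
            [_g("m1", 100, "mom", 150, 154)],
        )
        (pm,) = hap.markers
        assert not pm.resolved and pm.mendelian_consistent

    def test_inconsistency_flagged_not_raised(self):
        hap = phase_str_trio(
            [_g("m1", 100, "kid", 150, 154)],
            [_g("m1", 100, "dad", 160, 162)],
            [_g("m1", 100, "mom", 164, 166)],
        )
        (pm,) = hap.markers
        assert not pm.mendelian_consistent


MAP10 = [(f"m{i}", "16", 1_000_000 * i) for i in range(1, 11)]


def _patient(sample, genos):
    return [
        STRGenotype(f"m{i}", "16", 1_000_000 * i, sample, g)
        for i, g in enumerate(genos, start=1)
    ]


class TestMinimalSharedHaplotype:
    def test_core_run_with_flanking_boundaries(self):
        # both patients identically homozygous at markers 3..7, discordant at 2 and 8
        p1 = _patient(
            "p1",
            [(1, 1), (2, 2), (5, 5), (5, 5), (5, 5), (5, 5), (5, 5), (1, 2), (1, 1), (1, 1)],
        )
        p2 = _patient(
            "p2",
            [(1, 1), (3, 3), (5, 5), (5, 5), (5, 5), (5, 5), (5, 5), (2, 2), (1, 1), (1, 1)],
        )
        mh = minimal_shared_haplotype({"p1": p1, "p2": p2}, MAP10)
        assert mh.core_markers == ("m3", "m4", "m5", "m6", "m7")
        assert (mh.left_boundary, mh.right_boundary) == ("m2", "m8")
        assert (mh.region.start, mh.region.end) == (2_000_000, 8_000_000)
        assert mh.region.length == 6_000_000

    def test_all_het_patient_gives_empty_result(self):
        p1 = _patient("p1", [(5, 5)] * 10)
        p2 = _patient("p2", [(1, 2)] * 10)
        mh = minimal_shared_haplotype({"p1": p1, "p2": p2}, MAP10)
        assert mh.region is None and mh.diagnostic

    def test_adding_patients_never_grows_the_haplotype(self):
        p1 = _patient("p1", [(5, 5)] * 10)
        p2 = _patient("p2", [(1, 1)] + [(5, 5)] * 8 + [(1, 1)])
        p3 = _patient("p3", [(1, 1), (2, 2)] + [(5, 5)] * 6 + [(3, 3), (1, 1)])
        two = minimal_shared_haplotype({"p1": p1, "p2": p2}, MAP10)
        three = minimal_shared_haplotype({"p1": p1, "p2": p2, "p3": p3}, MAP10)
        assert set(three.core_markers) <= set(two.core_markers)

    def test_recovers_region_containing_planted_variant(self, sim_dataset):
        df = sim_dataset.str_genotypes
        marker_map = [
            (str(r.marker), str(r.chrom), int(r.position))
            for r in df.drop_duplicates("marker").sort_values("position").itertuples()
        ]
        by_patient = {}
        for sample in ("F1-IV.3", "F2-IV.3"):
            sub = df[df["sample"] == sample]
            by_patient[sample] = [
                STRGenotype(
                    str(r.marker), str(r.chrom), int(r.position), sample,
                    (int(r.allele1), int(r.allele2)),
                )
                for r in sub.itertuples()
            ]
        mh = minimal_shared_haplotype(by_patient, marker_map)
        causal = sim_dataset.causal_key
        assert mh.region is not None
        assert mh.region.start <= causal.pos <= mh.region.end
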