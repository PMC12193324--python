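"""Codon counting, RSCU, composition, ENC, CAI/CBI/Fop."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocub import (
    CodingSequence,
    CodonCounts,
    CodonUsageProfiler,
    ReferenceSet,
    cai,
    cbi,
    composition,
    count_codons,
    enc_wright,
    fop,
    get_code,
    rscu,
)

from conftest import enc_brute_force, random_counts

CODE = get_code(1)


class TestCountCodons:
    def test_direct_readoff(self):
        assert count_codons("ATGAAACGATAA").counts == {"ATG": 1, "AAA": 1, "CGA": 1}

    def test_include_stop(self):
        counts = count_codons("ATGAAACGATAA", include_stop=True).counts
        assert counts == {"ATG": 1, "AAA": 1, "CGA": 1, "TAA": 1}

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible"):
            count_codons("ATGAAAC")


class TestRscu:
    def test_uniform_fourfold_family_is_one(self):
        counts = CodonCounts({"GCT": 5, "GCC": 5, "GCA": 5, "GCG": 5})
        vals = rscu(counts)
        assert all(vals[c] == pytest.approx(1.0) for c in ("GCT", "GCC", "GCA", "GCG"))

    def test_arginine_hand_computation(self):
        # AGA=3, AGG=1 of the 6-fold Arg family: RSCU(AGA) = 3/(4/6) = 4.5
        counts = CodonCounts({"AGA": 3, "AGG": 1})
        vals = rscu(counts)
        assert vals["AGA"] == pytest.approx(4.5)
        assert vals["AGG"] == pytest.approx(1.5)
        assert all(
            vals[c] == 0.0 for c in ("CGA", "CGC", "CGG", "CGT")
        )

    def test_unobserved_families_absent_not_zero_filled(self):
        vals = rscu(CodonCounts({"AAA": 2}))
        assert "GCT" not in vals
        assert set(vals) == {"AAA", "AAG"}

    def test_single_codon_family_is_one_when_observed(self):
        assert rscu(CodonCounts({"ATG": 7}))["ATG"] == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_family_size(self, seed):
        counts = random_counts(np.random.default_rng(seed))
        vals = rscu(counts)
        for aa, fam in CODE.families.items():
            observed = [c for c in fam if c in vals]
            if not observed:
                continue
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))


class TestComposition:
    def test_all_gc(self):
        comp = composition(count_codons("GGCGGC"))
        assert (comp.gc1, comp.gc2, comp.gc3, comp.gc_all) == (100, 100, 100, 100)

    def test_met_trp_only_has_no_synonymous_third_positions(self):
        comp = composition(count_codons("ATGTGG"))
        assert math.isnan(comp.gc3s)
        assert math.isnan(comp.a3s)

    def test_gc12_is_mean_of_gc1_gc2(self):
        # GGT: GC1=100, GC2=100; AAA: 0,0 -> GC12 = 50
        comp = composition(count_codons("GGTAAA"))
        assert comp.gc12 == pytest.approx((comp.gc1 + comp.gc2) / 2) == 50.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_third_position_counts_conserve_total(self, seed):
        counts = random_counts(np.random.default_rng(seed))
        if counts.total == 0:
            return
        comp = composition(counts)
        assert comp.a3 + comp.t3 + comp.c3 + comp.g3 == comp.n_codons
        assert comp.gc_all == pytest.approx((comp.gc1 + comp.gc2 + comp.gc3) / 3)
        assert min(comp.gc1, comp.gc2, comp.gc3) <= comp.gc_all <= max(
            comp.gc1, comp.gc2, comp.gc3
        )


class TestEnc:
    def test_single_codon_per_family_is_20(self, worked):
        cds, expected = worked
        f3 = next(c for c in cds if c.gene == "F3")
        assert enc_wright(count_codons(f3)) == expected["F3"]["enc"] == 20.0

    def test_uniform_usage_large_counts_approaches_61(self):
        counts = CodonCounts({c: 10_000 for c in CODE.sense_codons})
        assert enc_wright(counts) == pytest.approx(61.0, abs=0.05)

    def test_empty_family_structure_gives_nan(self):
        assert math.isnan(enc_wright(CodonCounts({"ATG": 5})))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        counts = random_counts(np.random.default_rng(seed))
        expected = enc_brute_force(counts.counts)
        got = enc_wright(counts)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_concentrating_counts_never_increases_enc(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_counts(rng)
        before = enc_wright(counts)
        if math.isnan(before):
            return
        # move every family's counts onto its most-used codon
        concentrated = {}
        for aa, fam in CODE.families.items():
            tot = sum(counts.counts.get(c, 0) for c in fam)
            if tot:
                top = max(fam, key=lambda c: (counts.counts.get(c, 0), c))
                concentrated[top] = tot
        after = enc_wright(CodonCounts(concentrated))
        assert after <= before + 1e-9


@pytest.fixture()
def tiny_ref():
    """Reference with known weights over one 2-fold and one 4-fold family."""
    return ReferenceSet(
        name="tiny",
        optimal_codons=frozenset({"AAA", "GCT"}),
        cai_weights={"AAA": 1.0, "AAG": 0.25, "GCT": 1.0, "GCC": 0.5,
                     "GCA": 0.5, "GCG": 0.5},
    )


class TestCai:
    def test_only_weight_one_codons(self, tiny_ref):
        assert cai(CodonCounts({"AAA": 10, "GCT": 3}), tiny_ref) == pytest.approx(1.0)

    def test_geometric_mean_hand_case(self, tiny_ref):
        # one codon at w=0.25 and one at w=1: CAI = sqrt(0.25) = 0.5
        assert cai(CodonCounts({"AAA": 1, "AAG": 1}), tiny_ref) == pytest.approx(0.5)

    def test_constant_weights_give_that_weight(self, tiny_ref):
        assert cai(CodonCounts({"GCC": 4, "GCA": 2}), tiny_ref) == pytest.approx(0.5)

    def test_zero_weight_floored_with_warning(self):
        ref = ReferenceSet("z", frozenset(), {"AAA": 1.0, "AAG": 0.0})
        with pytest.warns(UserWarning, match="floored"):
            val = cai(CodonCounts({"AAG": 2}), ref)
        assert val == pytest.approx(1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 9))
    def test_invariant_to_count_scaling(self, seed, k):
        counts = random_counts(np.random.default_rng(seed))
        if not counts.counts:
            return
        ref = ReferenceSet.from_counts(counts, CODE)
        scaled = CodonCounts({c: k * n for c, n in counts.counts.items()})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b = cai(counts, ref), cai(scaled, ref)
        assert a == pytest.approx(b, rel=1e-12)


class TestCbiFop:
    def test_only_optimal_codons(self, tiny_ref):
        counts = CodonCounts({"AAA": 5, "GCT": 5})
        assert cbi(counts, tiny_ref) == pytest.approx(1.0)
        assert fop(counts, tiny_ref) == pytest.approx(1.0)

    def test_uniform_usage_gives_cbi_zero(self, tiny_ref):
        counts = CodonCounts({"AAA": 3, "AAG": 3, "GCT": 2, "GCC": 2,
                              "GCA": 2, "GCG": 2})
        assert cbi(counts, tiny_ref) == pytest.approx(0.0)

    def test_all_counts_on_nonoptimal_twofold_is_minus_one(self, tiny_ref):
        # N_opt=0, N_ran=2, N_tot=4 -> (0-2)/(4-2) = -1
        assert cbi(CodonCounts({"AAG": 4}), tiny_ref) == pytest.approx(-1.0)

    def test_no_optimal_codons_fop_zero(self, tiny_ref):
        assert fop(CodonCounts({"AAG": 4, "GCC": 4}), tiny_ref) == 0.0

    def test_fop_simple_ratio(self, tiny_ref):
        # 3 optimal of 8 synonymous codons
        counts = CodonCounts({"AAA": 3, "AAG": 3, "GCC": 2})
        assert fop(counts, tiny_ref) == pytest.approx(0.375)

    def test_degenerate_cbi_is_nan(self):
        # both Lys codons optimal: N_ran == N_tot
        ref = ReferenceSet("d", frozenset({"AAA", "AAG"}), {})
        assert math.isnan(cbi(CodonCounts({"AAA": 2, "AAG": 2}), ref))


class TestProfiler:
    def test_worked_fixture_profiles(self, worked):
        cds, expected = worked
        prof = CodonUsageProfiler().fit(cds)
        table = prof.transform(cds).set_index("gene")
        for gene, exp in expected.items():
            row = table.loc[gene]
            for key in ("gc1", "gc2", "gc3", "gc_all", "gc12", "gc3s",
                        "a3s", "t3s", "c3s", "g3s", "a3", "t3", "c3", "g3", "enc"):
                if key in exp:
                    assert row[key] == pytest.approx(exp[key]), (gene, key)

    def test_sklearn_api_round_trip(self, worked):
        cds, _ = worked
        prof = CodonUsageProfiler(pool_fraction=0.25)
        params = prof.get_params()
        assert params["pool_fraction"] == 0.25
        prof.set_params(include_stop=False).fit(cds)
        assert hasattr(prof, "reference_set_")
        out = prof.transform(cds)
        assert list(out["gene"]) == [c.gene for c in cds]

    def test_transform_before_fit_raises(self, worked):
        cds, _ = worked
        with pytest.raises(ValueError, match="not fitted"):
            CodonUsageProfiler().transform(cds)

    def test_accepts_name_sequence_pairs(self):
        out = CodonUsageProfiler().fit_transform(
            [("g1", "ATGAAACGATAA"), ("g2", "ATGGCTGCCTAA")]
        )
        assert list(out["gene"]) == ["g1", "g2"]
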