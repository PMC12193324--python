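"""Neutrality regression, ENC plot, PR2, correlations, RSCU clustering."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocub import (
    CodonCounts,
    NeutralityRegression,
    correlation_matrix,
    enc_expected,
    enc_plot,
    get_code,
    neutrality_regression,
    pr2,
    rscu_cluster,
)

CODE = get_code(1)


class TestEncExpected:
    @pytest.mark.parametrize(
        "gc3, value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form_values(self, gc3, value):
        assert enc_expected(gc3) == pytest.approx(value)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    def test_maximum_near_half_and_exceeds_60(self):
        grid = np.linspace(0.01, 0.99, 981)
        vals = enc_expected(grid)
        argmax = grid[int(np.argmax(vals))]
        assert abs(argmax - 0.5) < 0.02
        assert vals.max() > 60


class TestNeutralityRegression:
    def test_identity_line(self):
        x = np.array([30.0, 40.0, 50.0, 60.0])
        reg = NeutralityRegression().fit(x, x)
        assert reg.slope_ == pytest.approx(1.0)
        assert reg.rvalue_ == pytest.approx(1.0)

    def test_constant_response_slope_zero(self):
        x = np.array([30.0, 40.0, 50.0])
        reg = NeutralityRegression().fit(x, np.full(3, 45.0))
        assert reg.slope_ == pytest.approx(0.0)

    def test_zero_variance_predictor_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            NeutralityRegression().fit(np.full(4, 40.0), np.arange(4.0))

    def test_predict_follows_fit(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(20, 60, 30)
        y = 0.4 * x + 10 + rng.normal(0, 0.5, 30)
        reg = NeutralityRegression().fit(x, y)
        assert reg.predict(np.array([50.0]))[0] == pytest.approx(
            reg.slope_ * 50 + reg.intercept_
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.uniform(0, 100, n)
        if np.ptp(x) == 0:
            return
        y = rng.uniform(0, 100, n)
        reg = NeutralityRegression().fit(x, y)
        # brute-force normal equations
        A = np.vstack([x, np.ones(n)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert reg.slope_ == pytest.approx(beta[0], abs=1e-9)
        assert reg.intercept_ == pytest.approx(beta[1], abs=1e-9)

    def test_wrapper_from_profiles(self):
        profiles = pd.DataFrame(
            {"gc3": [30.0, 40, 50, 60], "gc12": [35.0, 40, 45, 50]}
        )
        res = neutrality_regression(profiles)
        assert res.slope == pytest.approx(0.5)
        assert res.interpretation.startswith("mutation")


class TestEncPlot:
    def test_gene_on_curve_has_zero_deviation(self):
        profiles = pd.DataFrame(
            {"gene": ["g"], "gc3s": [50.0], "enc": [enc_expected(0.5)]}
        )
        res = enc_plot(profiles)
        assert res.deviations[0] == pytest.approx(0.0)
        assert res.n_below == 0 and res.n_above == 0

    def test_uniform_usage_gene_sits_just_above_curve(self):
        # near-uniform usage at GC3s ~ 0.5 gives ENC ~ 61, curve 60.5
        from mitocub import composition, enc_wright

        counts = CodonCounts({c: 5000 for c in CODE.sense_codons})
        comp = composition(counts)
        profiles = pd.DataFrame(
            {"gene": ["u"], "gc3s": [comp.gc3s], "enc": [enc_wright(counts)]}
        )
        res = enc_plot(profiles)
        assert res.deviations[0] == pytest.approx(0.5, abs=0.1)

    def test_selection_regime_sits_below_curve(self):
        from mitocub import SyntheticSpec, generate, profile_genes

        cds, _ = generate(
            SyntheticSpec(n_genes=30, regime="selection",
                          selection_strength=0.7, seed=5)
        )
        res = enc_plot(profile_genes(cds))
        assert res.n_below > res.n_above

    def test_axis_choice_validated(self):
        with pytest.raises(ValueError):
            enc_plot(pd.DataFrame({"gene": [], "gc3s": [], "enc": []}), x="gc2")


class TestPr2:
    def test_balanced_center(self):
        counts = CodonCounts({"GGA": 1, "GGT": 1, "GGC": 1, "GGG": 1})
        pt = pr2(counts)
        assert (pt.x, pt.y) == (0.5, 0.5)
        assert pt.quadrant is None  # boundary point

    def test_hand_ratios(self):
        # fourfold Gly box: G3=3, C3=1, A3=1, T3=3
        counts = CodonCounts({"GGG": 3, "GGC": 1, "GGA": 1, "GGT": 3})
        pt = pr2(counts)
        assert pt.x == pytest.approx(0.75)
        assert pt.y == pytest.approx(0.25)
        assert pt.quadrant == "IV"

    def test_all_third_positions_t_gives_y_zero(self):
        pt = pr2(CodonCounts({"GGT": 4, "GCT": 2}))
        assert pt.y == 0.0

    def test_strict_mode_ignores_twofold_families(self):
        # AAA/AAG are not fourfold sites; alone they give undefined PR2
        pt = pr2(CodonCounts({"AAA": 5, "AAG": 5}))
        assert math.isnan(pt.x) and math.isnan(pt.y) and pt.quadrant is None
        loose = pr2(CodonCounts({"AAA": 5, "AAG": 5}), fourfold_only=False)
        assert loose.y == 1.0  # A3/(A3+T3) with only A endings among A/T

    @pytest.mark.parametrize(
        "g, c, a, t, quadrant",
        [(3, 1, 3, 1, "I"), (1, 3, 3, 1, "II"), (1, 3, 1, 3, "III"),
         (3, 1, 1, 3, "IV")],
    )
    def test_quadrant_assignment(self, g, c, a, t, quadrant):
        counts = CodonCounts({"GGG": g, "GGC": c, "GGA": a, "GGT": t})
        assert pr2(counts).quadrant == quadrant


class TestCorrelationMatrix:
    @pytest.fixture()
    def profiles(self):
        rng = np.random.default_rng(11)
        n = 20
        gc3 = rng.uniform(30, 60, n)
        return pd.DataFrame(
            {
                "n_codons": rng.integers(100, 700, n),
                "gc3": gc3,
                "gc_all": gc3 * 0.5 + rng.normal(0, 0.5, n) + 30,
                "enc": rng.uniform(40, 61, n),
                "cai": -gc3 / 100 + rng.normal(0, 1e-6, n),
            }
        )

    def test_diagonal_is_one_and_symmetric(self, profiles):
        res = correlation_matrix(profiles)
        r = res.r.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"gc3": [1.0, 2, 3, 4], "enc": [-1.0, -2, -3, -4]})
        res = correlation_matrix(df, variables=["gc3", "enc"])
        assert res.r.loc["gc3", "enc"] == pytest.approx(-1.0)
        assert res.stars.loc["gc3", "enc"] == "**"

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame(
            {"gc3": [1.0, 2, 3, 4], "enc": [5.0, 5, 5, 5], "cai": [1.0, 2, 1, 2]}
        )
        res = correlation_matrix(df, variables=["gc3", "enc", "cai"])
        assert math.isnan(res.r.loc["gc3", "enc"])

    def test_pvalues_match_permutation_null(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        df = pd.DataFrame({"gc3": x, "enc": y})
        res = correlation_matrix(df, variables=["gc3", "enc"])
        observed = abs(res.r.loc["gc3", "enc"])
        perms = 0
        n_perm = 2000
        for _ in range(n_perm):
            yy = rng.permutation(y)
            perms += abs(np.corrcoef(x, yy)[0, 1]) >= observed
        mc_p = perms / n_perm
        assert res.p.loc["gc3", "enc"] == pytest.approx(mc_p, abs=0.05)


class TestRscuCluster:
    def _rows(self, mat, labels):
        return pd.DataFrame(mat, index=labels)

    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2, 30)
        c = rng.uniform(0, 2, 30)
        dend = rscu_cluster(self._rows([a, a, c], ["A", "B", "C"]))
        assert dend.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        assert dend.newick.count("A") == 1

    def test_anticorrelated_rows_at_distance_two(self):
        x = np.array([1.0, 2, 3, 4])
        dend = rscu_cluster(self._rows([x, -x + 5], ["P", "Q"]))
        assert dend.merge_heights[-1] == pytest.approx(2.0)

    def test_topology_pairs_correlated_rows(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 2, 59)
        b = a + rng.normal(0, 0.01, 59)
        c = rng.uniform(0, 2, 59)
        dend = rscu_cluster(self._rows([a, c, b], ["A", "C", "B"]))
        # brute-force distances confirm (A,B) closest
        def d(u, v):
            return 1 - np.corrcoef(u, v)[0, 1]

        pairs = {
            ("A", "B"): d(a, b), ("A", "C"): d(a, c), ("B", "C"): d(b, c)
        }
        assert min(pairs, key=pairs.get) == ("A", "B")
        # the first merge joins A and B, so the topology is ((A,B),C)
        first = sorted(
            dend.leaves[i]
            for i in (int(dend.linkage[0, 0]), int(dend.linkage[0, 1]))
        )
        assert first == ["A", "B"]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        mat = rng.uniform(0, 2, (8, 59))
        dend = rscu_cluster(self._rows(mat, [f"s{i}" for i in range(8)]))
        heights = dend.merge_heights
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_zero_variance_row_raises_with_name(self):
        mat = [[1.0, 1, 1, 1], [1.0, 2, 3, 4]]
        with pytest.raises(ValueError, match="flatrow"):
            rscu_cluster(self._rows(mat, ["flatrow", "ok"]))

    def test_newick_parses_with_dendropy(self):
        import dendropy

        rng = np.random.default_rng(6)
        mat = rng.uniform(0, 2, (5, 40))
        labels = ["sp1", "sp2", "sp3", "sp4", "sp5"]
        dend = rscu_cluster(self._rows(mat, labels))
        tree = dendropy.Tree.get(data=dend.newick, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == labels
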