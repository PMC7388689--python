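"""Conditional/conjunction FDR, data-driven thresholds and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pleiokit as pk


def brute_force_cfdr(p1, p2):
    """O(N^2) dominance-count oracle, independent of the fast path."""
    n = len(p1)
    out = np.empty(n)
    for i in range(n):
        n2 = np.sum(p2 <= p2[i])
        both = np.sum((p1 <= p1[i]) & (p2 <= p2[i]))
        out[i] = min(1.0, p1[i] * n2 / both)
    return out


SPEC_P1 = np.array([0.001, 0.02, 0.5, 0.04, 0.2])
SPEC_P2 = np.array([0.01, 0.005, 0.3, 0.9, 0.04])


class TestCfdrValues:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(size=1000) ** 2
        p2 = rng.uniform(size=1000) ** 2
        assert np.array_equal(pk.cfdr_values(p1, p2), brute_force_cfdr(p1, p2))

    def test_oracle_equality_with_ties(self):
        rng = np.random.default_rng(4)
        p1 = rng.choice([0.01, 0.05, 0.2, 0.8], size=300)
        p2 = rng.choice([0.02, 0.1, 0.5, 1.0], size=300)
        assert np.array_equal(pk.cfdr_values(p1, p2), brute_force_cfdr(p1, p2))

    def test_five_snp_worked_example(self):
        c = pk.cfdr_values(SPEC_P1, SPEC_P2)
        assert c[0] == pytest.approx(0.001 * 2 / 1)  # 0.002

    def test_single_snp_returns_its_pvalue(self):
        assert pk.cfdr_values(np.array([0.03]), np.array([0.5]))[0] == 0.03

    def test_uninformative_conditioning_gives_empirical_fdr(self):
        """All conditional p = 1: cFDR_i = p1_i * N / rank(p1_i)."""
        rng = np.random.default_rng(5)
        p1 = rng.uniform(size=200)
        got = pk.cfdr_values(p1, np.ones(200))
        rank = np.searchsorted(np.sort(p1), p1, side="right")
        assert np.allclose(got, np.minimum(1, p1 * 200 / rank))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pk.cfdr_values(np.array([]), np.array([]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_cfdr_dominates_principal_pvalue(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(size=50)
        p2 = rng.uniform(size=50)
        assert (pk.cfdr_values(p1, p2) >= p1 - 1e-15).all()

    def test_invariant_to_snp_order(self):
        rng = np.random.default_rng(6)
        p1 = rng.uniform(size=100)
        p2 = rng.uniform(size=100)
        perm = rng.permutation(100)
        assert np.allclose(pk.cfdr_values(p1, p2)[perm],
                           pk.cfdr_values(p1[perm], p2[perm]))


class TestCcfdr:
    def test_worked_example_reverse_direction(self):
        c12 = pk.cfdr_values(SPEC_P1, SPEC_P2)
        c21 = pk.cfdr_values(SPEC_P2, SPEC_P1)
        assert c21[0] == pytest.approx(0.01 * 1 / 1)
        assert pk.ccfdr_values(c12, c21)[0] == pytest.approx(0.01)

    def test_max_properties(self):
        a = np.array([0.1, 0.5, 0.2])
        b = np.array([0.1, 0.3, 0.4])
        cc = pk.ccfdr_values(a, b)
        assert (cc >= a).all() and (cc >= b).all()
        assert np.array_equal(pk.ccfdr_values(a, a), a)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            pk.ccfdr_values(np.zeros(3), np.zeros(4))


class TestThreshold:
    def test_maximum_of_qualifying_cfdrs(self):
        cfdr = np.array([1e-7, 2e-6, 9.8e-6, 0.5])
        p = np.array([1e-9, 1e-9, 1e-9, 0.5])
        assert pk.cfdr_threshold(cfdr, p) == pytest.approx(9.8e-6)

    def test_single_qualifying_snp(self):
        assert pk.cfdr_threshold(np.array([3e-6, 0.9]),
                                 np.array([1e-10, 0.9])) == pytest.approx(3e-6)

    def test_no_genomewide_hit_is_an_error(self):
        with pytest.raises(ValueError, match="manual"):
            pk.cfdr_threshold(np.array([0.1]), np.array([0.1]))


class TestStratifiedQQ:
    def test_three_snp_ecdf_example(self):
        curves = pk.stratified_qq(np.array([0.001, 0.01, 0.1]),
                                  np.array([0.5, 0.5, 0.5]), cutoffs=(1.0,))
        c = curves[1.0]
        assert np.allclose(c["ecdf"], [1 / 3, 2 / 3, 1.0])
        assert np.allclose(c["neglog10_p"], [3, 2, 1])

    def test_cutoff_one_is_the_all_snp_curve(self):
        rng = np.random.default_rng(7)
        p1, p2 = rng.uniform(size=500), rng.uniform(size=500)
        curves = pk.stratified_qq(p1, p2)
        assert len(curves[1.0]) == 500

    def test_independent_traits_show_no_enrichment(self):
        """Null pair: stratified curves indistinguishable from baseline (KS)."""
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(8)
        p1, p2 = rng.uniform(size=20_000), rng.uniform(size=20_000)
        for t in (0.1, 0.01):
            stat = ks_2samp(p1, p1[p2 <= t])
            assert stat.pvalue > 0.01


class TestFoldEnrichment:
    def test_hand_ratio(self):
        # stratum: 100 SNPs, 10 in the tail; overall: 1,000 SNPs, 20 in tail
        p1 = np.full(1000, 0.5)
        p1[:20] = 1e-4
        p2 = np.full(1000, 0.5)
        p2[10:110] = 0.001  # stratum of 100 holds 10 of the tail SNPs
        out = pk.fold_enrichment(p1, p2, cutoffs=(0.001,), x_grid=np.array([3.0]))
        assert out["enrichment"].item() == pytest.approx((10 / 100) / (20 / 1000))

    def test_baseline_stratum_is_identity(self):
        rng = np.random.default_rng(9)
        p1, p2 = rng.uniform(size=500), rng.uniform(size=500)
        out = pk.fold_enrichment(p1, p2, cutoffs=(1.0,),
                                 x_grid=np.array([0.0, 0.5, 1.0]))
        assert np.allclose(out["enrichment"], 1.0)

    def test_enrichment_grows_with_stricter_conditioning(self, panel20k):
        """Shared effects: stricter conditional stratum, higher enrichment."""
        vals = {0.1: [], 0.001: []}
        for rep in range(10):
            cfg = pk.SimulationConfig(seed=4000 + rep)
            truth = pk.simulate_effects(cfg, panel20k)
            s1, s2 = pk.simulate_sumstats(truth, panel20k, cfg)
            out = pk.fold_enrichment(s1["pvalue"].to_numpy(),
                                     s2["pvalue"].to_numpy(),
                                     cutoffs=(0.1, 0.001),
                                     x_grid=np.array([2.0]))
            for t in (0.1, 0.001):
                sel = out[out["cutoff"] == t]
                if len(sel):
                    vals[t].append(sel["enrichment"].item())
        assert np.mean(vals[0.001]) > np.mean(vals[0.1]) > 1.0


class TestManhattanData:
    def test_threshold_line_matches_figure_convention(self):
        # a ccFDR cutoff of 8.9e-4 sits at -log10 ~ 3.05, i.e. the 3.1 line
        df, y = pk.conjunction_manhattan_data(np.array([8.9e-4]),
                                              ["1"], [100], cutoff=8.9e-4)
        assert y == pytest.approx(3.0506, abs=1e-3)
        assert df["neglog10_ccfdr"].item() == pytest.approx(y)

    def test_ccfdr_of_one_maps_to_zero(self):
        df, _ = pk.conjunction_manhattan_data(np.array([1.0]), ["1"], [5], 0.05)
        assert df["neglog10_ccfdr"].item() == 0.0

    def test_chromosome_offsets_strictly_increase(self):
        df, _ = pk.conjunction_manhattan_data(
            np.array([0.5, 0.5, 0.5, 0.5]),
            ["1", "1", "2", "2"], [10, 20, 5, 15], 0.05)
        x = df["x"].to_numpy()
        assert (np.diff(x) > 0).all()


class TestModelInterface:
    def test_fit_produces_flags_and_summary(self, small_sim):
        _, panel, _, s1, s2 = small_sim
        pair = pk.harmonize(pk.validate_sumstats(s1), pk.validate_sumstats(s2))
        res = pk.CfdrModel(pair).fit()
        t = res.table
        assert (t["ccfdr"] == np.maximum(t["cfdr_1g2"], t["cfdr_2g1"])).all()
        assert res.cutoff_cc == max(res.cutoff_1g2, res.cutoff_2g1)
        assert res.n_sig_cc <= min(res.n_sig_1g2, res.n_sig_2g1)
        assert "Conditional FDR" in res.summary()

    def test_manual_cutoffs_bypass_data_driven_rule(self):
        df = pd.DataFrame({"snp_id": ["a", "b"], "chrom": ["1", "1"],
                           "pos": [1, 2], "p1": [0.2, 0.4], "p2": [0.3, 0.5]})
        res = pk.CfdrModel(df).fit(manual_cutoffs=(0.5, 0.5))
        assert res.cutoff_cc == 0.5
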