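"""F_ST estimators, LD scores, LDCV, binning and the low/high split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crosspop as cp
from crosspop.pipeline import _simulate_polymorphic
from crosspop.stratify import (
    SnpStrata,
    _equal_count_bins,
    fst_hudson,
    fst_hudson_overall,
    fst_weir_cockerham,
)


class TestFst:
    def test_hudson_formula_value(self):
        # p1=0.1, p2=0.9, n -> infinity: 0.64/0.82
        v = fst_hudson(np.array([0.1]), 10**12, np.array([0.9]), 10**12)
        assert v[0] == pytest.approx(0.64 / 0.82, rel=1e-6)

    def test_no_differentiation_near_zero(self):
        v = fst_hudson(np.array([0.3]), 10**12, np.array([0.3]), 10**12)
        assert abs(v[0]) < 1e-10

    def test_unbiased_under_null(self, rng):
        # identical true frequencies: expectation of the estimator is <= 0
        p = 0.3
        n = 200
        f1 = rng.binomial(2 * n, p, 20000) / (2 * n)
        f2 = rng.binomial(2 * n, p, 20000) / (2 * n)
        v = fst_hudson(f1, 2 * n, f2, 2 * n)
        assert np.nanmean(v) < 0.002

    def test_undefined_denominator_nan(self):
        v = fst_hudson(np.array([0.0]), 100, np.array([0.0]), 100)
        assert np.isnan(v[0])

    def test_weir_cockerham_direct_formula(self):
        # evaluate the frequency-only theta by hand for one configuration
        p1, p2, nd = 0.2, 0.6, 50.0  # 50 diploids each
        r, n_bar, nc = 2.0, 50.0, 50.0
        p_bar = 0.4
        s2 = (nd * (p1 - p_bar) ** 2 + nd * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (nd * 2 * p1 * (1 - p1) + nd * 2 * p2 * (1 - p2)) / (r * n_bar)
        a = n_bar / nc * (s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 / 2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        expected = a / (a + b + c)
        v = fst_weir_cockerham(np.array([p1]), 100, np.array([p2]), 100)
        assert v[0] == pytest.approx(expected, rel=1e-12)

    def test_estimator_dispatch(self):
        with pytest.raises(ValueError):
            cp.fst_per_snp(np.array([0.5]), 10, np.array([0.5]), 10, estimator="nope")


class TestLdScores:
    def test_isolated_snp_self_term(self, rng):
        g = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
        pos = np.array([0, 5_000_000, 10_000_000])
        scores = cp.ld_scores(g, pos, window_kb=1000.0)
        np.testing.assert_allclose(scores, 1.0, atol=1e-12)

    def test_independent_snps_mean_one(self, rng):
        n, m = 200, 2000
        g = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        pos = np.arange(m) * 1000
        scores = cp.ld_scores(g, pos, window_kb=100.0)
        # adjustment removes the (m_window - 1)/(n - 2) inflation
        assert abs(scores.mean() - 1.0) < 0.05
        raw = cp.ld_scores(g, pos, window_kb=100.0, adjust=False)
        assert raw.mean() > scores.mean() + 0.5

    def test_monotone_in_ld_rho(self):
        means = []
        for rho in (0.0, 0.4, 0.8):
            model = cp.PopulationModel(n_pop1=400, n_pop2=10, m=300,
                                       ld_block_size=10, ld_rho=rho, seed=21)
            ds, _ = cp.simulate_dataset(model, cp.TraitArchitecture(m_causal=10))
            mask = ds.population_mask(1)
            s = cp.ld_scores(ds.genotypes[mask].astype(float),
                             ds.snp_table["pos"].to_numpy(), window_kb=200.0)
            means.append(s.mean())
        assert means[0] < means[1] < means[2]


class TestLdcv:
    def test_values(self):
        assert cp.ldcv(np.array([2.0]), np.array([2.0]))[0] == 0.0
        assert cp.ldcv(np.array([2.0]), np.array([1.0]))[0] == pytest.approx(
            1.0 / (np.sqrt(2) * 1.5), rel=1e-12
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(0.01, 100))
    def test_scale_invariance(self, l1, l2, c):
        a = cp.ldcv(np.array([l1]), np.array([l2]))[0]
        b = cp.ldcv(np.array([c * l1]), np.array([c * l2]))[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cp.ldcv(np.array([0.0]), np.array([0.0]))


class TestBins:
    def test_possible_bin_counts(self, rng):
        f1 = rng.uniform(0.01, 0.99, 5000)
        f2 = rng.uniform(0.01, 0.99, 5000)
        l1 = rng.gamma(4, 2, 5000)
        l2 = rng.gamma(4, 2, 5000)
        _, n_fst = cp.make_bins(f1, f2, l1, l2, 125, 4)
        assert n_fst == 250_000
        _, n_ldcv = cp.make_bins(f1, f2, l1, l2, 20, 25)
        assert n_ldcv == 250_000

    def test_single_bin_collapses(self, rng):
        f = rng.uniform(0.1, 0.9, 50)
        joint, n = cp.make_bins(f, f, f, f, 1, 1)
        assert n == 1 and len(np.unique(joint)) == 1

    def test_equal_count_property(self, rng):
        v = rng.standard_normal(1003)
        b = _equal_count_bins(v, 10)
        counts = np.bincount(b)
        assert counts.max() - counts.min() <= 1
        # binning respects order: max of bin k <= min of bin k+1
        for k in range(9):
            assert v[b == k].max() <= v[b == k + 1].min() + 1e-12


class TestSplit:
    def test_even_bin_sorted_halves(self):
        bins = np.zeros(4, dtype=int)
        metric = np.array([0.1, 0.3, 0.2, 0.4])
        grp = cp.split_within_bins(bins, metric, seed=0)
        assert list(grp) == ["low", "high", "low", "high"]

    def test_odd_bin_seeded_coin(self):
        bins = np.zeros(3, dtype=int)
        metric = np.array([0.1, 0.2, 0.3])
        a = cp.split_within_bins(bins, metric, seed=5)
        b = cp.split_within_bins(bins, metric, seed=5)
        assert list(a) == list(b)
        assert a[0] == "low" and a[2] == "high"  # extremes always fixed
        sizes = {tuple(cp.split_within_bins(bins, metric, seed=s).tolist())
                 for s in range(20)}
        assert len(sizes) == 2  # the median SNP lands on both sides across seeds

    def test_group_sizes_within_odd_bin_count(self, rng):
        m = 20_000
        bins = rng.integers(0, 6000, m)
        metric = rng.random(m)
        grp = cp.split_within_bins(bins, metric, seed=1)
        n_odd = sum(c % 2 for c in np.bincount(bins) if c)
        assert abs((grp == "low").sum() - (grp == "high").sum()) <= n_odd

    def test_metric_separation(self, rng):
        bins = rng.integers(0, 50, 2000)
        metric = rng.random(2000)
        grp = cp.split_within_bins(bins, metric, seed=1)
        assert metric[grp == "high"].mean() > metric[grp == "low"].mean()

    def test_nan_metric_rejected(self):
        with pytest.raises(ValueError):
            cp.split_within_bins(np.zeros(2, int), np.array([0.1, np.nan]), 0)


class TestBuildStrata:
    def test_table_and_groups(self, small_dataset):
        ds, _ = small_dataset
        strata = cp.build_strata(ds, n_freq_bins=10, n_ld_bins=2, seed=0)
        t = strata.table
        assert set(t["group"]) == {"low", "high"}
        assert strata.n_possible_bins == 10 * 10 * 2 * 2
        assert t["fst"].notna().all()
        assert (t.loc[t["group"] == "high", "fst"].mean()
                > t.loc[t["group"] == "low", "fst"].mean())

    def test_deterministic_given_seed(self, small_dataset):
        ds, _ = small_dataset
        a = cp.build_strata(ds, n_freq_bins=10, n_ld_bins=2, seed=3).table
        b = cp.build_strata(ds, n_freq_bins=10, n_ld_bins=2, seed=3).table
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def stratified_fit():
    model = cp.PopulationModel(n_pop1=300, n_pop2=300, m=600,
                               ld_block_size=10, ld_rho=0.3, seed=31)
    arch = cp.TraitArchitecture(m_causal=250, rg_true=0.8,
                                h2_pop1=0.6, h2_pop2=0.6)
    ds, y = _simulate_polymorphic(model, arch)
    return ds, y


class TestTwoComponent:

    def test_null_component_h2_near_zero(self, stratified_fit):
        ds, y = stratified_fit
        causal = ds.truth["causal_mask"]
        # place every causal SNP in the low group
        table = pd.DataFrame({
            "snp": ds.snp_table["snp"],
            "snp_index": np.arange(ds.n_snps),
            "group": np.where(causal, "low", "high"),
        })
        strata = SnpStrata(table, 1)
        fit = cp.two_component_fit(ds, strata, y)
        d_low = {"Vg1": fit["Vg1_1"], "Vg2": fit["Vg2_1"]}
        # component 2 (the causal-free group) should carry ~no variance
        se1 = np.sqrt(max(fit.subcov(["Vg1_2"])[0, 0], 0))
        se2 = np.sqrt(max(fit.subcov(["Vg2_2"])[0, 0], 0))
        assert fit["Vg1_2"] <= 2 * max(se1, 0.03)
        assert fit["Vg2_2"] <= 2 * max(se2, 0.03)
        assert d_low["Vg1"] > fit["Vg1_2"]

    def test_decomposition_consistency(self, stratified_fit):
        ds, y = stratified_fit
        rng = np.random.default_rng(0)
        groups = np.where(rng.random(ds.n_snps) < 0.5, "low", "high")
        table = pd.DataFrame({"snp": ds.snp_table["snp"],
                              "snp_index": np.arange(ds.n_snps),
                              "group": groups})
        fit2 = cp.two_component_fit(ds, SnpStrata(table, 1), y)
        g = cp.compute_grm(ds, mode="specific")
        from crosspop.pipeline import _stack
        biv, _ = _stack(ds, y, [g.matrix])
        fit1 = cp.reml_fit(biv)
        d1 = cp.derive_rg(fit1)
        d2 = cp.derive_rg(fit2)  # h2 sums over both components
        for pop in (1, 2):
            se = max(d1[f"h2_pop{pop}_se"], d2[f"h2_pop{pop}_se"])
            assert abs(d2[f"h2_pop{pop}"] - d1[f"h2_pop{pop}"]) < 3 * se
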