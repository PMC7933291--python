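"""GWAS scan calibration, clumping traces, split-sample design and r_b."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import crosspop as cp
from crosspop.pipeline import _simulate_polymorphic
from crosspop.simulate import GenotypeDataset
from crosspop.sumstats import _rb


def _dataset_from_genotypes(g, positions=None):
    n, m = g.shape
    snp = pd.DataFrame({
        "snp": [f"s{j + 1}" for j in range(m)], "chrom": 1,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "G",
    })
    sample = pd.DataFrame({
        "fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)],
        "population": 1, "sex": 1, "admix_fraction": 0.0,
    })
    return GenotypeDataset(g.astype(np.int8), snp, sample)


class TestGwasScan:
    def test_null_pvalues_uniform(self, rng):
        n, m = 400, 3000
        g = rng.binomial(2, 0.3, size=(n, m))
        y = rng.standard_normal(n)
        ss = cp.gwas_scan(_dataset_from_genotypes(g), y)
        assert kstest(ss["p"].dropna(), "uniform").pvalue > 0.01

    def test_perfect_fit_limit(self):
        g = np.array([[0], [1], [2], [0], [1], [2]])
        y = 2.0 * g[:, 0].astype(float)
        ss = cp.gwas_scan(_dataset_from_genotypes(g), y)
        assert ss.loc[0, "b"] == pytest.approx(2.0)
        assert ss.loc[0, "se"] == pytest.approx(0.0, abs=1e-12)
        assert ss.loc[0, "p"] < 1e-100

    def test_effect_recovery_against_truth(self):
        model = cp.PopulationModel(n_pop1=800, n_pop2=20, m=300, ld_rho=0.0, seed=17)
        arch = cp.TraitArchitecture(m_causal=30, rg_true=1.0,
                                    h2_pop1=0.8, h2_pop2=0.8)
        ds, y = _simulate_polymorphic(model, arch)
        idx = np.where(ds.population_mask(1))[0]
        ss = cp.gwas_scan(ds, y, sample_index=idx)
        # recover the realized per-allele effects: the simulator scales the
        # standardized effects so var(g) = h2 exactly
        mask = ds.population_mask(1)
        graw = ds.genotypes[mask].astype(float)
        p = graw.mean(axis=0) / 2
        z = (graw - 2 * p) / np.sqrt(2 * p * (1 - p))
        gval = z @ ds.truth["beta_pop1"]
        scale = np.sqrt(arch.h2_pop1 / gval.var(ddof=1))
        beta_true = ds.truth["beta_pop1"] * scale / np.sqrt(2 * p * (1 - p))
        causal = ds.truth["causal_mask"]
        zscores = (ss["b"].to_numpy() - beta_true)[causal] / ss["se"].to_numpy()[causal]
        assert np.mean(np.abs(zscores) < 3) >= 0.9

    def test_covariate_projection(self, rng):
        n = 300
        cov = rng.standard_normal(n)
        g = rng.binomial(2, 0.4, size=(n, 5))
        y = 2.0 * cov + rng.standard_normal(n)
        ss_adj = cp.gwas_scan(_dataset_from_genotypes(g), y, covariates=cov[:, None])
        assert (ss_adj["p"] > 1e-4).all()  # nothing should look associated

    def test_monomorphic_skipped(self, rng):
        g = np.column_stack([np.ones(100), rng.binomial(2, 0.5, 100)])
        ss = cp.gwas_scan(_dataset_from_genotypes(g), rng.standard_normal(100))
        assert np.isnan(ss.loc[0, "b"]) and np.isfinite(ss.loc[1, "b"])


class TestClump:
    def _ld_trio(self, rng):
        """s1 and s3 in LD (r2 ~ 0.5) 100 kb apart, s2 isolated at 5 Mb."""
        n = 400
        x1 = rng.binomial(2, 0.5, n)
        # construct a partner with r2 ~ 0.5 by copying with noise
        flip = rng.random(n) < 0.35
        x3 = np.where(flip, rng.binomial(2, 0.5, n), x1)
        x2 = rng.binomial(2, 0.5, n)
        g = np.column_stack([x1, x3, x2])
        ds = _dataset_from_genotypes(g, np.array([100_000, 200_000, 5_000_000]))
        ds.snp_table["snp"] = ["s1", "s3", "s2"]
        return ds

    def test_hand_worked_greedy_trace(self, rng):
        ds = self._ld_trio(rng)
        ss = pd.DataFrame({
            "SNP": ["s1", "s2", "s3"], "A1": "G", "A2": "A",
            "freq": 0.5, "b": 0.1, "se": 0.01,
            "p": [1e-10, 1e-9, 1e-12], "N": 400,
        })
        sent = cp.clump(ss, ds, p_threshold=5e-8, r2_threshold=0.01, window_kb=1000)
        # s3 (smallest p) absorbs s1; s2 is its own sentinel
        assert sent.sentinels == ["s3", "s2"]
        assert set(sent.clumps["s3"]) == {"s3", "s1"}

    def test_all_independent_all_sentinels(self, rng):
        g = rng.binomial(2, 0.5, size=(300, 4))
        ds = _dataset_from_genotypes(g, np.arange(4) * 10_000_000)
        ss = pd.DataFrame({
            "SNP": [f"s{j}" for j in (1, 2, 3, 4)], "A1": "G", "A2": "A",
            "freq": 0.5, "b": 0.1, "se": 0.01,
            "p": [1e-9, 1e-10, 0.5, 1e-11], "N": 300,
        })
        sent = cp.clump(ss, ds, p_threshold=5e-8)
        assert set(sent.sentinels) == {"s1", "s2", "s4"}  # s3 fails threshold

    def test_two_round_removes_long_range_ld(self, rng):
        # two sentinels 5 Mb apart with r2 just above 0.01: round 1 (1 Mb)
        # keeps both, round 2 (10 Mb) drops the weaker
        n = 2000
        x1 = rng.binomial(2, 0.5, n)
        flip = rng.random(n) < 0.88
        x2 = np.where(flip, rng.binomial(2, 0.5, n), x1)
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert 0.01 < r2 < 0.05
        ds = _dataset_from_genotypes(np.column_stack([x1, x2]),
                                     np.array([1_000_000, 6_000_000]))
        ss = pd.DataFrame({
            "SNP": ["s1", "s2"], "A1": "G", "A2": "A", "freq": 0.5,
            "b": 0.1, "se": 0.01, "p": [1e-12, 1e-9], "N": n,
        })
        round1 = cp.clump(ss, ds, window_kb=1000)
        assert set(round1.sentinels) == {"s1", "s2"}
        both = cp.clump_two_round(ss, ds, window_kb=1000, window2_kb=10_000)
        assert both.sentinels == ["s1"]

    def test_row_order_invariance(self, rng):
        ds = self._ld_trio(rng)
        ss = pd.DataFrame({
            "SNP": ["s1", "s2", "s3"], "A1": "G", "A2": "A",
            "freq": 0.5, "b": 0.1, "se": 0.01,
            "p": [1e-10, 1e-9, 1e-12], "N": 400,
        })
        a = cp.clump(ss, ds).sentinels
        b = cp.clump(ss.iloc[[2, 0, 1]].reset_index(drop=True), ds).sentinels
        assert a == b


class TestSplitSample:
    def test_disjoint_exhaustive_deterministic(self, small_dataset):
        ds, y = small_dataset
        r1 = np.random.default_rng(4)
        ss_d, ss_e, idx_d, idx_e = cp.split_sample_reestimate(ds, y, 0.5, r1, population=1)
        pool = np.where(ds.population_mask(1))[0]
        assert len(np.intersect1d(idx_d, idx_e)) == 0
        np.testing.assert_array_equal(np.sort(np.r_[idx_d, idx_e]), pool)
        r2 = np.random.default_rng(4)
        _, _, idx_d2, _ = cp.split_sample_reestimate(ds, y, 0.5, r2, population=1)
        np.testing.assert_array_equal(idx_d, idx_d2)

    def test_winners_curse_shrinkage(self):
        model = cp.PopulationModel(n_pop1=1200, n_pop2=20, m=400, ld_rho=0.0, seed=23)
        arch = cp.TraitArchitecture(m_causal=60, rg_true=1.0, h2_pop1=0.6, h2_pop2=0.6)
        ds, y = _simulate_polymorphic(model, arch)
        rng = np.random.default_rng(0)
        ss_d, ss_e, idx_d, _ = cp.split_sample_reestimate(ds, y, 0.5, rng, population=1)
        # sentinels selected for significance in the discovery half
        top = ss_d.nsmallest(20, "p")["SNP"]
        bd = ss_d.set_index("SNP").loc[top, "b"].abs().mean()
        be = ss_e.set_index("SNP").loc[top, "b"].abs().mean()
        assert be < bd  # re-estimated effects shed the winner's-curse bias


class TestRb:
    def _pairs(self, k, r_true, se_a, se_b, rng):
        b = rng.standard_normal(k) * 0.1
        b2 = r_true * b + np.sqrt(1 - r_true**2) * rng.standard_normal(k) * 0.1
        obs_a = b + rng.standard_normal(k) * se_a
        obs_b = b2 + rng.standard_normal(k) * se_b
        ids = [f"s{j}" for j in range(k)]
        mk = lambda bb, se: pd.DataFrame({
            "SNP": ids, "A1": "G", "A2": "A", "freq": 0.5,
            "b": bb, "se": se, "p": 0.5, "N": 1000,
        })
        return mk(obs_a, np.full(k, se_a)), mk(obs_b, np.full(k, se_b)), ids

    def test_noise_free_identity(self, rng):
        a, b, ids = self._pairs(50, 1.0, 1e-8, 1e-8, rng)
        b["b"] = a["b"]
        r, se = cp.rb_estimate(a, b, ids)
        assert r == pytest.approx(1.0, abs=1e-4)
        assert se < 1e-4

    def test_error_correction_removes_attenuation(self, rng):
        a, b, ids = self._pairs(500, 0.8, 0.05, 0.05, rng)
        naive = np.corrcoef(a["b"], b["b"])[0, 1]
        r, se = cp.rb_estimate(a, b, ids)
        assert naive < r  # attenuation removed
        assert abs(r - 0.8) < 2.5 * se

    def test_independent_effects_near_zero(self, rng):
        a, b, ids = self._pairs(300, 0.0, 0.02, 0.02, rng)
        r, se = cp.rb_estimate(a, b, ids)
        assert abs(r) < 3 * se

    def test_allele_flip_invariance(self, rng):
        a, b, ids = self._pairs(100, 0.7, 0.02, 0.02, rng)
        r1, _ = cp.rb_estimate(a, b, ids)
        flipped = b.copy()
        flipped["A1"], flipped["A2"] = b["A2"], b["A1"]
        flipped["b"] = -b["b"]
        r2, _ = cp.rb_estimate(a, flipped, ids)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_symmetry(self, rng):
        a, b, ids = self._pairs(100, 0.6, 0.03, 0.03, rng)
        r1, s1 = cp.rb_estimate(a, b, ids)
        r2, s2 = cp.rb_estimate(b, a, ids)
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_noise_dominated_undefined(self, rng):
        a, b, ids = self._pairs(50, 0.8, 5.0, 5.0, rng)
        with pytest.raises(ValueError, match="undefined"):
            cp.rb_estimate(a, b, ids)

    def test_too_few_sentinels(self, rng):
        a, b, ids = self._pairs(5, 0.8, 0.01, 0.01, rng)
        with pytest.raises(ValueError, match="sentinels"):
            cp.rb_estimate(a, b, ids)

    def test_jackknife_se_scales_with_k(self, rng):
        ses = []
        for k in (100, 400):
            a, b, ids = self._pairs(k, 1.0, 0.03, 0.03, rng)
            _, se = cp.rb_estimate(a, b, ids)
            ses.append(se)
        assert ses[1] < ses[0]

    def test_negative_control_rejects_identical_inputs(self, rng):
        a, _, ids = self._pairs(50, 1.0, 0.02, 0.02, rng)
        with pytest.raises(ValueError, match="identical"):
            cp.negative_control(a, a.copy(), ids)

    def test_negative_control_near_one(self, rng):
        # two disjoint same-population halves: same truth, independent errors
        a, b, ids = self._pairs(400, 1.0, 0.03, 0.03, rng)
        r, se = cp.negative_control(a, b, ids)
        assert abs(r - 1.0) < 2 * se + 0.02


class TestMaIo:
    def test_round_trip(self, tmp_path, rng):
        df = pd.DataFrame({
            "SNP": ["a", "b"], "A1": ["A", "C"], "A2": ["G", "T"],
            "freq": [0.2, 0.4], "b": [0.01, -0.02], "se": [0.005, 0.006],
            "p": [0.04, 0.001], "N": [1000, 1000],
        })
        path = str(tmp_path / "x.ma")
        cp.write_ma(df, path)
        back = cp.read_ma(path)
        pd.testing.assert_frame_equal(back, df, check_dtype=False)

    def test_missing_column_rejected(self, tmp_path):
        path = str(tmp_path / "bad.ma")
        pd.DataFrame({"SNP": ["a"], "A1": ["A"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            cp.read_ma(path)
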