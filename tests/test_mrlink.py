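import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cismr.genotype_sim import LDMatrix
from cismr.iv_selection import IVSet, cojo_select
from cismr.mrlink import (
    TagSet,
    calibrate_pvalues,
    fit_beta_calibration,
    mrlink_fit,
    mrlink_fit_from_grams,
    select_tags,
)
from cismr.assoc import marginal_scan
from cismr.phenotype_sim import select_causal_sets, simulate_phenotypes


def ivset(indices, betas, ids=None):
    indices = np.asarray(indices)
    if ids is None:
        ids = np.array([f"v{i}" for i in indices], dtype=object)
    k = len(indices)
    return IVSet(
        indices=indices, variant_ids=ids, conditional_beta=np.asarray(betas, float),
        conditional_se=np.full(k, 0.01), conditional_p=np.full(k, 1e-10),
    )


class TestSelectTags:
    def ld(self, r):
        m = r.shape[0]
        ids = np.array([f"v{i}" for i in range(m)], dtype=object)
        return LDMatrix(r=r, variant_ids=ids)

    def test_no_candidates(self):
        ld = self.ld(np.eye(4))
        tags = select_tags(ld, ivset([0], [0.3]))
        assert len(tags) == 0

    def test_near_duplicate_excluded(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.995)  # r^2 = 0.995 > upper window
        r[0, 2] = r[2, 0] = np.sqrt(0.5)
        tags = select_tags(self.ld(r), ivset([0], [0.3]))
        assert list(tags.indices) == [2]

    def test_mutual_high_ld_pruned(self):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = np.sqrt(0.6)
        r[0, 2] = r[2, 0] = np.sqrt(0.5)
        r[1, 2] = r[2, 1] = np.sqrt(0.98)  # candidates 1, 2 nearly duplicate
        tags = select_tags(self.ld(r), ivset([0], [0.3]))
        assert len(tags) == 1 and tags.indices[0] in (1, 2)

    def test_window_satisfied(self, small_cache):
        arch = select_causal_sets(small_cache.ld_ref, 3, mode="overlap", seed=0)
        ivs = ivset(arch.s_E, arch.beta_E[arch.s_E])
        tags = select_tags(small_cache.ld_ref, ivs)
        r2 = small_cache.ld_ref.r2
        assert len(np.intersect1d(tags.indices, ivs.indices)) == 0
        for t in tags.indices:
            assert 0.1 < r2[ivs.indices, t].max() < 0.99
        if len(tags) > 1:
            sub = r2[np.ix_(tags.indices, tags.indices)].copy()
            np.fill_diagonal(sub, 0)
            assert sub.max() < 0.95


class TestMrlinkFit:
    def test_lambda_zero_no_tags_is_ols(self, small_cache):
        """With no penalty and no tags the fit is simple OLS on the predictor."""
        G = small_cache.G_out
        rng = np.random.default_rng(3)
        y = rng.normal(size=G.n_individuals)
        ivs = ivset([5], [0.4])
        res = mrlink_fit(G, y, ivs, TagSet(np.array([]), np.array([])), lam=0.0)
        x = G.standardized()[:, 5].astype(float) * 0.4  # predictor, m_E = 1
        xc = x - x.mean()
        yc = y - y.mean()
        slope = xc @ yc / (xc @ xc)
        assert res.estimate == pytest.approx(slope, rel=1e-10)
        resid = yc - slope * xc
        se = np.sqrt(resid @ resid / (len(y) - 1) / (xc @ xc))
        assert res.se == pytest.approx(se, rel=1e-6)

    def test_gram_path_matches_explicit(self, small_cache):
        G = small_cache.G_out
        rng = np.random.default_rng(4)
        y = rng.normal(size=G.n_individuals)
        arch = select_causal_sets(small_cache.ld_ref, 2, mode="overlap", seed=1)
        ivs = ivset(arch.s_E, arch.beta_E[arch.s_E])
        tags = select_tags(small_cache.ld_ref, ivs)
        explicit = mrlink_fit(G, y, ivs, tags, lam=0.1)
        X = G.standardized().astype(np.float64)
        yc = y - y.mean()
        fast = mrlink_fit_from_grams(
            X.T @ X, X.T @ yc, float(yc @ yc), G.n_individuals, ivs, tags, lam=0.1
        )
        assert fast.estimate == pytest.approx(explicit.estimate, rel=1e-6)
        assert fast.se == pytest.approx(explicit.se, rel=1e-6)
        assert fast.p_raw == pytest.approx(explicit.p_raw, rel=1e-6)

    def test_no_ivs_status(self, small_cache):
        empty = IVSet(np.array([]), np.array([]), np.array([]), np.array([]), np.array([]))
        res = mrlink_fit(
            small_cache.G_out, np.zeros(small_cache.G_out.n_individuals) + 1e-9,
            empty, TagSet(np.array([]), np.array([])),
        )
        assert res.status == "too_few_ivs"

    def test_parameter_recovery(self, small_cache):
        """In the identifiable (tag-free, unpenalized) limit the estimate
        recovers the causal effect on the per-SD-exposure scale; the full
        tagged ridge model keeps the sign but attenuates towards zero, since
        tags are collinear with the genetic exposure predictor."""
        ols_est, full_est, sd_yE = [], [], []
        for seed in range(25):
            arch = select_causal_sets(small_cache.ld_ref, 3, mode="ld", seed=seed)
            ph_exp = simulate_phenotypes(small_cache.G_exp, arch, 0.4, 0.0, seed=seed)
            ph_out = simulate_phenotypes(small_cache.G_out, arch, 0.4, 0.0, seed=1000 + seed)
            stats = marginal_scan(small_cache.G_exp, ph_exp.y_E)
            ivs = cojo_select(stats, small_cache.ld_ref, p_threshold=1e-5)
            if len(ivs) == 0:
                continue
            sd_yE.append(ph_exp.y_E.std())
            no_tags = TagSet(np.array([], dtype=int), np.array([]))
            ols_est.append(
                mrlink_fit(small_cache.G_out, ph_out.y_O, ivs, no_tags, lam=0.0).estimate
            )
            tags = select_tags(small_cache.ld_ref, ivs)
            res = mrlink_fit(small_cache.G_out, ph_out.y_O, ivs, tags, lam=0.1)
            if res.status == "ok":
                full_est.append(res.estimate)
        assert len(ols_est) >= 10
        # conditional betas are per SD of exposure, so the recovered effect is
        # b_E * sd(y_E); winner's curse at this small n attenuates mildly
        expected = 0.4 * np.median(sd_yE)
        assert np.median(ols_est) == pytest.approx(expected, abs=0.15)
        assert np.median(full_est) > 0.0


class TestCalibration:
    def test_uniform_null_is_identity(self, rng):
        null_p = rng.uniform(size=4000)
        a, b = fit_beta_calibration(null_p)
        assert a == pytest.approx(1.0, abs=0.08)
        assert b == pytest.approx(1.0, abs=0.08)
        p = np.array([0.01, 0.2, 0.5, 0.9])
        assert np.allclose(calibrate_pvalues(null_p, p), p, atol=0.03)

    def test_probability_integral_transform(self, rng):
        """Fresh draws from the fitted null become uniform after calibration."""
        null_p = rng.beta(2, 5, size=3000)
        fresh = rng.beta(2, 5, size=1500)
        cal = calibrate_pvalues(null_p, fresh)
        assert sps.kstest(cal, "uniform").pvalue > 0.01

    def test_boundary_and_monotonicity(self, rng):
        null_p = rng.beta(0.7, 1.3, size=500)
        assert calibrate_pvalues(null_p, 1.0) == 1.0
        grid = np.linspace(0.001, 0.999, 50)
        cal = calibrate_pvalues(null_p, grid)
        assert np.all(np.diff(cal) >= 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_beta_calibration(np.array([]))
        with pytest.raises(ValueError):
            fit_beta_calibration(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            calibrate_pvalues(np.array([0.2, 0.4]), 1.5)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.001, max_value=0.999))
    def test_calibrated_in_unit_interval(self, p_raw):
        null_p = np.linspace(0.01, 0.99, 200)
        cal = calibrate_pvalues(null_p, p_raw)
        assert 0 < cal <= 1
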