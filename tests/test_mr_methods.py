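import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cismr.assoc import SummaryStats
from cismr.genotype_sim import LDMatrix
from cismr.iv_selection import IVSet
from cismr.mr_methods import (
    MIN_IVS,
    HarmonizedIVData,
    harmonize,
    ivw,
    lda_mr_egger,
    mr_egger,
    mr_presso,
)


def make_data(beta_exp, beta_out, se_exp=None, se_out=None, ld=None):
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    k = len(beta_exp)
    return HarmonizedIVData(
        variant_ids=np.array([f"v{i}" for i in range(k)], dtype=object),
        beta_exp=beta_exp,
        se_exp=np.full(k, 0.02) if se_exp is None else np.asarray(se_exp, float),
        beta_out=beta_out,
        se_out=np.full(k, 0.05) if se_out is None else np.asarray(se_out, float),
        eaf=np.full(k, 0.3),
        ld=np.eye(k) if ld is None else np.asarray(ld, float),
    )


def stats_table(ids, a1, a2, b, se=0.02, freq=0.3, n=5000):
    k = len(ids)
    return SummaryStats(
        table=pd.DataFrame(
            {
                "SNP": ids, "A1": a1, "A2": a2, "freq": freq,
                "b": b, "se": se, "p": 1e-10, "N": n, "valid": True,
            }
        )
    )


class TestHarmonize:
    def ivs(self, ids):
        k = len(ids)
        return IVSet(
            indices=np.arange(k), variant_ids=np.array(ids, dtype=object),
            conditional_beta=np.ones(k), conditional_se=np.ones(k),
            conditional_p=np.full(k, 1e-9),
        )

    def test_negative_exposure_flipped(self):
        exp = stats_table(["v0"], ["A"], ["G"], [-0.3])
        out = stats_table(["v0"], ["A"], ["G"], [0.1])
        data = harmonize(exp, out, self.ivs(["v0"]))
        assert data.beta_exp[0] == pytest.approx(0.3)
        assert data.beta_out[0] == pytest.approx(-0.1)
        assert data.eaf[0] == pytest.approx(0.7)

    def test_positive_unchanged_and_allele_swap(self):
        exp = stats_table(["v0", "v1"], ["A", "C"], ["G", "T"], [0.2, 0.4])
        out = stats_table(["v0", "v1"], ["A", "T"], ["G", "C"], [0.1, 0.2])
        data = harmonize(exp, out, self.ivs(["v0", "v1"]))
        assert data.beta_out[0] == pytest.approx(0.1)  # same orientation
        assert data.beta_out[1] == pytest.approx(-0.2)  # swapped alleles flipped

    def test_incompatible_alleles_error(self):
        exp = stats_table(["v0"], ["A"], ["G"], [0.2])
        out = stats_table(["v0"], ["C"], ["T"], [0.1])
        with pytest.raises(ValueError, match="v0"):
            harmonize(exp, out, self.ivs(["v0"]))


class TestIVW:
    def test_single_iv_ratio(self):
        res = ivw(make_data([0.5], [0.2]))
        assert res.estimate == pytest.approx(0.4)

    def test_two_identical_ivs_shrink_se(self):
        one = ivw(make_data([0.5], [0.2]))
        two = ivw(make_data([0.5, 0.5], [0.2, 0.2]))
        assert two.estimate == pytest.approx(one.estimate)
        assert two.se == pytest.approx(one.se / np.sqrt(2))

    def test_three_iv_hand_computed(self):
        """Weighted mean with the two-term SEs, computed by hand."""
        bE = np.array([0.3, 0.5, 0.4])
        bO = np.array([0.12, 0.21, 0.15])
        seE = np.array([0.02, 0.03, 0.025])
        seO = np.array([0.05, 0.04, 0.06])
        ratios = bO / bE
        var = seO**2 / bE**2 + bO**2 * seE**2 / bE**4
        w = 1 / var
        expect = np.sum(w * ratios) / np.sum(w)
        res = ivw(make_data(bE, bO, se_exp=seE, se_out=seO))
        assert res.estimate == pytest.approx(expect)
        assert res.se == pytest.approx(1 / np.sqrt(np.sum(w)))

    def test_zero_exposure_effect_error(self):
        with pytest.raises(ValueError):
            ivw(make_data([0.0], [0.1]))


class TestEgger:
    def test_exact_line(self):
        bE = np.array([0.2, 0.4, 0.6, 0.8])
        res = mr_egger(make_data(bE, 0.4 * bE))
        assert res.estimate == pytest.approx(0.4, abs=1e-10)
        assert res.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_intercept_shift_invariance(self):
        bE = np.array([0.2, 0.4, 0.6, 0.8])
        base = mr_egger(make_data(bE, 0.4 * bE))
        shifted = mr_egger(make_data(bE, 0.4 * bE + 0.1))
        assert shifted.estimate == pytest.approx(base.estimate, abs=1e-10)
        assert shifted.extras["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_wls_oracle(self, rng):
        bE = np.array([0.2, 0.5, 0.7, 0.9])
        bO = np.array([0.05, 0.25, 0.2, 0.42])
        seO = np.array([0.03, 0.06, 0.04, 0.05])
        res = mr_egger(make_data(bE, bO, se_out=seO))
        fit = sm.WLS(bO, sm.add_constant(bE), weights=1 / seO**2).fit()
        assert res.estimate == pytest.approx(fit.params[1])
        assert res.se == pytest.approx(fit.bse[1])

    def test_too_few_ivs(self):
        res = mr_egger(make_data([0.3, 0.4], [0.1, 0.2]))
        assert res.status == "too_few_ivs"


class TestLDAEgger:
    def test_identity_ld_reduces_to_wls(self):
        bE = np.array([0.2, 0.5, 0.7, 0.9])
        bO = np.array([0.05, 0.25, 0.2, 0.42])
        seO = np.array([0.03, 0.06, 0.04, 0.05])
        gls = lda_mr_egger(make_data(bE, bO, se_out=seO))
        wls = mr_egger(make_data(bE, bO, se_out=seO))
        assert gls.estimate == pytest.approx(wls.estimate)
        assert gls.se == pytest.approx(wls.se)

    def test_gls_oracle_with_correlation(self):
        bE = np.array([0.3, 0.5, 0.8])
        bO = np.array([0.1, 0.22, 0.3])
        seO = np.array([0.05, 0.04, 0.06])
        R = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]])
        res = lda_mr_egger(make_data(bE, bO, se_out=seO, ld=R))
        # explicit GLS: (W' S^-1 W)^-1 W' S^-1 y
        S = np.diag(seO) @ R @ np.diag(seO)
        W = np.column_stack([np.ones(3), bE])
        Sinv = np.linalg.inv(S)
        coef = np.linalg.solve(W.T @ Sinv @ W, W.T @ Sinv @ bO)
        assert res.estimate == pytest.approx(coef[1])

    def test_singular_ld_no_solution(self):
        R = np.array([[1, 1.0, 0.2], [1.0, 1, 0.2], [0.2, 0.2, 1.0]])
        res = lda_mr_egger(make_data([0.3, 0.3, 0.5], [0.1, 0.1, 0.2], ld=R))
        assert res.status == "no_solution"


class TestPresso:
    def test_homogeneous_equals_ivw(self, rng):
        bE = rng.uniform(0.3, 0.8, size=6)
        bO = 0.3 * bE + rng.normal(0, 0.02, size=6)
        data = make_data(bE, bO)
        res = mr_presso(data, n_sim=500, seed=1)
        assert res.status == "ok"
        assert res.extras["n_outliers"] == 0
        assert res.estimate == pytest.approx(ivw(data).estimate)

    def test_outlier_removed(self, rng):
        """One deviant IV among eight consistent ones is flagged and dropped;
        the estimate then equals IVW on the consistent subset.  The outlier
        must not dominate the leave-one-out fits, else every IV looks deviant
        (the documented too-many-outliers failure mode, tested below)."""
        bE = np.array([0.3, 0.4, 0.5, 0.6, 0.7, 0.5, 0.45, 0.55, 0.5])
        bO = 0.3 * bE
        bO[-1] += 0.6
        res = mr_presso(make_data(bE, bO), n_sim=800, seed=2)
        assert res.status == "ok"
        assert res.extras["n_outliers"] == 1
        clean = make_data(bE[:-1], bO[:-1])
        assert res.estimate == pytest.approx(ivw(clean).estimate, rel=1e-6)

    def test_mutually_inconsistent_too_many_outliers(self):
        bE = np.array([0.5, 0.5, 0.5])
        bO = np.array([2.0, -2.0, 0.0])
        res = mr_presso(
            make_data(bE, bO, se_out=np.full(3, 0.01)), n_sim=800,
            outlier_alpha=0.9, seed=3,
        )
        assert res.status == "too_many_outliers"

    def test_too_few_ivs(self):
        res = mr_presso(make_data([0.3, 0.4], [0.1, 0.2]))
        assert res.status == "too_few_ivs"


class TestCrossMethodProperties:
    def test_sign_equivariance(self, rng):
        bE = rng.uniform(0.2, 0.9, size=5)
        bO = 0.3 * bE + rng.normal(0, 0.03, size=5)
        R = np.eye(5)
        for fn in (ivw, mr_egger, lda_mr_egger):
            pos = fn(make_data(bE, bO, ld=R))
            neg = fn(make_data(bE, -bO, ld=R))
            assert neg.estimate == pytest.approx(-pos.estimate)
            assert abs(neg.t_statistic) == pytest.approx(abs(pos.t_statistic))

    def test_minimum_iv_applicability_matrix(self):
        """Applicability rules: 1 IV suffices for IVW (and MR-link); the
        Egger family and the outlier test need 3."""
        assert MIN_IVS == {
            "mr_link": 1, "ivw": 1, "lda_mr_egger": 3, "mr_egger": 3, "mr_presso": 3
        }
        two = make_data([0.3, 0.4], [0.1, 0.15])
        assert ivw(two).status == "ok"
        assert mr_egger(two).status == "too_few_ivs"
        assert lda_mr_egger(two).status == "too_few_ivs"
        assert mr_presso(two).status == "too_few_ivs"
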