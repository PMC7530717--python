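"""Two-sample summary-statistics MR estimators used as comparators.

All estimators consume :class:`HarmonizedIVData`: per-IV marginal exposure and
outcome effects aligned so the effect allele is the one with a positive effect
on the exposure, plus the IV LD matrix for the LD-aware Egger variant.

Minimum IV counts are enforced as applicability rules: 1 for IVW, 3 for
MR-Egger, LDA-MR-Egger and MR-PRESSO (which additionally needs at least two
IVs surviving outlier removal).
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from dataclasses import dataclass
from scipy import stats

from .assoc import SummaryStats
from .genotype_sim import LDMatrix
from .iv_selection import IVSet
from .mrlink import MRResult

__all__ = [
    "HarmonizedIVData",
    "harmonize",
    "ivw",
    "mr_egger",
    "lda_mr_egger",
    "mr_presso",
    "MIN_IVS",
]

MIN_IVS = {"mr_link": 1, "ivw": 1, "lda_mr_egger": 3, "mr_egger": 3, "mr_presso": 3}


@dataclass
class HarmonizedIVData:
    """Per-IV effects with a common effect-allele orientation.

    After harmonization every exposure effect is positive; outcome effects,
    allele frequencies and the signs of the IV LD correlations are flipped
    jointly with the exposure alleles.
    """

    variant_ids: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray
    ld: np.ndarray  # signed correlation matrix over the IVs

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.ld = np.asarray(self.ld, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.beta_exp)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ivs: IVSet,
    ld: LDMatrix | None = None,
) -> HarmonizedIVData:
    """Align exposure/outcome records at the IVs to a common effect allele.

    Records are matched by variant id.  If the outcome's allele pair is the
    flip of the exposure's, the outcome effect and frequency are flipped to
    the exposure orientation; incompatible allele pairs raise a ``ValueError``
    naming the variant.  Finally both effects are re-signed so every exposure
    effect is positive, and the IV LD correlations are re-signed to match.
    """
    exp_ix = {v: i for i, v in enumerate(exposure.variant_ids)}
    out_ix = {v: i for i, v in enumerate(outcome.variant_ids)}
    et, ot = exposure.table, outcome.table

    rows = []
    for vid in ivs.variant_ids:
        if vid not in exp_ix or vid not in out_ix:
            raise KeyError(f"IV {vid!r} missing from exposure or outcome statistics")
        i, j = exp_ix[vid], out_ix[vid]
        ea1, ea2 = et["A1"].iat[i], et["A2"].iat[i]
        oa1, oa2 = ot["A1"].iat[j], ot["A2"].iat[j]
        b_o, f_o = ot["b"].iat[j], ot["freq"].iat[j]
        if (oa1, oa2) == (ea1, ea2):
            pass
        elif (oa1, oa2) == (ea2, ea1):
            b_o, f_o = -b_o, 1.0 - f_o
        else:
            raise ValueError(
                f"allele mismatch at {vid!r}: exposure {ea1}/{ea2} vs outcome {oa1}/{oa2}"
            )
        rows.append(
            (vid, et["b"].iat[i], et["se"].iat[i], b_o, ot["se"].iat[j], et["freq"].iat[i])
        )

    vid_a = np.array([r[0] for r in rows], dtype=object)
    b_e = np.array([r[1] for r in rows])
    se_e = np.array([r[2] for r in rows])
    b_o = np.array([r[3] for r in rows])
    se_o = np.array([r[4] for r in rows])
    eaf = np.array([r[5] for r in rows])

    sign = np.where(b_e < 0, -1.0, 1.0)
    b_e, b_o = b_e * sign, b_o * sign
    eaf = np.where(sign < 0, 1.0 - eaf, eaf)

    if ld is not None:
        pos = {v: i for i, v in enumerate(ld.variant_ids)}
        order = np.array([pos[v] for v in vid_a])
        R = ld.r[np.ix_(order, order)] * np.outer(sign, sign)
    else:
        R = np.eye(len(vid_a))
    return HarmonizedIVData(
        variant_ids=vid_a, beta_exp=b_e, se_exp=se_e, beta_out=b_o,
        se_out=se_o, eaf=eaf, ld=R,
    )


def _wald_ratios(
    data: HarmonizedIVData, compat_printed_formulas: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-IV Wald ratios and their two-term standard errors.

    The default is the standard form: ratio ``beta_O / beta_E`` with
    ``se^2 = se_O^2/beta_E^2 + beta_O^2 se_E^2 / beta_E^4``.  The
    ``compat_printed_formulas`` flag reproduces an inverted-ratio variant
    (ratio ``beta_E / beta_O``; second term with denominator ``beta_E^2``)
    kept only for auditability.
    """
    bE, bO = data.beta_exp, data.beta_out
    if np.any(bE == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    if compat_printed_formulas:
        ratio = bE / bO
        var = data.se_out**2 / bE**2 + bO**2 * data.se_exp**2 / bE**2
    else:
        ratio = bO / bE
        var = data.se_out**2 / bE**2 + bO**2 * data.se_exp**2 / bE**4
    return ratio, np.sqrt(var)


def ivw(data: HarmonizedIVData, compat_printed_formulas: bool = False) -> MRResult:
    """Inverse-variance-weighted fixed-effects meta-analysis of Wald ratios."""
    k = len(data)
    if k < MIN_IVS["ivw"]:
        return MRResult(method="ivw", n_ivs=k, status="too_few_ivs")
    ratio, se_r = _wald_ratios(data, compat_printed_formulas)
    w = 1.0 / se_r**2
    est = float(np.sum(w * ratio) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    t = est / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(t)), np.finfo(float).tiny, 1.0))
    return MRResult(
        method="ivw", estimate=est, se=se, t_statistic=t, p_raw=p, n_ivs=k, status="ok"
    )


def mr_egger(data: HarmonizedIVData) -> MRResult:
    """Egger regression: WLS of outcome on exposure effects with intercept.

    The slope estimates the causal effect; the intercept estimates average
    directional pleiotropy.  Weights are 1/se_O^2.
    """
    k = len(data)
    if k < MIN_IVS["mr_egger"]:
        return MRResult(method="mr_egger", n_ivs=k, status="too_few_ivs")
    X = sm.add_constant(data.beta_exp)
    fit = sm.WLS(data.beta_out, X, weights=1.0 / data.se_out**2).fit()
    return MRResult(
        method="mr_egger",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_statistic=float(fit.tvalues[1]),
        p_raw=float(np.clip(fit.pvalues[1], np.finfo(float).tiny, 1.0)),
        n_ivs=k,
        status="ok",
        extras={
            "intercept": float(fit.params[0]),
            "intercept_se": float(fit.bse[0]),
            "intercept_p": float(fit.pvalues[0]),
        },
    )


def lda_mr_egger(data: HarmonizedIVData) -> MRResult:
    """LD-aware Egger regression: GLS with error covariance D R D.

    R is the signed IV LD matrix and D = diag(se_O), so correlated IVs are
    down-weighted jointly rather than treated as independent evidence.
    """
    k = len(data)
    if k < MIN_IVS["lda_mr_egger"]:
        return MRResult(method="lda_mr_egger", n_ivs=k, status="too_few_ivs")
    D = np.diag(data.se_out)
    sigma = D @ data.ld @ D
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return MRResult(method="lda_mr_egger", n_ivs=k, status="no_solution")
    X = sm.add_constant(data.beta_exp)
    fit = sm.GLS(data.beta_out, X, sigma=sigma).fit()
    return MRResult(
        method="lda_mr_egger",
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_statistic=float(fit.tvalues[1]),
        p_raw=float(np.clip(fit.pvalues[1], np.finfo(float).tiny, 1.0)),
        n_ivs=k,
        status="ok",
        extras={"intercept": float(fit.params[0]), "intercept_se": float(fit.bse[0])},
    )


def _loo_ivw_slopes(bE: np.ndarray, bO: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out slopes of the weighted through-origin IVW regression."""
    sw_xy = np.sum(w * bE * bO)
    sw_xx = np.sum(w * bE**2)
    return (sw_xy - w * bE * bO) / (sw_xx - w * bE**2)


def mr_presso(
    data: HarmonizedIVData,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> MRResult:
    """Outlier-robust IVW: detect and drop pleiotropic IVs, then re-estimate.

    The global test compares the observed weighted residual sum of squares of
    the IVs around their leave-one-out IVW fits against a parametric null in
    which effects are redrawn from their standard errors (``n_sim``
    replicates).  Per-IV outlier p-values use the same simulations; IVs are
    flagged at ``outlier_alpha`` Bonferroni-corrected for the IV count.  The
    returned estimate is IVW on the surviving IVs (identical to plain IVW
    when nothing is flagged); fewer than two survivors yields status
    ``too_many_outliers``.
    """
    k = len(data)
    if k < MIN_IVS["mr_presso"]:
        return MRResult(method="mr_presso", n_ivs=k, status="too_few_ivs")
    rng = np.random.default_rng(seed)
    bE, seE, bO, seO = data.beta_exp, data.se_exp, data.beta_out, data.se_out
    w = 1.0 / seO**2

    b_loo = _loo_ivw_slopes(bE, bO, w)
    d_obs = w * (bO - b_loo * bE) ** 2
    rss_obs = float(np.sum(d_obs))

    bE_sim = rng.normal(bE, seE, size=(n_sim, k))
    bO_sim = rng.normal(b_loo * bE_sim, seO, size=(n_sim, k))
    # leave-one-out slopes recomputed within each simulated replicate
    sw_xy = (w * bE_sim * bO_sim).sum(axis=1, keepdims=True)
    sw_xx = (w * bE_sim**2).sum(axis=1, keepdims=True)
    b_loo_sim = (sw_xy - w * bE_sim * bO_sim) / (sw_xx - w * bE_sim**2)
    d_sim = w * (bO_sim - b_loo_sim * bE_sim) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(d_sim >= d_obs, axis=0)) / (n_sim + 1)
    flagged = outlier_p < outlier_alpha / k

    keep = ~flagged
    if keep.sum() < 2:
        return MRResult(
            method="mr_presso",
            n_ivs=k,
            status="too_many_outliers",
            extras={"global_p": global_p, "n_outliers": int(flagged.sum())},
        )
    sub = HarmonizedIVData(
        variant_ids=data.variant_ids[keep],
        beta_exp=bE[keep], se_exp=seE[keep],
        beta_out=bO[keep], se_out=seO[keep],
        eaf=data.eaf[keep],
        ld=data.ld[np.ix_(keep.nonzero()[0], keep.nonzero()[0])],
    )
    res = ivw(sub)
    return MRResult(
        method="mr_presso",
        estimate=res.estimate,
        se=res.se,
        t_statistic=res.t_statistic,
        p_raw=res.p_raw,
        n_ivs=int(keep.sum()),
        status="ok",
        extras={"global_p": global_p, "n_outliers": int(flagged.sum()),
                "outlier_p": outlier_p},
    )
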