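"""Causal inference from cis instruments with tag-SNP pleiotropy correction.

The estimator jointly models the outcome phenotype on individual-level data as

    y_O = (X beta_hat_E / m_E) * b_E  +  (X_T / sqrt(m_T)) * gamma  +  eps

where ``X beta_hat_E`` is the genetic exposure predictor built from the
conditional IV effects, and ``X_T`` holds every tag-SNP: a non-IV variant in
moderate LD (0.1 < r^2 < 0.99) with at least one IV, pruned so tags stay at
r^2 < 0.95 with each other.  The tag block is a nuisance term that absorbs
pleiotropic signal carried by variants in LD with the IVs.  The system is
solved by ridge regression; the causal effect b_E gets a Wald test whose
standard error uses the ridge sandwich covariance, and the resulting
(conservative) p-value is calibrated through a beta distribution fitted to
matched null runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .genotype_sim import GenotypeMatrix, LDMatrix, ld_matrix
from .iv_selection import IVSet

__all__ = [
    "TagSet",
    "MRResult",
    "select_tags",
    "mrlink_fit",
    "fit_beta_calibration",
    "calibrate_pvalues",
    "DEFAULT_LAMBDA",
]

# Ridge penalty, expressed relative to the mean diagonal of the design Gram
# matrix (so its strength tracks the per-column signal scale, which for the
# tag block is n / m_T — "small relative to the tag count").  The total
# penalty added to X'X is lambda * mean(diag(X'X)).  Chosen so the null Wald
# statistic is conservative (the beta calibration removes the
# conservativeness) while collinear tags are shrunk enough to keep power;
# see docs/methods.md.
DEFAULT_LAMBDA = 0.1


@dataclass
class TagSet:
    """Tag-SNP indices with each tag's max r^2 against the IV set."""

    indices: np.ndarray
    max_r2_with_iv: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.max_r2_with_iv = np.asarray(self.max_r2_with_iv, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class MRResult:
    """One estimator's causal-effect estimate for one exposure/outcome pair."""

    method: str
    estimate: float = np.nan
    se: float = np.nan
    t_statistic: float = np.nan
    p_raw: float = np.nan
    p_calibrated: float = np.nan
    n_ivs: int = 0
    status: str = "ok"
    extras: dict = field(default_factory=dict)

    @property
    def p(self) -> float:
        """Decision p-value: calibrated when available, else raw."""
        return self.p_calibrated if np.isfinite(self.p_calibrated) else self.p_raw


def select_tags(
    ld_ref: GenotypeMatrix | LDMatrix,
    ivs: IVSet,
    r2_lower: float = 0.1,
    r2_upper: float = 0.99,
    prune_r2: float = 0.95,
) -> TagSet:
    """Pick tag-SNPs: moderate-LD neighbours of the IVs, pruned for high LD.

    Candidates are all non-IV variants whose max r^2 over the IVs lies in
    ``(r2_lower, r2_upper)``; iterating candidates by descending max r^2, a
    candidate is kept iff its r^2 with every already-kept tag is below
    ``prune_r2``.  An empty tag set is legitimate output.
    """
    ld = ld_ref if isinstance(ld_ref, LDMatrix) else ld_matrix(ld_ref)
    r2 = ld.r ** 2
    iv_idx = ivs.indices
    if len(iv_idx) == 0:
        return TagSet(indices=np.array([], dtype=np.int64), max_r2_with_iv=np.array([]))
    max_r2 = r2[iv_idx, :].max(axis=0)
    cand = np.flatnonzero((max_r2 > r2_lower) & (max_r2 < r2_upper))
    cand = np.setdiff1d(cand, iv_idx)
    if cand.size == 0:
        return TagSet(indices=np.array([], dtype=np.int64), max_r2_with_iv=np.array([]))

    order = cand[np.argsort(-max_r2[cand], kind="stable")]
    # greedy prune: walking down by max r^2 with the IVs, a kept candidate
    # knocks out every later candidate at r^2 >= prune_r2 with it
    alive = np.ones(r2.shape[0], dtype=bool)
    kept: list[int] = []
    for j in order:
        if alive[j]:
            kept.append(int(j))
            alive &= r2[j, :] < prune_r2
    kept_arr = np.array(sorted(kept), dtype=np.int64)
    return TagSet(indices=kept_arr, max_r2_with_iv=max_r2[kept_arr])


def _ridge_wald(
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    lam_total: float,
    penalize_exposure: bool = True,
) -> tuple[float, float, float, float, np.ndarray, float]:
    """Ridge solve + sandwich Wald test from sufficient statistics.

    Returns (b, se, t, p, coefficients, df_eff).  The covariance is the
    ridge sandwich  sigma^2 A^-1 X'X A^-1  with A = X'X + lambda I and
    sigma^2 = RSS / (n - tr(A^-1 X'X))  (residual df from the trace of the
    hat matrix).
    """
    p = XtX.shape[0]
    A = XtX + lam_total * np.eye(p)
    if not penalize_exposure:
        A[0, 0] = XtX[0, 0]
    if lam_total > 0:
        cho = linalg.cho_factor(A, check_finite=False)
        solve = lambda B: linalg.cho_solve(cho, B, check_finite=False)
    else:
        solve = lambda B: linalg.solve(A, B, assume_a="sym", check_finite=False)
    theta = solve(Xty)
    Ainv_XtX = solve(XtX)
    df_eff = float(np.trace(np.atleast_2d(Ainv_XtX)))
    rss = float(yty - 2.0 * theta @ Xty + theta @ (XtX @ theta))
    dof = max(n - df_eff, 1.0)
    sigma2 = max(rss, 0.0) / dof
    e0 = np.zeros(p)
    e0[0] = 1.0
    a0 = solve(e0)
    var_b = sigma2 * float(a0 @ (XtX @ a0))
    b = float(theta[0])
    se = float(np.sqrt(max(var_b, 0.0)))
    if se == 0:
        return b, se, np.nan, np.nan, theta, df_eff
    t = b / se
    p_raw = float(np.clip(2.0 * stats.t.sf(abs(t), dof), np.finfo(float).tiny, 1.0))
    return b, se, t, p_raw, theta, df_eff


def mrlink_fit(
    G_out: GenotypeMatrix,
    y_O: np.ndarray,
    ivs: IVSet,
    tags: TagSet,
    lam: float | None = None,
    penalize_exposure: bool = True,
) -> MRResult:
    """Fit the ridge joint model on the outcome cohort and Wald-test b_E.

    ``lam`` is the ridge penalty relative to the mean diagonal of the design
    Gram matrix (default :data:`DEFAULT_LAMBDA`); ``lam=0`` with no tags
    reduces to OLS of the outcome on the genetic exposure predictor.

    The design's exposure column is scaled by 1/m_E, which multiplies its raw
    coefficient by m_E; the reported ``estimate`` and ``se`` are divided back
    by m_E so the estimate reads as outcome units per 1 SD of the (genetically
    predicted) exposure, independent of the IV count.  The Wald statistic is
    unaffected by this rescaling.

    Tag coefficients are returned in ``extras["tag_coefficients"]`` as
    nuisance diagnostics.  The calibrated p-value is left NaN here; apply
    :func:`calibrate_pvalues` with matched null runs to fill it in.
    """
    y = np.asarray(y_O, dtype=np.float64)
    if len(y) != G_out.n_individuals:
        raise ValueError("phenotype length must equal outcome cohort size")
    if len(ivs) == 0:
        return MRResult(method="mr_link", n_ivs=0, status="too_few_ivs")
    lam = DEFAULT_LAMBDA if lam is None else lam
    n = G_out.n_individuals
    m_E = len(ivs)
    m_T = len(tags)

    X = G_out.standardized().astype(np.float64)
    predictor = X[:, ivs.indices] @ ivs.conditional_beta / m_E
    if m_T:
        design = np.column_stack([predictor, X[:, tags.indices] / np.sqrt(m_T)])
    else:
        design = predictor[:, None]
    yc = y - y.mean()
    XtX = design.T @ design
    Xty = design.T @ yc
    yty = float(yc @ yc)
    try:
        b, se, t, p_raw, theta, df_eff = _ridge_wald(
            XtX, Xty, yty, n, lam * float(np.mean(np.diag(XtX))), penalize_exposure
        )
    except np.linalg.LinAlgError:
        return MRResult(method="mr_link", n_ivs=m_E, status="no_solution")
    if not np.isfinite(t):
        return MRResult(method="mr_link", n_ivs=m_E, status="no_solution")
    return MRResult(
        method="mr_link",
        estimate=b / m_E,
        se=se / m_E,
        t_statistic=t,
        p_raw=p_raw,
        n_ivs=m_E,
        status="ok",
        extras={"tag_coefficients": theta[1:], "df_eff": df_eff, "n_tags": m_T},
    )


def mrlink_fit_from_grams(
    gram: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    ivs: IVSet,
    tags: TagSet,
    lam: float | None = None,
    penalize_exposure: bool = True,
) -> MRResult:
    """Fast path of :func:`mrlink_fit` from precomputed sufficient statistics.

    ``gram`` is the full standardized-genotype Gram matrix X'X of the outcome
    cohort and ``Xty`` the vector X'(y - mean(y)); both are reused across
    replicates that share a genotype cohort, so each fit costs only the
    (1 + m_T)-dimensional solve.  Results are identical to building the
    design explicitly.
    """
    if len(ivs) == 0:
        return MRResult(method="mr_link", n_ivs=0, status="too_few_ivs")
    lam = DEFAULT_LAMBDA if lam is None else lam
    m_E = len(ivs)
    m_T = len(tags)
    s = ivs.indices
    beta = ivs.conditional_beta

    c_c = float(beta @ gram[np.ix_(s, s)] @ beta) / m_E**2
    c_y = float(beta @ Xty[s]) / m_E
    if m_T:
        T = tags.indices
        rt = np.sqrt(m_T)
        c_T = (beta @ gram[np.ix_(s, T)]) / m_E / rt
        XtX = np.empty((1 + m_T, 1 + m_T))
        XtX[0, 0] = c_c
        XtX[0, 1:] = c_T
        XtX[1:, 0] = c_T
        XtX[1:, 1:] = gram[np.ix_(T, T)] / m_T
        Xty_full = np.concatenate([[c_y], Xty[T] / rt])
    else:
        XtX = np.array([[c_c]])
        Xty_full = np.array([c_y])
    try:
        b, se, t, p_raw, theta, df_eff = _ridge_wald(
            XtX, Xty_full, yty, n, lam * float(np.mean(np.diag(XtX))), penalize_exposure
        )
    except np.linalg.LinAlgError:
        return MRResult(method="mr_link", n_ivs=m_E, status="no_solution")
    if not np.isfinite(t):
        return MRResult(method="mr_link", n_ivs=m_E, status="no_solution")
    return MRResult(
        method="mr_link",
        estimate=b / m_E,
        se=se / m_E,
        t_statistic=t,
        p_raw=p_raw,
        n_ivs=m_E,
        status="ok",
        extras={"tag_coefficients": theta[1:], "df_eff": df_eff, "n_tags": m_T},
    )


def fit_beta_calibration(null_p: np.ndarray) -> tuple[float, float] | None:
    """Maximum-likelihood Beta(a, b) fit to a sample of null p-values.

    Initialization is by moment matching.  Returns ``None`` when the fit
    degenerates (non-positive shapes or non-finite likelihood inputs), in
    which case callers should fall back to the empirical CDF.
    """
    x = np.asarray(null_p, dtype=np.float64)
    if x.size == 0:
        raise ValueError("need at least one null p-value")
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("null p-values must lie strictly inside (0, 1)")
    try:
        a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    except Exception:
        return None
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return None
    return float(a), float(b)


def calibrate_pvalues(null_p: np.ndarray, p_raw):
    """Calibrate raw p-values through a beta CDF fitted to null p-values.

    The calibrated value is ``CDF_Beta(a, b)(p_raw)`` — the probability
    integral transform under the fitted null distribution — and is monotone
    nondecreasing in ``p_raw``.  If the beta fit degenerates, an
    empirical-CDF calibration is used instead (with a warning).
    """
    p_arr = np.asarray(p_raw, dtype=np.float64)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p_raw must lie in [0, 1]")
    fit = fit_beta_calibration(null_p)
    if fit is None:
        warnings.warn(
            "beta calibration fit degenerated; falling back to the empirical CDF",
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.sort(np.asarray(null_p, dtype=np.float64))
        ranks = np.searchsorted(x, p_arr, side="right")
        out = (ranks + 1) / (x.size + 2)
        out = np.where(p_arr >= 1.0, 1.0, out)
    else:
        a, b = fit
        out = stats.beta.cdf(p_arr, a, b)
        out = np.where(p_arr >= 1.0, 1.0, np.clip(out, np.finfo(float).tiny, 1.0))
    return float(out) if np.isscalar(p_raw) else out
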