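"""Approximate-Bayes-factor colocalization for two quantitative traits.

Implements the original single-causal-variant enumeration: per-variant
Wakefield approximate Bayes factors for each trait, prior-weighted sums over
the five sharing hypotheses, and posterior probabilities PP0-PP4.  PP4 is the
posterior probability that both traits share one causal variant in the region.

Hypotheses: H0 no association; H1/H2 one trait associated; H3 both traits
associated with distinct causal variants; H4 both associated with the same
causal variant.  Default priors are the conventional p1 = p2 = 1e-4 and
p12 = 1e-5 per variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .assoc import SummaryStats

__all__ = ["ColocResult", "coloc_abf", "coloc_decision"]

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: np.ndarray  # [PP0, PP1, PP2, PP3, PP4]
    priors: tuple[float, float, float]
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=np.float64)
        if abs(self.pp.sum() - 1.0) > 1e-8:
            raise ValueError("posterior probabilities must sum to 1")
        if np.any((self.pp < 0) | (self.pp > 1)):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def _estimate_sdY(varbeta: np.ndarray, maf: np.ndarray, n: np.ndarray) -> float:
    """Phenotype SD from summary data, assuming effects on the raw y scale.

    For a simple regression on a genotype with variance 2f(1-f), approximately
    var(beta_j) ~ var(y) / (n * 2 f_j (1 - f_j)); a regression through the
    origin of 1/varbeta on n * 2f(1-f) recovers var(y).
    """
    x = n * 2.0 * maf * (1.0 - maf)
    y = 1.0 / varbeta
    var_y = float(np.sum(x * y) / np.sum(x * x))
    if not np.isfinite(var_y) or var_y <= 0:
        raise ValueError("could not estimate phenotype variance from summary data")
    return float(np.sqrt(var_y))


def _log_abf(
    beta: np.ndarray, se: np.ndarray, sd_prior: float
) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant."""
    V = se**2
    W = sd_prior**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)


def coloc_abf(
    stats1: SummaryStats,
    stats2: SummaryStats,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    sdY_handling: str = "estimate",
    prior_sd_scale: float = 0.15,
    sdY1: float | None = None,
    sdY2: float | None = None,
) -> ColocResult:
    """Colocalization of two quantitative-trait association scans.

    Inputs are marginal effect sizes, standard errors and allele frequencies
    for the variants shared between the two scans.  The per-variant prior
    effect SD is ``prior_sd_scale * sdY`` (0.15 by convention); with
    ``sdY_handling="estimate"`` sdY is recovered from varbeta, MAF and n, and
    with ``"unit"`` the betas are taken as already on a standardized-phenotype
    scale (sdY = 1).  An explicitly known phenotype SD can be passed as
    ``sdY1`` / ``sdY2`` and overrides the handling flag for that trait.
    """
    p1, p2, p12 = priors
    if np.array_equal(stats1.variant_ids, stats2.variant_ids):
        shared = list(stats1.variant_ids)
        i1 = i2 = np.arange(len(shared))
    else:
        shared = [v for v in stats1.variant_ids if v in set(stats2.variant_ids)]
        if not shared:
            raise ValueError("no shared variants between the two scans")
        ix1 = {v: i for i, v in enumerate(stats1.variant_ids)}
        ix2 = {v: i for i, v in enumerate(stats2.variant_ids)}
        i1 = np.array([ix1[v] for v in shared])
        i2 = np.array([ix2[v] for v in shared])

    def trait(stats, idx, sdY):
        b = stats.beta[idx]
        se = stats.se[idx]
        ok = np.isfinite(b) & np.isfinite(se) & (se > 0)
        f = np.minimum(stats.freq[idx], 1 - stats.freq[idx])
        n = stats.n[idx]
        if sdY is None:
            sdY = 1.0 if sdY_handling == "unit" else _estimate_sdY(
                se[ok] ** 2, f[ok], n[ok]
            )
        labf = np.full(len(idx), -np.inf)
        labf[ok] = _log_abf(b[ok], se[ok], prior_sd_scale * sdY)
        return labf

    l1 = trait(stats1, i1, sdY1)
    l2 = trait(stats2, i2, sdY2)

    # log hypothesis sums over single-variant configurations
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + _log_sum_h3(l1, l2, s1, s2, s12),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocResult(
        pp=pp, priors=priors, log_abf1=l1, log_abf2=l2,
        variant_ids=np.asarray(shared, dtype=object),
    )


def _log_sum_h3(l1, l2, s1, s2, s12) -> float:
    """log( sum_{i != j} exp(l1_i + l2_j) ) = log( e^{s1+s2} - e^{s12} )."""
    a, b = s1 + s2, s12
    if a <= b:  # single shared variant: the off-diagonal sum is empty
        return -np.inf
    with np.errstate(over="ignore"):
        return float(a + np.log1p(-np.exp(b - a)))


def coloc_decision(result: ColocResult, threshold: float = 0.9) -> bool:
    """Declare colocalization iff PP4 strictly exceeds the threshold."""
    return result.pp4 > threshold
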