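"""Instrumental-variable selection from summary statistics + an LD reference.

Two selectors are provided:

* :func:`cojo_select` — stepwise conditional-joint selection in the style of
  GCTA-COJO: joint models are reconstructed from marginal statistics and
  reference LD, candidates are admitted when their conditional p-value passes
  the threshold, and the final conditional effects come from the joint fit of
  the selected set.
* :func:`clump_select` — greedy p-value clumping: the best remaining variant
  seeds a clump and removes everything above an r^2 threshold with it.

All joint algebra runs on the standardized (correlation) scale: the marginal
effect of variant j is recovered from its z-score as
``r_j = z_j / sqrt(z_j^2 + n - 2)``, which is exact for a simple regression of
a standardized phenotype on a standardized genotype.  Conditional effects are
therefore reported per 1 SD of genotype, per 1 SD of phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .assoc import SummaryStats
from .genotype_sim import GenotypeMatrix, LDMatrix, ld_matrix

__all__ = ["IVSet", "cojo_select", "clump_select"]

P_THRESHOLD = 5e-8  # genome-wide significance used throughout
_SCHUR_MIN = 1e-3  # ill-conditioned candidate guard


@dataclass
class IVSet:
    """Selected instruments with conditional effect sizes."""

    indices: np.ndarray  # positions in the summary-statistics table
    variant_ids: np.ndarray
    conditional_beta: np.ndarray  # standardized (correlation) scale
    conditional_se: np.ndarray
    conditional_p: np.ndarray
    method: str = "cojo"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.conditional_beta = np.asarray(self.conditional_beta, dtype=np.float64)
        self.conditional_se = np.asarray(self.conditional_se, dtype=np.float64)
        self.conditional_p = np.asarray(self.conditional_p, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.indices)


def _resolve_ld(
    stats: SummaryStats, ld_ref: GenotypeMatrix | LDMatrix
) -> np.ndarray:
    """Correlation matrix over the stats variants, in stats order."""
    if isinstance(ld_ref, LDMatrix):
        ld = ld_ref
    else:
        ld = ld_matrix(ld_ref)
    if len(ld.variant_ids) == len(stats.variant_ids) and np.array_equal(
        ld.variant_ids, stats.variant_ids
    ):
        return ld.r
    pos = {v: i for i, v in enumerate(ld.variant_ids)}
    try:
        order = np.array([pos[v] for v in stats.variant_ids])
    except KeyError as e:
        raise KeyError(f"variant {e.args[0]!r} absent from the LD reference") from e
    return ld.r[np.ix_(order, order)]


def _marginal_r(stats: SummaryStats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r, p, n) arrays with invalid records masked to NaN / p=1."""
    z = stats.beta / stats.se
    n = stats.n
    r = z / np.sqrt(z**2 + np.maximum(n - 2, 1))
    p = stats.p.copy()
    bad = ~np.isfinite(r) | ~np.isfinite(p)
    r[bad] = 0.0
    p[bad] = 1.0
    return r, p, n


def _rank_order(p: np.ndarray, stats: SummaryStats) -> np.ndarray:
    """Ascending-p order with ties broken by position then id."""
    ids = np.array([str(v) for v in stats.variant_ids])
    pos = np.arange(len(p))
    return np.lexsort((ids, pos, p))


def _joint_fit(R: np.ndarray, r_marg: np.ndarray, idx: np.ndarray, n_eff: float):
    """Joint model of the variants ``idx`` from correlations alone.

    Returns (beta, se, p) on the standardized scale, using residual variance
    ``sigma^2 = (1 - r' R^-1 r) * n / (n - k - 1)`` with unit phenotype
    variance.
    """
    Rs = R[np.ix_(idx, idx)]
    rs = r_marg[idx]
    Rinv = np.linalg.inv(Rs)
    beta = Rinv @ rs
    ve = float(rs @ beta)
    dof = n_eff - len(idx) - 1
    sigma2 = max(1.0 - ve, 1e-12) * n_eff / dof
    se = np.sqrt(sigma2 * np.diag(Rinv) / n_eff)
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def cojo_select(
    stats: SummaryStats,
    ld_ref: GenotypeMatrix | LDMatrix,
    p_threshold: float = P_THRESHOLD,
    collinearity_r2: float = 0.9,
) -> IVSet:
    """Stepwise conditional-joint selection of instruments.

    Starting from the smallest-p variant, each step evaluates every remaining
    candidate in a joint model with the current selection (reconstructed from
    reference LD and marginal statistics) and admits the candidate with the
    smallest conditional p-value, provided it passes ``p_threshold`` and its
    r^2 with every selected variant stays below ``collinearity_r2``.  The
    returned conditional effects come from the final joint fit.
    """
    R = _resolve_ld(stats, ld_ref)
    r_marg, p_marg, n_arr = _marginal_r(stats)
    m = len(r_marg)
    order = _rank_order(p_marg, stats)
    if p_marg[order[0]] >= p_threshold:
        return _empty_ivset("cojo")

    selected = [int(order[0])]
    while True:
        S = np.array(selected)
        n_eff = float(np.min(n_arr[S]))
        Rs_inv = np.linalg.inv(R[np.ix_(S, S)])
        rs = r_marg[S]

        cand = np.setdiff1d(np.arange(m), S)
        if cand.size == 0:
            break
        Rcs = R[np.ix_(S, cand)]  # |S| x c
        ok = (Rcs**2).max(axis=0) < collinearity_r2
        cand, Rcs = cand[ok], Rcs[:, ok]
        if cand.size == 0:
            break

        U = Rs_inv @ Rcs  # |S| x c
        schur = 1.0 - np.einsum("ij,ij->j", Rcs, U)
        well = schur > _SCHUR_MIN
        if not well.all():
            warnings.warn(
                "dropping ill-conditioned joint candidates during stepwise selection",
                RuntimeWarning,
                stacklevel=2,
            )
        cand, Rcs, U, schur = cand[well], Rcs[:, well], U[:, well], schur[well]
        if cand.size == 0:
            break

        b_cond = (r_marg[cand] - rs @ U) / schur
        ve_base = float(rs @ (Rs_inv @ rs))
        ve = ve_base + b_cond**2 * schur
        n_c = np.minimum(n_arr[cand], n_eff)
        dof = n_c - (len(S) + 1) - 1
        sigma2 = np.maximum(1.0 - ve, 1e-12) * n_c / dof
        se_cond = np.sqrt(sigma2 / (n_c * schur))
        t = b_cond / se_cond
        p_cond = 2.0 * sps.t.sf(np.abs(t), dof)

        best = np.lexsort((cand, p_cond))[0]  # ties broken by variant position
        if p_cond[best] < p_threshold:
            selected.append(int(cand[best]))
        else:
            break

    S = np.array(sorted(selected))
    n_eff = float(np.min(n_arr[S]))
    beta, se, p = _joint_fit(R, r_marg, S, n_eff)
    return IVSet(
        indices=S,
        variant_ids=stats.variant_ids[S],
        conditional_beta=beta,
        conditional_se=se,
        conditional_p=p,
        method="cojo",
    )


def clump_select(
    stats: SummaryStats,
    ld_ref: GenotypeMatrix | LDMatrix,
    p_threshold: float = P_THRESHOLD,
    r2_threshold: float = 0.1,
) -> IVSet:
    """Greedy p-value clumping.

    Repeatedly takes the smallest-p unassigned significant variant as an index
    IV and removes every variant with r^2 above ``r2_threshold`` with it.
    Conditional effects are the marginal effects (no joint fit is performed),
    reported on the standardized scale for consistency with
    :func:`cojo_select`.
    """
    R = _resolve_ld(stats, ld_ref)
    r_marg, p_marg, n_arr = _marginal_r(stats)
    order = _rank_order(p_marg, stats)

    available = np.ones(len(p_marg), dtype=bool)
    picked: list[int] = []
    for j in order:
        if p_marg[j] >= p_threshold:
            break
        if not available[j]:
            continue
        picked.append(int(j))
        available &= R[j, :] ** 2 <= r2_threshold
        available[j] = False

    if not picked:
        return _empty_ivset("clump")
    S = np.array(sorted(picked))
    # standardized-scale marginal SE: se(r) with unit phenotype variance
    se_std = np.sqrt(np.maximum(1.0 - r_marg[S] ** 2, 1e-12) / (n_arr[S] - 2))
    return IVSet(
        indices=S,
        variant_ids=stats.variant_ids[S],
        conditional_beta=r_marg[S],
        conditional_se=se_std,
        conditional_p=p_marg[S],
        method="clump",
    )


def _empty_ivset(method: str) -> IVSet:
    z = np.array([])
    return IVSet(
        indices=z, variant_ids=z, conditional_beta=z, conditional_se=z,
        conditional_p=z, method=method,
    )
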