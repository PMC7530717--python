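"""Phenotype simulation under a two-exposure causal model.

An observed exposure E and an unobserved (pleiotropic) exposure U are each
driven by a small set of causal variants in one cis region:

    y_E = X beta_E + C + eps_E
    y_U = X beta_U + C + eps_U
    y_O = y_E * b_E + y_U * b_U + C + eps_O

with a per-individual shared confounder C ~ N(0, var 0.5) and unit-variance
measurement noise.  Nonzero per-allele effects are drawn from U(-0.5, 0.5).
The causal variant sets and effect vectors are shared across cohorts; C and
the noise terms are drawn per cohort call.

Pleiotropy modes for choosing the unobserved-exposure variants s_U:

* ``"ld"``      — s_U disjoint from s_E, each member in moderate LD
                  (0.25 < r^2 < 0.95) with at least one member of s_E;
* ``"overlap"`` — s_U identical to s_E;
* ``"mixed"``   — a fraction of s_U copied from s_E, the rest from the
                  moderate-LD window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_sim import GenotypeMatrix, LDMatrix

__all__ = [
    "CausalArchitecture",
    "PhenotypeSet",
    "InfeasibleArchitectureError",
    "select_causal_sets",
    "simulate_phenotypes",
]

EFFECT_LOW, EFFECT_HIGH = -0.5, 0.5
LD_WINDOW = (0.25, 0.95)


class InfeasibleArchitectureError(RuntimeError):
    """Raised when no variant set satisfying the pleiotropy mode exists."""


@dataclass
class CausalArchitecture:
    """Causal variant indices and effects for the two exposures."""

    s_E: np.ndarray
    s_U: np.ndarray
    beta_E: np.ndarray  # dense length-m vectors, nonzero only on s_E / s_U
    beta_U: np.ndarray
    mode: str = "ld"

    def __post_init__(self) -> None:
        self.s_E = np.asarray(self.s_E, dtype=np.int64)
        self.s_U = np.asarray(self.s_U, dtype=np.int64)
        self.beta_E = np.asarray(self.beta_E, dtype=np.float64)
        self.beta_U = np.asarray(self.beta_U, dtype=np.float64)

    @property
    def k(self) -> int:
        return len(self.s_E)


@dataclass
class PhenotypeSet:
    """Simulated phenotypes for one cohort."""

    y_E: np.ndarray
    y_U: np.ndarray
    y_O: np.ndarray
    cohort: str = ""
    b_E: float = 0.0
    b_U: float = 0.0


def select_causal_sets(
    ld: LDMatrix,
    k: int,
    mode: str = "ld",
    overlap_fraction: float = 1.0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 50,
) -> CausalArchitecture:
    """Draw causal variant sets s_E, s_U and fresh effect sizes.

    s_E is drawn uniformly from the region.  s_U follows the pleiotropy mode
    (see module docstring).  For ``mode="ld"`` a draw of s_E with too few
    moderate-LD partners is resampled up to ``max_tries`` times before an
    :class:`InfeasibleArchitectureError` is raised.  A candidate qualifies for
    the LD window if its max r^2 over members of s_E falls inside the window.
    """
    if mode not in ("ld", "overlap", "mixed"):
        raise ValueError(f"unknown pleiotropy mode {mode!r}")
    rng = np.random.default_rng(seed)
    m = ld.r.shape[0]
    if k < 1 or k > m:
        raise ValueError("k must be in [1, n_variants]")
    r2 = ld.r2
    lo, hi = LD_WINDOW

    n_overlap = k if mode == "overlap" else (
        int(np.ceil(overlap_fraction * k)) if mode == "mixed" else 0
    )
    n_ld = k - n_overlap

    for _ in range(max_tries):
        s_E = rng.choice(m, size=k, replace=False)
        if n_ld == 0:
            s_U = s_E.copy()
            break
        max_r2 = r2[s_E, :].max(axis=0)
        pool = np.flatnonzero((max_r2 > lo) & (max_r2 < hi))
        pool = np.setdiff1d(pool, s_E, assume_unique=False)
        if len(pool) < n_ld:
            continue
        s_ld = rng.choice(pool, size=n_ld, replace=False)
        s_U = np.concatenate([s_E[:n_overlap], s_ld]) if n_overlap else s_ld
        break
    else:
        raise InfeasibleArchitectureError(
            f"no architecture with k={k} found in mode={mode!r}: "
            f"too few variants in the {lo} < r^2 < {hi} window"
        )

    beta_E = np.zeros(m)
    beta_U = np.zeros(m)
    beta_E[s_E] = rng.uniform(EFFECT_LOW, EFFECT_HIGH, size=k)
    beta_U[s_U] = rng.uniform(EFFECT_LOW, EFFECT_HIGH, size=len(s_U))
    return CausalArchitecture(s_E=s_E, s_U=s_U, beta_E=beta_E, beta_U=beta_U, mode=mode)


def simulate_phenotypes(
    G: GenotypeMatrix,
    arch: CausalArchitecture,
    b_E: float,
    b_U: float,
    seed: int | np.random.Generator = 0,
    confounder_var: float = 0.5,
) -> PhenotypeSet:
    """Simulate y_E, y_U, y_O for one cohort under a fixed architecture.

    C and all noise terms are drawn fresh for this call (cohort-specific);
    the architecture (variant sets and effects) is shared across cohorts by
    passing the same ``arch``.
    """
    if arch.s_E.size and arch.s_E.max() >= G.n_variants:
        raise IndexError("architecture indices exceed genotype variant count")
    if arch.s_U.size and arch.s_U.max() >= G.n_variants:
        raise IndexError("architecture indices exceed genotype variant count")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    X = G.dosages

    # only touch the causal columns: X beta == X[:, s] beta[s]
    g_E = X[:, arch.s_E].astype(np.float64) @ arch.beta_E[arch.s_E]
    g_U = X[:, arch.s_U].astype(np.float64) @ arch.beta_U[arch.s_U]

    C = rng.normal(0.0, np.sqrt(confounder_var), size=n)
    y_E = g_E + C + rng.normal(0.0, 1.0, size=n)
    y_U = g_U + C + rng.normal(0.0, 1.0, size=n)
    y_O = y_E * b_E + y_U * b_U + C + rng.normal(0.0, 1.0, size=n)
    return PhenotypeSet(y_E=y_E, y_U=y_U, y_O=y_O, cohort=G.label, b_E=b_E, b_U=b_U)
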