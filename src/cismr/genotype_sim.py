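"""Simulation of LD-structured haplotypes and genotype cohorts.

A small founder-haplotype mosaic model stands in for a reference-panel-expanded
genomic region: the region is divided into LD blocks, each block carries a
handful of founder haplotypes, and every panel haplotype copies one founder per
block with a small per-site mismatch rate.  Cohorts are then expanded from the
panel with a Li-Stephens-style copying process (switch to a random panel
haplotype with a per-interval recombination probability), so allele frequencies
and LD agree across cohorts up to sampling error.

Dosages are stored as integer counts of the effect (A1) allele; genotype
standardization happens downstream in the association code and is never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HaplotypePanel",
    "GenotypeMatrix",
    "LDMatrix",
    "build_panel",
    "expand_cohorts",
    "filter_biallelic_maf",
    "ld_matrix",
]


@dataclass
class HaplotypePanel:
    """Binary haplotypes (haplotypes x variants) with bp positions."""

    alleles: np.ndarray
    positions: np.ndarray
    variant_ids: np.ndarray
    recomb_rate: float = 0.0
    mismatch_rate: float = 0.0
    groups: np.ndarray | None = None  # subpopulation label per haplotype

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.groups is None:
            self.groups = np.zeros(self.alleles.shape[0], dtype=np.int64)
        self.groups = np.asarray(self.groups, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x variants matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids must be unique")
        if self.alleles.shape[1] != len(self.positions):
            raise ValueError("positions length must equal variant count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def frequencies(self) -> np.ndarray:
        """Allele-1 frequency per variant."""
        return self.alleles.mean(axis=0)


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages`` counts copies of the A1 (effect) allele, entries in {0,1,2}.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    a1: np.ndarray = None
    a2: np.ndarray = None
    label: str = ""

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        m = self.dosages.shape[1]
        if self.a1 is None:
            self.a1 = np.array(["A"] * m, dtype=object)
        if self.a2 is None:
            self.a2 = np.array(["G"] * m, dtype=object)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        for meta in (self.variant_ids, self.positions, self.a1, self.a2):
            if len(meta) != m:
                raise ValueError("variant metadata length must equal column count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the A1 allele (not folded)."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def standardized(self) -> np.ndarray:
        """Dosages transformed to per-column mean 0, variance 1 (float32).

        Monomorphic columns come out as all-zero rather than NaN.
        """
        X = self.dosages.astype(np.float32)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variant_ids=self.variant_ids[idx],
            positions=self.positions[idx],
            a1=self.a1[idx],
            a2=self.a2[idx],
            label=self.label,
        )


@dataclass
class LDMatrix:
    """Pearson correlations between variant dosage columns."""

    r: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.variant_ids) != self.r.shape[0]:
            raise ValueError("variant id count must match matrix size")

    @property
    def r2(self) -> np.ndarray:
        return self.r**2


def build_panel(
    n_haplotypes: int,
    n_variants: int,
    block_length: int = 100_000,
    seed: int | np.random.Generator = 0,
    n_founders: int = 16,
    mismatch_rate: float = 0.002,
    spacing: int = 1_000,
    pattern_renew: float = 0.01,
    pattern_flip: float = 0.008,
    freq_beta: tuple[float, float] = (0.35, 0.35),
    n_groups: int = 4,
) -> HaplotypePanel:
    """Build a haplotype reference panel with block LD structure.

    Each block of ``block_length`` bp holds ``n_founders`` founder haplotypes;
    every panel haplotype copies one founder per block, flipping each allele
    with probability ``mismatch_rate``.  Founder allele patterns evolve along
    the chromosome as a Markov chain — at each variant the pattern is redrawn
    with probability ``pattern_renew``, otherwise carried over with each
    founder allele flipped with probability ``pattern_flip`` — so within-block
    pairwise r^2 spans near-duplicates down to near-independence with a
    distance decay, while variants in different blocks are near-independent.

    With ``n_groups > 1`` the panel carries subtle population structure:
    every group runs its own founder chain against shared per-variant
    frequency targets, so allele frequencies drift apart between groups (Fst
    on the order of 1/n_founders).  This reproduces the weak long-range
    background LD (r^2 of a few permil) seen between distant variants in
    real cohorts, which matters for the calibration of methods that assume
    fully independent instruments.

    Variants sit every ``spacing`` bp on a single synthetic contig, 1-based.
    """
    if n_haplotypes < 4 or n_variants < 2:
        raise ValueError("need n_haplotypes >= 4 and n_variants >= 2")
    if not 0 <= mismatch_rate < 0.5:
        raise ValueError("mismatch_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)

    positions = np.arange(1, n_variants + 1, dtype=np.int64) * spacing
    block_of = (positions - 1) // int(block_length)
    _, block_idx = np.unique(block_of, return_inverse=True)
    n_blocks = block_idx.max() + 1

    # founder allele patterns, Markov along the chromosome within a block;
    # one chain per subpopulation group, sharing renewal frequency targets
    founders = np.empty((n_groups, n_founders, n_variants), dtype=np.int8)
    pattern = np.zeros((n_groups, n_founders), dtype=np.int8)
    prev_block = -1
    for j in range(n_variants):
        renew = block_idx[j] != prev_block or rng.random() < pattern_renew
        if renew:
            # U-shaped frequency draw: a site-frequency spectrum skewed
            # towards rare minor alleles, as in sequencing-based panels
            f = rng.beta(*freq_beta)
            pattern = (rng.random((n_groups, n_founders)) < f).astype(np.int8)
        else:
            flips = rng.random((n_groups, n_founders)) < pattern_flip
            pattern = np.where(flips, 1 - pattern, pattern).astype(np.int8)
        founders[:, :, j] = pattern
        prev_block = block_idx[j]

    # per haplotype, one founder choice per block, expanded to variants;
    # haplotypes are split evenly over the groups
    groups = np.repeat(np.arange(n_groups), -(-n_haplotypes // n_groups))[:n_haplotypes]
    choice = rng.integers(0, n_founders, size=(n_haplotypes, n_blocks))
    cols = np.arange(n_variants)
    alleles = founders[groups[:, None], choice[:, block_idx], cols]
    flips = rng.random((n_haplotypes, n_variants)) < mismatch_rate
    alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)

    ids = np.array([f"rs{p}" for p in positions], dtype=object)
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        variant_ids=ids,
        mismatch_rate=mismatch_rate,
        groups=groups,
    )


def _copy_haplotypes(
    panel_alleles: np.ndarray, n_hap: int, recomb_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Li-Stephens-style mosaic copying of ``n_hap`` haplotypes from the panel.

    Each new haplotype starts copying a uniformly chosen panel haplotype and
    switches to a fresh uniform choice with probability ``recomb_rate`` at
    every inter-variant interval.
    """
    n_panel, m = panel_alleles.shape
    # candidate template at every (haplotype, variant); kept only from the
    # last switch point onwards
    candidates = rng.integers(0, n_panel, size=(n_hap, m), dtype=np.int32)
    if recomb_rate <= 0:
        idx = np.broadcast_to(candidates[:, :1], (n_hap, m))
    else:
        switch = np.empty((n_hap, m), dtype=bool)
        switch[:, 0] = True
        switch[:, 1:] = rng.random((n_hap, m - 1)) < recomb_rate
        cols = np.arange(m, dtype=np.int32)
        last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
        idx = np.take_along_axis(candidates, last_switch, axis=1)
    return panel_alleles[idx, np.arange(m, dtype=np.int32)]


def expand_cohorts(
    panel: HaplotypePanel,
    sizes: list[int],
    recomb_rate: float = 0.005,
    seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
) -> list[GenotypeMatrix]:
    """Expand the panel into diploid cohorts of the requested sizes.

    Every individual is the sum of two independent mosaic haplotypes copied
    from the panel, so all cohorts are disjoint draws from one common
    process.  When the panel carries subpopulation groups, each individual
    is assigned a group uniformly and both haplotypes copy from that group's
    panel haplotypes (within-group mating), preserving the structure-induced
    long-range LD in the cohorts.
    """
    if panel.n_variants == 0 or panel.n_haplotypes == 0:
        raise RuntimeError("cannot expand an empty haplotype panel")
    if any(s <= 0 for s in sizes):
        raise ValueError("cohort sizes must be positive")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"cohort{i}" for i in range(len(sizes))]
    group_ids = np.unique(panel.groups)

    cohorts = []
    for size, label in zip(sizes, labels):
        dos = np.empty((size, panel.n_variants), dtype=np.int8)
        indiv_group = rng.integers(0, len(group_ids), size=size)
        for gi, g in enumerate(group_ids):
            rows = np.flatnonzero(indiv_group == gi)
            if rows.size == 0:
                continue
            sub = panel.alleles[panel.groups == g]
            h1 = _copy_haplotypes(sub, rows.size, recomb_rate, rng)
            h2 = _copy_haplotypes(sub, rows.size, recomb_rate, rng)
            dos[rows] = h1 + h2
        cohorts.append(
            GenotypeMatrix(
                dosages=dos,
                variant_ids=panel.variant_ids.copy(),
                positions=panel.positions.copy(),
                label=label,
            )
        )
    return cohorts


def filter_biallelic_maf(G: GenotypeMatrix, maf_min: float = 0.01) -> GenotypeMatrix:
    """Retain variants with minor allele frequency >= ``maf_min``.

    Order is preserved; an empty result is allowed.
    """
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    keep = np.flatnonzero(G.maf() >= maf_min)
    return G.take_variants(keep)


def ld_matrix(G: GenotypeMatrix, subset: np.ndarray | None = None) -> LDMatrix:
    """Pearson correlation matrix of dosage columns (r; r^2 = r*r)."""
    if G.n_individuals < 2:
        raise ValueError("need at least 2 individuals to compute LD")
    idx = np.arange(G.n_variants) if subset is None else np.asarray(subset)
    X = G.dosages[:, idx].astype(np.float64)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = G.variant_ids[idx[np.flatnonzero(sd == 0)[0]]]
        raise ValueError(f"monomorphic variant {bad!r}: correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(r=r, variant_ids=G.variant_ids[idx])
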