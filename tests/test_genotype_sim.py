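import numpy as np
import pytest

from cismr.genotype_sim import (
    build_panel,
    expand_cohorts,
    filter_biallelic_maf,
    ld_matrix,
)
from .conftest import make_genotypes


def corr_abs(alleles, i, j):
    return abs(np.corrcoef(alleles[:, i], alleles[:, j])[0, 1])


class TestBuildPanel:
    def test_seed_determinism(self):
        p1 = build_panel(100, 50, seed=1)
        p2 = build_panel(100, 50, seed=1)
        assert np.array_equal(p1.alleles, p2.alleles)
        assert np.array_equal(p1.positions, p2.positions)

    def test_block_structure_within_vs_cross(self):
        """Within-block pairs correlate far more than cross-block pairs."""
        p = build_panel(600, 120, block_length=20_000, seed=3)
        block = (p.positions - 1) // 20_000
        freqs = p.alleles.mean(axis=0)
        poly = np.flatnonzero((freqs > 0.05) & (freqs < 0.95))
        rng = np.random.default_rng(0)
        within, across = [], []
        for _ in range(400):
            i, j = rng.choice(poly, 2, replace=False)
            r = corr_abs(p.alleles, i, j)
            (within if block[i] == block[j] else across).append(r)
        assert within and across
        assert np.mean(within) > 2 * np.mean(across)

    def test_separate_blocks_near_independent(self):
        p = build_panel(4000, 2, block_length=500, spacing=1000, seed=5)
        f = p.alleles.mean(axis=0)
        assert all((f > 0) & (f < 1))
        assert corr_abs(p.alleles, 0, 1) < 0.1

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            build_panel(2, 50)
        with pytest.raises(ValueError):
            build_panel(100, 1)


class TestExpandCohorts:
    def test_paper_cohort_sizes(self):
        """The default study design: outcome 15000, exposure and reference 5000."""
        p = build_panel(100, 30, seed=2)
        cohorts = expand_cohorts(p, [15_000, 5_000, 5_000], seed=0)
        assert [g.n_individuals for g in cohorts] == [15_000, 5_000, 5_000]
        assert all(g.n_variants == 30 for g in cohorts)

    def test_no_recombination_copies_panel_haplotypes(self):
        p = build_panel(50, 40, seed=4)
        (G,) = expand_cohorts(p, [200], recomb_rate=0.0, seed=7)
        # each simulated haplotype must equal one panel haplotype exactly;
        # dosage rows are sums of two panel rows
        sums = {
            tuple(a + b)
            for g in np.unique(p.groups)
            for a in p.alleles[p.groups == g]
            for b in p.alleles[p.groups == g]
        }
        for row in G.dosages[:20]:
            assert tuple(row) in sums

    def test_cohort_frequencies_match_panel(self):
        p = build_panel(200, 60, seed=8)
        (G,) = expand_cohorts(p, [20_000], seed=9)
        f_panel = p.frequencies()
        f_cohort = G.dosages.mean(axis=0) / 2
        se = np.sqrt(f_panel * (1 - f_panel) / (2 * 20_000)) + 1e-9
        # mismatch-driven drift is tiny; sampling error dominates
        assert np.mean(np.abs(f_cohort - f_panel)) < 3 * np.mean(se) + 0.01

    def test_determinism_and_errors(self):
        p = build_panel(50, 20, seed=1)
        a = expand_cohorts(p, [100, 50], seed=3)
        b = expand_cohorts(p, [100, 50], seed=3)
        assert np.array_equal(a[0].dosages, b[0].dosages)
        assert np.array_equal(a[1].dosages, b[1].dosages)
        with pytest.raises(ValueError):
            expand_cohorts(p, [0])


class TestMafFilter:
    def test_threshold(self):
        # frequencies 0.005, 0.02, 0.4 on 100 individuals
        n = 100
        dos = np.zeros((n, 3), dtype=np.int8)
        dos[:1, 0] = 1  # maf 0.005
        dos[:4, 1] = 1  # maf 0.02
        dos[:40, 2] = 2  # maf 0.4
        G = make_genotypes(dos)
        kept = filter_biallelic_maf(G, maf_min=0.01)
        assert list(kept.variant_ids) == ["v1", "v2"]

    def test_identity_and_monomorphic(self):
        dos = np.array([[0, 2], [1, 2], [2, 2], [1, 2]], dtype=np.int8)
        G = make_genotypes(dos)
        kept = filter_biallelic_maf(G, maf_min=0.01)
        assert list(kept.variant_ids) == ["v0"]  # monomorphic column removed
        low = filter_biallelic_maf(G.take_variants([0]), maf_min=0.01)
        assert low.n_variants == 1  # identity when all pass

    def test_invalid_threshold(self):
        G = make_genotypes([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            filter_biallelic_maf(G, maf_min=0.7)


class TestLDMatrix:
    def test_self_and_duplicate(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        G = make_genotypes(np.column_stack([col, col, col[::-1]]))
        ld = ld_matrix(G)
        assert ld.r[0, 0] == pytest.approx(1.0)
        assert ld.r[0, 1] == pytest.approx(1.0)
        assert np.allclose(ld.r, ld.r.T)

    def test_hand_computed_four_individuals(self):
        """Pearson correlation on a 4 x 2 dosage table, against the closed form."""
        x = np.array([0.0, 1, 2, 1])
        y = np.array([2.0, 1, 0, 1])
        G = make_genotypes(np.column_stack([x, y]).astype(int))
        ld = ld_matrix(G)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert ld.r[0, 1] == pytest.approx(num / den)

    def test_brute_force_equivalence(self, small_cache):
        G = small_cache.G_ref.take_variants(np.arange(15))
        ld = ld_matrix(G)
        X = G.dosages.astype(float)
        for i in range(15):
            for j in range(15):
                expected = np.corrcoef(X[:, i], X[:, j])[0, 1]
                assert ld.r[i, j] == pytest.approx(expected, abs=1e-10)

    def test_monomorphic_error_names_variant(self):
        dos = np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8)
        G = make_genotypes(dos, ids=["mono1", "ok"])
        with pytest.raises(ValueError, match="mono1"):
            ld_matrix(G)
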