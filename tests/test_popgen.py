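"""Segregation classes, EM haplotype frequencies / r2, LD decay, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rrlsnp as r
from rrlsnp.genotyping import MISSING, GenotypeMatrix
from rrlsnp.popgen import (
    Segregation,
    _pair_loglik,
    em_haplotype_freqs,
    ld_site_filter,
    mann_whitney_greater,
)


def grid_search_loglik(g1, g2, n_grid=10_001):
    """Independent 1-D oracle: allele margins are fixed by the data, so the
    likelihood is maximised over f(AB) alone."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n = len(g1)
    pa = 1 - g1.sum() / (2 * n)
    pb = 1 - g2.sum() / (2 * n)
    counts = np.bincount(g1 * 3 + g2, minlength=9).astype(float)
    lo = max(0.0, pa + pb - 1)
    hi = min(pa, pb)
    best = -np.inf
    for t in np.linspace(lo, hi, n_grid):
        f = np.array([t, pa - t, pb - t, 1 - pa - pb + t])
        if (f < -1e-12).any():
            continue
        ll = _pair_loglik(np.clip(f, 0, 1), counts.reshape(3, 3))
        best = max(best, ll)
    return best


def random_genotype_pair(rng, n, polymorphic=True):
    for _ in range(500):
        g1 = rng.integers(0, 3, size=n)
        g2 = rng.integers(0, 3, size=n)
        if not polymorphic:
            return g1, g2
        if 0 < g1.sum() < 2 * n and 0 < g2.sum() < 2 * n:
            return g1, g2
    raise RuntimeError


class TestClassifySegregation:
    groups = np.array(["cultivated"] * 2 + ["wild"] * 2)

    def test_group_a_only(self):
        # cultivated samples carry (10 ref, 3 alt) reads, wild (8 ref, 0 alt)
        seg = r.classify_segregation([10, 0, 8, 0], [3, 0, 0, 0], self.groups)
        assert seg.value == "vinifera_polymorphic"
        assert seg.poly_a and not seg.poly_b

    def test_shared(self):
        seg = r.classify_segregation([5, 0, 4, 0], [2, 0, 3, 0], self.groups)
        assert seg.value == "shared_polymorphic"

    def test_fixed_difference(self):
        seg = r.classify_segregation([6, 6, 0, 0], [0, 0, 7, 7], self.groups)
        assert seg.value == "fixed_difference"
        assert not seg.poly_a and not seg.poly_b

    def test_no_reads_unclassified(self):
        seg = r.classify_segregation([0, 0, 0, 0], [0, 0, 0, 0], self.groups)
        assert seg.value == "unclassified"

    def test_partition_identity_on_random_classes(self):
        rng = np.random.default_rng(1)
        classes = []
        for _ in range(300):
            ref = rng.integers(0, 5, size=4)
            alt = rng.integers(0, 5, size=4)
            classes.append(r.classify_segregation(ref, alt, self.groups))
        s = r.segregation_summary(classes)
        lhs = (
            s["share_polymorphic_a"] + s["share_polymorphic_b"]
            - s["shared_polymorphic"] + s["fixed_difference"] + s["unclassified"]
        )
        assert lhs == pytest.approx(1.0, abs=1e-12)


class TestEMHaplotypeFreqs:
    def test_no_double_heterozygotes_equals_direct_counting(self):
        # phase unambiguous: haplotypes countable by hand
        g1 = np.array([0, 0, 1, 2, 2, 1])
        g2 = np.array([0, 1, 0, 2, 1, 2])
        hf = em_haplotype_freqs(g1, g2)
        # direct count: each individual contributes two known haplotypes
        # (0,0)->2xAB, (0,1)->AB+Ab, (1,0)->AB+aB, (2,2)->2xab,
        # (2,1)->aB+ab, (1,2)->Ab+ab
        expect = np.array([4, 2, 2, 4]) / 12
        assert np.allclose(hf.f, expect, atol=1e-7)

    def test_perfect_association_gives_r2_one(self):
        g1 = np.array([0] * 10 + [2] * 5)
        g2 = np.array([0] * 10 + [2] * 5)
        assert em_haplotype_freqs(g1, g2).r2 == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError):
            em_haplotype_freqs(np.array([0, 0, 0]), np.array([0, 1, 2]))
        assert r.r2_pair(np.array([0, 0, 0]), np.array([0, 1, 2])) is None

    def test_missing_excluded_pairwise(self):
        g1 = np.array([0, 2, MISSING, 1])
        g2 = np.array([0, 2, 1, MISSING])
        hf = em_haplotype_freqs(g1, g2)
        assert hf.n == 2

    def test_em_matches_grid_oracle_on_small_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            g1, g2 = random_genotype_pair(rng, int(rng.integers(3, 7)))
            hf = em_haplotype_freqs(g1, g2)
            assert hf.loglik >= grid_search_loglik(g1, g2, 2001) - 1e-6

    @given(st.integers(0, 2**32 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_r2_invariant_under_relabeling(self, seed):
        """r2 is unchanged by swapping allele labels at either locus and by
        exchanging the loci."""
        rng = np.random.default_rng(seed)
        g1, g2 = random_genotype_pair(rng, 12)
        base = r.r2_pair(g1, g2)
        assert base is not None
        assert r.r2_pair(2 - g1, g2) == pytest.approx(base, abs=1e-6)
        assert r.r2_pair(g1, 2 - g2) == pytest.approx(base, abs=1e-6)
        assert r.r2_pair(g2, g1) == pytest.approx(base, abs=1e-6)


class TestLDSiteFilter:
    def _matrix(self, cols):
        cols = np.array(cols, dtype=np.int8).T
        n, m = cols.shape
        return GenotypeMatrix(
            samples=[f"s{i}" for i in range(n)],
            groups=["cultivated"] * n,
            sites=[("chr1", 10 * j) for j in range(m)],
            ref_alleles=["A"] * m, alt_alleles=["G"] * m,
            calls=cols,
        )

    def test_two_missing_excluded(self):
        m = self._matrix([[0, 1, MISSING, MISSING, 0, 0, 0, 1, 0, 0]])
        assert ld_site_filter(m, group=None).n_sites == 0

    def test_one_missing_retained(self):
        m = self._matrix([[0, 1, MISSING, 1, 0, 0, 0, 1, 0, 0]])
        assert ld_site_filter(m, group=None).n_sites == 1

    def test_singleton_excluded_two_hets_retained(self):
        single = [[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]]
        double = [[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]]
        assert ld_site_filter(self._matrix(single), group=None).n_sites == 0
        assert ld_site_filter(self._matrix(double), group=None).n_sites == 1

    def test_monomorphic_excluded(self):
        m = self._matrix([[0] * 10, [2] * 10])
        assert ld_site_filter(m, group=None).n_sites == 0


class TestLDDecayProfile:
    def test_perfectly_correlated_sites_give_unit_bins(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=10).astype(np.int8)
        while not 0 < col.sum() < 18:
            col = rng.integers(0, 3, size=10).astype(np.int8)
        calls = np.tile(col[:, None], (1, 12))
        m = GenotypeMatrix(
            samples=[f"s{i}" for i in range(10)], groups=["cultivated"] * 10,
            sites=[("chr1", 50 * j) for j in range(12)],
            ref_alleles=["A"] * 12, alt_alleles=["G"] * 12, calls=calls,
        )
        bins = r.ld_decay_profile(m, bin_size=20, max_distance=1000)
        assert len(bins) >= 1
        assert all(b.median_r2 == pytest.approx(1.0, abs=1e-9) for b in bins)

    def test_bins_cover_pairs_once_in_distance_order(self):
        m = r.simulate_block_genotypes(n_samples=8, n_sites_per_chrom=40, seed=5)
        bins = r.ld_decay_profile(m, bin_size=100, max_distance=20_000)
        assert all(b.n == 100 for b in bins)
        assert [b.mean_distance for b in bins] == sorted(
            b.mean_distance for b in bins
        )

    def test_empty_profile_when_no_pairs(self):
        m = GenotypeMatrix(
            samples=["a", "b"], groups=["cultivated"] * 2,
            sites=[("chr1", 1)], ref_alleles=["A"], alt_alleles=["G"],
            calls=np.array([[0], [1]], dtype=np.int8),
        )
        assert r.ld_decay_profile(m) == []


class TestBackgroundLD:
    def test_single_chromosome_rejected(self):
        m = GenotypeMatrix(
            samples=["a", "b"], groups=["cultivated"] * 2,
            sites=[("chr1", 1), ("chr1", 50)],
            ref_alleles=["A"] * 2, alt_alleles=["G"] * 2,
            calls=np.array([[0, 1], [1, 0]], dtype=np.int8),
        )
        with pytest.raises(ValueError):
            r.background_ld(m)

    def test_seeded_repeatability_and_exhaustion(self):
        m = r.simulate_block_genotypes(n_samples=8, n_sites_per_chrom=15, seed=6)
        a = r.background_ld(m, n_pairs=100, seed=9)
        b = r.background_ld(m, n_pairs=100, seed=9)
        assert np.array_equal(a, b)
        everything = r.background_ld(m, n_pairs=10**9, seed=9)
        assert len(everything) <= 15 * 15


class TestMannWhitney:
    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(2)
        pool = rng.random(4000)
        p = mann_whitney_greater(pool[:2000], pool[2000:])
        assert 0.3 < p < 0.7

    def test_complete_separation(self):
        p = mann_whitney_greater(np.ones(50), np.zeros(50))
        assert p < 1e-10

    def test_mwu_bins_attaches_pvalues(self):
        m = r.simulate_block_genotypes(n_samples=8, n_sites_per_chrom=60, seed=8)
        bins = r.ld_decay_profile(m, bin_size=50, max_distance=20_000)
        bg = r.background_ld(m, n_pairs=500, seed=8)
        ps = r.mwu_bins(bins, bg)
        assert len(ps) == len(bins)
        assert all(0 < p <= 1 for p in ps)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            r.mwu_bins([], np.array([]))


class TestPCA:
    def _cluster_matrix(self):
        calls = np.zeros((8, 40), dtype=np.int8)
        calls[4:] = 2
        return GenotypeMatrix(
            samples=[f"s{i}" for i in range(8)], groups=["g"] * 8,
            sites=[("chr1", j) for j in range(40)],
            ref_alleles=["A"] * 40, alt_alleles=["G"] * 40, calls=calls,
        )

    def test_two_clusters_separate_on_pc1(self):
        res = r.pca(self._cluster_matrix(), min_called_samples=2)
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)
        pc1 = res.coordinates[:, 0]
        assert (pc1[:4] * pc1[4:] < 0).all()  # opposite sides of the origin

    def test_duplicate_samples_coincide(self):
        m = self._cluster_matrix()
        m.calls[1] = m.calls[0]
        res = r.pca(m, min_called_samples=2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_variance_fractions_are_valid(self, default_run):
        panel = default_run["panel"]
        readset = default_run["readset"]
        res = default_run["result"]
        group = dict(panel.samples)
        m = r.genotype_matrix(
            res.high_quality, readset.samples,
            [group[s] for s in readset.samples], rule="lenient",
        )
        out = r.pca(m, min_called_samples=14)
        vf = out.variance_fraction
        assert np.all(vf >= 0) and np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1 + 1e-9
        assert out.n_sites_used > 100

    def test_all_sites_filtered_is_an_error(self):
        m = self._cluster_matrix()
        with pytest.raises(ValueError):
            r.pca(m, min_called_samples=100)
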