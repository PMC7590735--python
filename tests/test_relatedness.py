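import math

import numpy as np
import pytest

from trionurture.relatedness import (
    allele_frequencies,
    build_relatedness,
    genotype_pca,
    ld_prune,
    parental_sum,
    relatedness_cutoff,
    standardize,
)
from trionurture.synthetic_data import MISSING


class TestStandardize:
    def test_child_scaling_at_half_frequency(self):
        g = np.array([[0], [1], [2], [1]])
        z, kept = standardize(g, np.array([0.5]), target_variance=1)
        np.testing.assert_allclose(z[:, 0], [-1.414, 0.0, 1.414, 0.0], atol=1e-3)
        assert list(kept) == [0]

    def test_parental_sum_scaling_gives_variance_two(self):
        g = np.array([[0], [2], [4]])
        z, _ = standardize(g, np.array([0.5]), target_variance=2)
        np.testing.assert_allclose(z[:, 0], [-2.0 * math.sqrt(2), 0.0, 2.0 * math.sqrt(2)])

    def test_monomorphic_dropped_with_report(self):
        g = np.array([[0, 2], [1, 2], [2, 2]])
        with pytest.warns(UserWarning, match="1 monomorphic"):
            z, kept = standardize(g, np.array([0.5, 1.0]))
        assert list(kept) == [0]
        assert z.shape == (3, 1)

    def test_missing_imputed_to_zero_after_centering(self):
        g = np.array([[0], [MISSING], [2]])
        z, _ = standardize(g, np.array([0.5]))
        assert z[1, 0] == 0.0

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            standardize(np.array([[1]]), np.array([1.5]))


class TestParentalSum:
    def test_sum_and_missing_propagation(self):
        m = np.array([[2, MISSING, 2]], dtype=np.int8)
        f = np.array([[1, 2, MISSING]], dtype=np.int8)
        s = parental_sum(m, f)
        assert s[0, 0] == 3
        assert s[0, 1] == MISSING
        assert s[0, 2] == MISSING

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            parental_sum(np.zeros((2, 3), dtype=np.int8), np.zeros((2, 4), dtype=np.int8))

    def test_constant_sum_column_dropped_downstream(self):
        m = np.full((3, 1), 2, dtype=np.int8)
        f = np.full((3, 1), 2, dtype=np.int8)
        s = parental_sum(m, f)
        freq = allele_frequencies(m, f)
        with pytest.warns(UserWarning, match="monomorphic"):
            _, kept = standardize(s, freq, target_variance=2)
        assert len(kept) == 0


class TestBuildRelatedness:
    def test_single_snp_outer_product(self):
        # M=1, f=0.5: children (2, 0) standardize to (+sqrt2, -sqrt2), so
        # K_oo is the plain outer product: diagonal 2, off-diagonal -2
        from trionurture.synthetic_data import TrioCohort
        import pandas as pd

        child = np.array([[2], [0]], dtype=np.int8)
        mother = np.array([[1], [1]], dtype=np.int8)
        father = np.array([[1], [1]], dtype=np.int8)
        cohort = TrioCohort(
            child_genotypes=child,
            mother_genotypes=mother,
            father_genotypes=father,
            snp_info=pd.DataFrame({"snp_id": ["s1"]}),
            sample_ids=pd.DataFrame(
                {"fid": ["f1", "f2"], "child_iid": ["c1", "c2"],
                 "mother_iid": ["m1", "m2"], "father_iid": ["d1", "d2"]}
            ),
            child_phenotype=np.zeros(2),
        )
        rel = build_relatedness(cohort)
        assert rel.K_oo[0, 1] == pytest.approx(-2.0)
        assert rel.K_oo[0, 0] == pytest.approx(2.0)

    def test_diagonal_means_near_one(self, small_relatedness):
        for K in small_relatedness.matrices:
            diag = np.diag(K)
            assert np.mean(diag) == pytest.approx(
                1.0, abs=3 * np.std(diag, ddof=1) / math.sqrt(len(diag)) + 0.02
            )

    def test_offdiagonal_mean_near_zero(self, small_relatedness):
        # estimating allele frequencies in-sample centres the scores, which
        # biases the mean off-diagonal by O(1/n); allow that plus MC noise
        K = small_relatedness.K_oo
        n = K.shape[0]
        off = K[np.triu_indices(n, 1)]
        tol = 2.0 / n + 3 * off.std(ddof=1) / math.sqrt(off.size)
        assert abs(off.mean()) < tol

    def test_allele_flip_invariance(self, small_cohort):
        rel = build_relatedness(small_cohort)
        import copy

        flip_cohort = copy.deepcopy(small_cohort)
        cols = np.arange(0, small_cohort.n_snps, 3)
        for attr in ("child_genotypes", "mother_genotypes", "father_genotypes"):
            g = getattr(flip_cohort, attr)
            block = g[:, cols]
            miss = block == MISSING
            block = (2 - block).astype(np.int8)
            block[miss] = MISSING
            g[:, cols] = block
        rel_flip = build_relatedness(flip_cohort)
        for a, b in zip(rel.matrices, rel_flip.matrices):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_snp_order_invariance(self, small_cohort):
        import copy

        perm = np.random.default_rng(0).permutation(small_cohort.n_snps)
        shuf = copy.deepcopy(small_cohort)
        for attr in ("child_genotypes", "mother_genotypes", "father_genotypes"):
            setattr(shuf, attr, getattr(shuf, attr)[:, perm])
        rel = build_relatedness(small_cohort)
        rel_shuf = build_relatedness(shuf)
        for a, b in zip(rel.matrices, rel_shuf.matrices):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_parent_child_relatedness_near_half(self, small_cohort):
        """Parent-child pairs sit at ~0.5 on the standardized-dosage scale."""
        freqs = allele_frequencies(
            small_cohort.mother_genotypes, small_cohort.father_genotypes
        )
        z_c, _ = standardize(small_cohort.child_genotypes, freqs, 1)
        z_m, _ = standardize(small_cohort.mother_genotypes, freqs, 1)
        vals = np.sum(z_c * z_m, axis=1) / z_c.shape[1]
        mc_se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        # in-sample frequency estimation shrinks cross-products by O(1/n)
        assert np.mean(vals) == pytest.approx(0.5, abs=3 * mc_se + 0.02)


class TestLdPrune:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 100)
        g = np.column_stack([a, a])
        assert list(ld_prune(g, 0.5, 10)) == [0]

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, (60, 8))
        assert list(ld_prune(g, 1.0, 10)) == list(range(8))

    def test_greedy_scan_hand_case(self):
        """r2 ~ (0.9, 0.1, 0.1) for pairs (1,2), (1,3), (2,3): keep {1, 3}."""
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.binomial(2, 0.5, n).astype(float)
        noise = rng.binomial(2, 0.5, n).astype(float)
        b = np.where(rng.random(n) < 0.95, a, noise)  # r2(a,b) ~ 0.9
        c = rng.binomial(2, 0.5, n).astype(float)
        g = np.column_stack([a, b, c])
        r2_ab = np.corrcoef(a, b)[0, 1] ** 2
        assert r2_ab > 0.5  # fixture sanity
        assert list(ld_prune(g, 0.5, 10)) == [0, 2]


class TestRelatednessCutoff:
    def test_single_violating_pair_loses_one_member(self):
        K = np.eye(4)
        K[1, 2] = K[2, 1] = 0.12
        kept = relatedness_cutoff(K, 0.1)
        assert len(kept) == 3
        assert 3 in kept and 0 in kept

    def test_nothing_removed_below_cutoff(self):
        K = np.eye(5) + 0.05
        np.fill_diagonal(K, 1.0)
        assert list(relatedness_cutoff(K, 0.1)) == list(range(5))

    def test_hub_individual_removed_first(self):
        """#0 violates with both #1 and #2: only #0 removed."""
        K = np.eye(3)
        K[0, 1] = K[1, 0] = 0.2
        K[0, 2] = K[2, 0] = 0.2
        assert list(relatedness_cutoff(K, 0.1)) == [1, 2]


class TestGenotypePca:
    def test_duplicate_rows_get_identical_scores(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((30, 50))
        z2 = np.vstack([z, z])
        scores = genotype_pca(z2, 3)
        np.testing.assert_allclose(scores[:30], scores[30:], atol=1e-8)

    def test_k_zero_gives_empty_block(self):
        z = np.random.default_rng(4).standard_normal((20, 10))
        assert genotype_pca(z, 0).shape == (20, 0)

    def test_k_too_large_rejected(self):
        z = np.zeros((5, 4))
        with pytest.raises(ValueError):
            genotype_pca(z, 4)

    def test_homogeneous_cohort_has_no_dominant_axis(self, small_cohort):
        """Leading eigenvalue stays within the null bulk from permuted
        genotypes (no population structure is simulated)."""
        freqs = allele_frequencies(
            small_cohort.mother_genotypes, small_cohort.father_genotypes
        )
        z, _ = standardize(small_cohort.child_genotypes, freqs, 1)
        zc = z - z.mean(axis=0)
        top = np.linalg.svd(zc, compute_uv=False)[0]
        rng = np.random.default_rng(5)
        perm = np.empty_like(zc)
        for j in range(zc.shape[1]):
            perm[:, j] = rng.permutation(zc[:, j])
        top_null = np.linalg.svd(perm - perm.mean(axis=0), compute_uv=False)[0]
        assert top < 1.1 * top_null
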