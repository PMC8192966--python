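"""Intra-consistency, inter-similarity, k-medoid clustering, covariate tests."""

import dataclasses

import numpy as np
import pytest

from explainstab import (
    average_scores,
    cluster_covariate_tests,
    ic_covariate_correlation,
    inter_similarity,
    intra_consistency,
    k_medoid_partition,
)
from explainstab.explain import ExplanationStack
from explainstab.reliability import AveragedScores, ClusterPartition, SimilarityMatrix


def _stack(scores, sid="s1", method="shap_kernel"):
    return ExplanationStack(subject_id=sid, method=method, scores=np.asarray(scores, float))


class TestAverageScores:
    def test_identity_and_hand_values(self):
        assert np.array_equal(average_scores(_stack([[1.0, 2.0], [1.0, 2.0]])), [1.0, 2.0])
        np.testing.assert_allclose(
            average_scores(_stack([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])), [1.0, 1.0, 1.0]
        )

    def test_matches_bruteforce_column_sums(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(7, 5))
        brute = np.array([sum(M[n, p] for n in range(7)) / 7 for p in range(5)])
        np.testing.assert_allclose(average_scores(_stack(M)), brute, atol=1e-12)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_scores(_stack(np.empty((0, 4))))


class TestIntraConsistency:
    def test_identical_rows_give_unit_ic(self):
        row = np.array([1.0, -2.0, 3.0, 0.5])
        e = intra_consistency(_stack(np.tile(row, (4, 1))))
        np.testing.assert_array_equal(e.pair_values, 1.0)
        assert e.mean_ic == 1.0

    def test_pair_count(self):
        rng = np.random.default_rng(1)
        e = intra_consistency(_stack(rng.normal(size=(3, 6))))
        assert len(e.pair_values) == 3  # N(N-1)/2 for N=3

    def test_mean_ic_decreases_with_noise(self):
        rng = np.random.default_rng(7)
        signal = rng.normal(size=12)
        means = []
        for sigma in (0.1, 0.5, 1.0, 2.0):
            noise_rng = np.random.default_rng(99)
            rows = signal + noise_rng.normal(0, sigma, size=(10, 12))
            means.append(intra_consistency(_stack(rows)).mean_ic)
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_zero_variance_rows_excluded_with_count(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(size=(3, 5))
        rows[0] = 4.2  # constant row: both its pairs undefined
        e = intra_consistency(_stack(rows))
        assert e.n_undefined == 2
        assert np.isfinite(e.mean_ic)

    def test_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(5, 8))
        perm = rng.permutation(8)
        a = intra_consistency(_stack(M)).pair_values
        b = intra_consistency(_stack(M[:, perm])).pair_values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestIcCovariate:
    def test_identity_covariate(self):
        ic = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        r, p = ic_covariate_correlation(ic, ic)
        assert r == pytest.approx(1.0)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(11)
        r, p = ic_covariate_correlation(rng.normal(size=300), rng.normal(size=300))
        assert abs(r) < 0.2

    def test_pairwise_complete_dropping(self):
        ic = np.array([0.1, np.nan, 0.9, 0.3, 0.6])
        cov = np.array([1.0, 2.0, np.nan, 3.0, 6.0])
        r, p = ic_covariate_correlation(ic, cov)  # pairs 0, 3, 4 survive
        expected = np.corrcoef([0.1, 0.3, 0.6], [1.0, 3.0, 6.0])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            ic_covariate_correlation([0.1, np.nan, 0.3], [1.0, 2.0, np.nan])


class TestInterSimilarity:
    def _avg(self, M, method="shap_kernel"):
        ids = np.asarray([f"s{i}" for i in range(len(M))])
        return AveragedScores(subject_ids=ids, matrix=np.asarray(M, float), method=method)

    def test_identical_rows_give_unit_offdiagonal(self):
        sim = inter_similarity(self._avg([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert sim.matrix[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(4)
        sim = inter_similarity(self._avg(rng.normal(size=(6, 9))))
        np.testing.assert_array_equal(sim.matrix, sim.matrix.T)
        np.testing.assert_array_equal(np.diag(sim.matrix), 1.0)

    def test_matches_pairwise_loop_oracle(self):
        from explainstab import pearson_correlation

        rng = np.random.default_rng(5)
        M = rng.normal(size=(5, 7))
        sim = inter_similarity(self._avg(M))
        for u in range(5):
            for t in range(u + 1, 5):
                assert sim.matrix[u, t] == pytest.approx(
                    pearson_correlation(M[u], M[t]), abs=1e-10
                )

    def test_zero_variance_row_gets_sentinel(self):
        M = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        sim = inter_similarity(self._avg(M))
        assert np.isnan(sim.matrix[0, 1]) and np.isnan(sim.matrix[2, 0])
        assert np.isfinite(sim.matrix[1, 2])


def planted_block_similarity(n_per_block, k, within, between, seed=0, jitter=0.01):
    rng = np.random.default_rng(seed)
    n = n_per_block * k
    S = np.full((n, n), between)
    for b in range(k):
        sl = slice(b * n_per_block, (b + 1) * n_per_block)
        S[sl, sl] = within
    noise = rng.normal(0, jitter, size=(n, n))
    S = S + (noise + noise.T) / 2
    np.fill_diagonal(S, 1.0)
    labels = np.repeat(np.arange(k), n_per_block)
    ids = np.asarray([f"s{i}" for i in range(n)])
    return SimilarityMatrix(subject_ids=ids, matrix=S, method="shap_kernel"), labels


class TestKMedoids:
    def test_recovers_planted_three_blocks(self):
        from sklearn.metrics import adjusted_rand_score

        sim, truth = planted_block_similarity(20, 3, within=0.9, between=0.1, seed=1)
        part = k_medoid_partition(sim, k_range=range(2, 16), seed=0)
        assert part.k == 3
        assert adjusted_rand_score(truth, part.labels) == 1.0
        assert set(part.medoid_ids) <= set(sim.subject_ids)

    def test_partition_equivariant_under_relabeling(self):
        sim, _ = planted_block_similarity(10, 3, 0.9, 0.1, seed=2)
        part = k_medoid_partition(sim, k_range=[3], seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(len(sim.subject_ids))
        sim_p = SimilarityMatrix(
            subject_ids=sim.subject_ids[perm],
            matrix=sim.matrix[np.ix_(perm, perm)],
            method=sim.method,
        )
        part_p = k_medoid_partition(sim_p, k_range=[3], seed=5)
        # co-membership is preserved regardless of label names
        def comembership(p):
            lab = {s: l for s, l in zip(p.subject_ids, p.labels)}
            ids = sorted(lab)
            return {(a, b): lab[a] == lab[b] for a in ids for b in ids}

        assert comembership(part) == comembership(part_p)

    def test_degenerate_matrix_rejected(self):
        n = 10
        S = np.full((n, n), 0.5)
        np.fill_diagonal(S, 1.0)
        sim = SimilarityMatrix(
            subject_ids=np.asarray([f"s{i}" for i in range(n)]), matrix=S, method="lime"
        )
        with pytest.raises(ValueError, match="non-clusterable"):
            k_medoid_partition(sim, k_range=[2, 3], seed=0)

    def test_planted_k_selected_across_contrast_and_seeds(self):
        for seed in range(5):
            sim, _ = planted_block_similarity(12, 4, within=0.7, between=0.2, seed=seed)
            part = k_medoid_partition(sim, k_range=range(2, 9), seed=seed)
            assert part.k == 4


class TestClusterCovariateTests:
    def _partition(self, cohort, labels):
        ids = cohort.subject_ids
        return ClusterPartition(
            k=len(np.unique(labels)), labels=np.asarray(labels),
            medoid_ids=ids[:1], selection_scores={}, subject_ids=ids,
            excluded_ids=np.asarray([]),
        )

    def test_separated_age_clusters_detected(self, tiny_cohort):
        cohort, _ = tiny_cohort
        young = cohort.age <= np.median(cohort.age)
        labels = np.where(young, 1, 2)
        res = cluster_covariate_tests(self._partition(cohort, labels), cohort)
        assert res["age"]["p_bonferroni"] < 1e-6
        assert res["age"]["posthoc"] is not None

    def test_bonferroni_never_decreases_p(self, tiny_cohort):
        cohort, _ = tiny_cohort
        rng = np.random.default_rng(8)
        labels = rng.integers(1, 4, size=cohort.n_subjects)
        res = cluster_covariate_tests(self._partition(cohort, labels), cohort)
        for cov in ("age", "fiq", "snr"):
            if not res[cov].get("skipped"):
                assert res[cov]["p_bonferroni"] >= res[cov]["p"]

    def test_entirely_missing_covariate_skipped(self, tiny_cohort):
        cohort, _ = tiny_cohort
        no_fiq = dataclasses.replace(cohort, fiq=np.full(cohort.n_subjects, np.nan))
        labels = np.where(np.arange(cohort.n_subjects) % 2 == 0, 1, 2)
        res = cluster_covariate_tests(self._partition(no_fiq, labels), no_fiq)
        assert res["fiq"]["skipped"]

    def test_single_cluster_rejected(self, tiny_cohort):
        cohort, _ = tiny_cohort
        with pytest.raises(ValueError, match="2 clusters"):
            cluster_covariate_tests(
                self._partition(cohort, np.ones(cohort.n_subjects, dtype=int)), cohort
            )

    def test_dunn_posthoc_available(self, tiny_cohort):
        cohort, _ = tiny_cohort
        young = cohort.age <= np.median(cohort.age)
        labels = np.where(young, 1, 2)
        res = cluster_covariate_tests(
            self._partition(cohort, labels), cohort, posthoc="dunn"
        )
        assert res["age"]["posthoc"] is not None
        assert (res["age"]["posthoc"]["p_adj"] <= 1.0).all()
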