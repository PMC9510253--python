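"""Masked-prediction harness: predictors, metrics, and the full protocol."""

import math

import numpy as np
import pytest

from pcm import (
    LSHConfig,
    SyntheticSpec,
    from_dense,
    generate,
    mae,
    mask_observed_cells,
    pcm_pipeline,
    pearson_similarity,
    predict_lsh,
    rmse,
    run_evaluation,
    upcc_predict,
)
from pcm.clustering import ClusterAssignment
from pcm.evaluation import (
    EvaluationError,
    _patient_means,
    _pearson_rows,
    _predict_lsh_bulk,
    _upcc_bulk,
    evaluate_once,
)


class TestMetrics:
    def test_mae_rmse_worked_values(self):
        assert mae([1.0, 2.0], [2.0, 4.0]) == pytest.approx(1.5)
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(math.sqrt(2.5))

    def test_perfect_prediction(self):
        assert mae([3.0, 1.0], [3.0, 1.0]) == 0.0
        assert rmse([3.0, 1.0], [3.0, 1.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EvaluationError):
            mae([], [])

    @pytest.mark.parametrize("seed", range(3))
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        p, t = rng.normal(size=50), rng.normal(size=50)
        assert rmse(p, t) >= mae(p, t)


class TestMasking:
    def test_split_is_a_partition_of_observed_cells(self, sparse_matrix):
        masked = mask_observed_cells(sparse_matrix, 0.25, seed=3)
        train = masked.train_matrix
        n_obs = sparse_matrix.observed_mask.sum()
        assert train.observed_mask.sum() + len(masked.test_cells) == n_obs
        for pid, did, truth in masked.test_cells:
            i, j = sparse_matrix.patient_index(pid), sparse_matrix.disease_index(did)
            assert sparse_matrix.observed_mask[i, j]
            assert not train.observed_mask[i, j]
            assert truth == sparse_matrix.values[i, j]

    def test_no_patient_or_disease_starves(self, sparse_matrix):
        masked = mask_observed_cells(sparse_matrix, 0.4, seed=0)
        assert masked.train_matrix.observed_mask.any(axis=1).all()
        assert masked.train_matrix.observed_mask.any(axis=0).all()

    def test_reproducible_per_seed(self, sparse_matrix):
        a = mask_observed_cells(sparse_matrix, 0.3, seed=5)
        b = mask_observed_cells(sparse_matrix, 0.3, seed=5)
        assert a.test_cells == b.test_cells

    def test_bad_fraction_rejected(self, sparse_matrix):
        with pytest.raises(EvaluationError):
            mask_observed_cells(sparse_matrix, 0.0)


class TestPearson:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),  # perfect linear relation
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [5, 5, 5], 0.0),  # zero-variance rule
            ([1, np.nan, 3], [np.nan, 2, 4], 0.0),  # one co-observed cell
        ],
    )
    def test_contract_cases(self, u, v, expected):
        assert pearson_similarity(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected
        )

    def test_vectorized_rows_match_scalar(self, sparse_matrix):
        sims = _pearson_rows(sparse_matrix, np.arange(sparse_matrix.m))
        for i in range(sparse_matrix.m):
            for j in range(sparse_matrix.m):
                expected = pearson_similarity(
                    np.where(sparse_matrix.observed_mask[i], sparse_matrix.values[i], np.nan),
                    np.where(sparse_matrix.observed_mask[j], sparse_matrix.values[j], np.nan),
                )
                assert sims[i, j] == pytest.approx(expected, abs=1e-9)


class TestClusterPredictor:
    def test_mean_of_cluster_mates(self):
        values = np.array([[np.nan], [2.0], [4.0], [9.0]])
        matrix = from_dense(values)
        clusters = ClusterAssignment({"p1": 0, "p2": 0, "p3": 0, "p4": 1}, 2)
        assert predict_lsh(matrix, clusters, ("p1", "d1")) == pytest.approx(3.0)

    def test_singleton_falls_back_to_disease_mean(self):
        values = np.array([[np.nan, 1.0], [2.0, 5.0], [4.0, 5.0]])
        matrix = from_dense(values)
        clusters = ClusterAssignment({"p1": 0, "p2": 1, "p3": 1}, 2)
        assert predict_lsh(matrix, clusters, ("p1", "d1")) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_bulk_equals_brute_force_mean(self, seed):
        """The vectorized path must equal a direct recomputation of the
        cluster-mate mean definition for every test cell."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 8, size=(20, 5))
        values[rng.random((20, 5)) < 0.2] = np.nan
        values[:, 0] = rng.uniform(0, 8, 20)  # keep every patient observed
        matrix = from_dense(values)
        labels = {f"p{i + 1}": int(i % 4) for i in range(20)}
        clusters = ClusterAssignment(labels, 4)
        cells = [
            (pid, did, 0.0)
            for i, pid in enumerate(matrix.patient_ids)
            for j, did in enumerate(matrix.disease_ids)
        ]
        preds, _ = _predict_lsh_bulk(matrix, clusters, cells)
        for (pid, did, _), got in zip(cells, preds):
            i, j = matrix.patient_index(pid), matrix.disease_index(did)
            mates = [
                q
                for q in range(20)
                if q != i and labels[matrix.patient_ids[q]] == labels[pid]
                and matrix.observed_mask[q, j]
            ]
            if mates:
                expected = float(np.mean(matrix.values[mates, j]))
            else:
                others = [q for q in range(20) if q != i and matrix.observed_mask[q, j]]
                expected = float(np.mean(matrix.values[others, j]))
            assert got == pytest.approx(expected)
            assert predict_lsh(matrix, clusters, (pid, did)) == pytest.approx(expected)


class TestUPCC:
    def test_single_perfect_neighbor_collapses_formula(self):
        # v tracks u exactly; prediction = mean_u + (value_v - mean_v)
        values = np.array(
            [
                [1.0, 2.0, 3.0, np.nan],
                [2.0, 3.0, 4.0, 6.0],
                [5.0, 1.0, 2.0, np.nan],
            ]
        )
        matrix = from_dense(values)
        mean_u, mean_v = 2.0, 15.0 / 4.0
        expected = mean_u + (6.0 - mean_v)
        assert upcc_predict(matrix, ("p1", "d4"), top_n=1) == pytest.approx(expected)

    def test_no_positive_neighbor_falls_back_to_disease_mean(self):
        values = np.array(
            [
                [1.0, 2.0, 3.0, np.nan],
                [3.0, 2.0, 1.0, 8.0],  # anti-correlated with p1
                [9.0, 8.0, 9.5, 4.0],  # uncorrelated-ish; force sim <= 0
            ]
        )
        values[2] = [3.0, 2.0, 1.0, 4.0]  # also anti-correlated
        matrix = from_dense(values)
        assert upcc_predict(matrix, ("p1", "d4")) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_formula_oracle(self, seed):
        """Independent evaluation of the mean-centred weighted formula on a
        random 15x6 instance with missing entries."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, size=(15, 6))
        values[rng.random((15, 6)) < 0.2] = np.nan
        values[:, 0] = rng.uniform(0, 5, 15)
        matrix = from_dense(values)
        top_n = 4
        for u in range(0, 15, 4):
            for j in range(6):
                pid, did = matrix.patient_ids[u], matrix.disease_ids[j]
                got = upcc_predict(matrix, (pid, did), top_n=top_n)
                # oracle: recompute from scratch with scalar pearson
                sims = np.array(
                    [
                        pearson_similarity(
                            np.where(matrix.observed_mask[u], matrix.values[u], np.nan),
                            np.where(matrix.observed_mask[v], matrix.values[v], np.nan),
                        )
                        for v in range(15)
                    ]
                )
                means = _patient_means(matrix)
                elig = [
                    v
                    for v in range(15)
                    if v != u and matrix.observed_mask[v, j] and sims[v] > 0
                ]
                elig.sort(key=lambda v: (-sims[v], v))
                top = elig[:top_n]
                if top:
                    w = sims[top]
                    dev = matrix.values[top, j] - means[top]
                    expected = means[u] + float(w @ dev) / float(np.abs(w).sum())
                else:
                    others = [
                        v for v in range(15) if v != u and matrix.observed_mask[v, j]
                    ]
                    expected = float(np.mean(matrix.values[others, j]))
                assert got == pytest.approx(expected, abs=1e-9)

    def test_bulk_equals_per_cell(self, sparse_matrix):
        masked = mask_observed_cells(sparse_matrix, 0.2, seed=1)
        preds, _, ops = _upcc_bulk(masked.train_matrix, masked.test_cells, top_n=5)
        for (pid, did, _), got in zip(masked.test_cells, preds):
            assert got == pytest.approx(
                upcc_predict(masked.train_matrix, (pid, did), top_n=5), abs=1e-9
            )
        n_test_patients = len({pid for pid, _, _ in masked.test_cells})
        assert ops == n_test_patients * (sparse_matrix.m - 1)


class TestRunEvaluation:
    def test_report_is_mean_of_per_seed_reports(self):
        matrix, _ = generate(SyntheticSpec(m=40, n=30, g=4, noise_sd=0.5, seed=2))
        cfg = LSHConfig(c=2, r=2, k=2, seed=0)
        avg = run_evaluation(matrix, cfg, mask_fraction=0.2, seeds=[0, 1])
        singles = [
            evaluate_once(matrix, cfg, 0.2, s, ("pcm", "upcc"), 10, "zero") for s in (0, 1)
        ]
        for method in ("pcm", "upcc"):
            assert avg[method].mae == pytest.approx(
                np.mean([s[method].mae for s in singles])
            )
            assert avg[method].similarity_ops == pytest.approx(
                np.mean([s[method].similarity_ops for s in singles])
            )

    def test_reproducible(self):
        matrix, _ = generate(SyntheticSpec(m=30, n=20, g=3, noise_sd=0.3, seed=7))
        cfg = LSHConfig(c=2, r=2, k=3, seed=5)
        a = run_evaluation(matrix, cfg, seeds=[0, 1])
        b = run_evaluation(matrix, cfg, seeds=[0, 1])
        assert a == b

    def test_rmse_dominates_mae_in_reports(self):
        matrix, _ = generate(SyntheticSpec(m=40, n=25, g=4, noise_sd=1.0, seed=3))
        reports = run_evaluation(matrix, LSHConfig(c=2, r=3, k=4, seed=1), seeds=[0])
        for rep in reports.values():
            assert rep.rmse >= rep.mae >= 0.0

    def test_noiseless_perfect_clustering_gives_zero_error(self):
        """With zero generator noise and the planted partition recovered,
        every cluster-mate holds the centroid value, so prediction error at
        masked cells vanishes without any fallback."""
        from pcm.evaluation import _predict_lsh_bulk
        from sklearn.metrics import adjusted_rand_score

        matrix, labels = generate(SyntheticSpec(m=24, n=40, g=3, noise_sd=0.0, seed=4))
        cfg = LSHConfig(c=2, r=4, k=4, seed=9)
        clusters = pcm_pipeline(matrix, cfg)  # hashes only, unmasked records
        got = [clusters.labels[p] for p in matrix.patient_ids]
        assert adjusted_rand_score(labels, got) == 1.0  # precondition
        masked = mask_observed_cells(matrix, 0.1, seed=0)
        preds, n_fallback = _predict_lsh_bulk(masked.train_matrix, clusters, masked.test_cells)
        truth = np.array([v for _, _, v in masked.test_cells])
        assert mae(preds, truth) == pytest.approx(0.0, abs=1e-12)
        assert n_fallback == 0

    def test_unknown_method_rejected(self, sparse_matrix):
        with pytest.raises(EvaluationError):
            run_evaluation(sparse_matrix, LSHConfig(), methods=("nope",), seeds=[0])
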