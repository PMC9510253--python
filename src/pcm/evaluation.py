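"""Masked-entry prediction harness: cluster-neighbor predictor vs UPCC.

The accuracy protocol hides a fraction of observed cells, predicts them,
and scores MAE and RMSE.  Two predictors are compared:

* the cluster predictor — for a hidden cell (patient, disease), the mean
  of the disease's observed values over the patient's cluster-mates,
  falling back to the disease's global observed mean and then the
  overall observed mean when no cluster-mate has a value;
* UPCC, classical user-based collaborative filtering — Pearson
  similarity over co-observed diseases, and a mean-centred weighted sum
  over the ``top_n`` most similar patients with positive similarity and
  an observed value at the target disease.

Cost is reported as a hardware-independent similarity-operation count:
UPCC pays one operation per Pearson pair it evaluates (m - 1 per test
patient); the cluster predictor pays one per within-bucket pair its
index tables enumerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .clustering import ClusterAssignment, cluster_from_tables
from .lsh import LSHConfig, collision_op_count, index_patients
from .matrix import PatientHealthMatrix

logger = logging.getLogger(__name__)

_MAX_MASK_REDRAWS = 100


class EvaluationError(ValueError):
    """Invalid evaluation request (empty score lists, bad fractions...)."""


@dataclass(frozen=True)
class MaskedEvaluation:
    """A train/test split of one matrix's observed cells.

    ``train_matrix`` keeps the source matrix with the test cells masked
    out; ``test_cells`` lists (patient_id, disease_id, true_value) for
    every hidden cell.  Hidden and train-observed cells are disjoint and
    their union is the original observed set.
    """

    train_matrix: PatientHealthMatrix
    test_cells: tuple[tuple[str, str, float], ...]
    mask_fraction: float
    seed: int


@dataclass(frozen=True)
class EvalReport:
    """Scores for one predictor, averaged over evaluation runs."""

    mae: float
    rmse: float
    n_predicted: float
    n_fallback: float
    similarity_ops: float


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise EvaluationError("pred and truth must be equal-length nonempty vectors")
    return float(np.mean(np.abs(pred - truth)))


def rmse(pred: Sequence[float], truth: Sequence[float]) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise EvaluationError("pred and truth must be equal-length nonempty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def mask_observed_cells(
    matrix: PatientHealthMatrix, mask_fraction: float, seed: int = 0
) -> MaskedEvaluation:
    """Hide a uniform random fraction of observed cells.

    Draws are redrawn (and logged) if masking would leave some patient
    or disease with no observed training cell, so row and column means
    stay defined; after a bounded number of redraws an error is raised.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise EvaluationError("mask_fraction must lie strictly between 0 and 1")
    obs_i, obs_j = np.nonzero(matrix.observed_mask)
    n_obs = obs_i.size
    n_mask = int(round(mask_fraction * n_obs))
    if n_mask < 1 or n_mask >= n_obs:
        raise EvaluationError(
            f"mask_fraction {mask_fraction} hides {n_mask} of {n_obs} observed cells"
        )
    rng = np.random.default_rng(seed)
    for attempt in range(_MAX_MASK_REDRAWS):
        chosen = rng.choice(n_obs, size=n_mask, replace=False)
        train_mask = matrix.observed_mask.copy()
        train_mask[obs_i[chosen], obs_j[chosen]] = False
        if train_mask.any(axis=1).all() and train_mask.any(axis=0).all():
            if attempt:
                logger.info("mask redrawn %d time(s) to keep rows/columns observed", attempt)
            break
        logger.warning("degenerate mask (empty patient or disease); redrawing")
    else:
        raise EvaluationError(
            f"could not draw a non-degenerate mask in {_MAX_MASK_REDRAWS} attempts"
        )
    chosen = np.sort(chosen)
    test_cells = tuple(
        (
            matrix.patient_ids[obs_i[c]],
            matrix.disease_ids[obs_j[c]],
            float(matrix.values[obs_i[c], obs_j[c]]),
        )
        for c in chosen
    )
    train_values = np.where(train_mask, matrix.values, np.nan)
    train = PatientHealthMatrix(
        list(matrix.patient_ids), list(matrix.disease_ids), train_values, train_mask
    )
    return MaskedEvaluation(train, test_cells, mask_fraction, seed)


# ---------------------------------------------------------------------------
# cluster-neighbor predictor


def _fallback_means(train: PatientHealthMatrix) -> tuple[np.ndarray, float]:
    O = train.observed_mask
    X0 = np.where(O, train.values, 0.0)
    col_counts = O.sum(axis=0)
    col_sums = X0.sum(axis=0)
    overall = float(col_sums.sum() / O.sum()) if O.any() else 0.0
    disease_means = np.where(col_counts > 0, col_sums / np.maximum(col_counts, 1), overall)
    return disease_means, overall


def predict_lsh(
    train: PatientHealthMatrix,
    clusters: ClusterAssignment,
    cell: tuple[str, str],
) -> float:
    """Cluster-mate mean for one cell, with the two-stage fallback."""
    value, _ = _predict_lsh_cell(train, clusters, cell)
    return value


def _predict_lsh_cell(
    train: PatientHealthMatrix, clusters: ClusterAssignment, cell: tuple[str, str]
) -> tuple[float, bool]:
    pid, did = cell
    u = train.patient_index(pid)
    j = train.disease_index(did)
    label = clusters.labels[pid]
    mates = [
        i
        for i, q in enumerate(train.patient_ids)
        if clusters.labels[q] == label and i != u and train.observed_mask[i, j]
    ]
    if mates:
        return float(train.values[mates, j].mean()), False
    _, overall = _fallback_means(train)
    # global disease mean excluding the target patient's own value
    col = train.observed_mask[:, j].copy()
    col[u] = False
    if col.sum() > 0:
        return float(train.values[col, j].mean()), True
    return overall, True


def _predict_lsh_bulk(
    train: PatientHealthMatrix,
    clusters: ClusterAssignment,
    cells: Sequence[tuple[str, str, float]],
) -> tuple[np.ndarray, int]:
    """Vectorized cluster-mean prediction for many (pid, did, truth) cells."""
    O = train.observed_mask
    X0 = np.where(O, train.values, 0.0)
    labels = np.array([clusters.labels[p] for p in train.patient_ids])
    g = clusters.n_groups
    onehot = np.zeros((train.m, g))
    onehot[np.arange(train.m), labels] = 1.0
    grp_sums = onehot.T @ X0  # (g, n)
    grp_counts = onehot.T @ O
    _, overall = _fallback_means(train)
    col_counts = O.sum(axis=0)
    col_sums = X0.sum(axis=0)

    pidx = {p: i for i, p in enumerate(train.patient_ids)}
    didx = {d: j for j, d in enumerate(train.disease_ids)}
    preds = np.empty(len(cells))
    n_fallback = 0
    for t, (pid, did, _) in enumerate(cells):
        u, j = pidx[pid], didx[did]
        gi = labels[u]
        cnt = grp_counts[gi, j] - O[u, j]
        if cnt > 0:
            preds[t] = (grp_sums[gi, j] - X0[u, j]) / cnt
        else:
            n_fallback += 1
            other = col_counts[j] - int(O[u, j])
            if other > 0:
                preds[t] = (col_sums[j] - X0[u, j]) / other
            else:
                preds[t] = overall
    return preds, n_fallback


# ---------------------------------------------------------------------------
# UPCC (user-based Pearson collaborative filtering)


def pearson_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation over co-observed cells (nan = missing).

    Fewer than two co-observed cells, or zero variance on either side,
    yields similarity 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    co = np.isfinite(u) & np.isfinite(v)
    if co.sum() < 2:
        return 0.0
    a, b = u[co], v[co]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    if math.isnan(r):
        return 0.0
    return max(-1.0, min(1.0, r))


def _pearson_rows(train: PatientHealthMatrix, rows: np.ndarray) -> np.ndarray:
    """Pearson similarity of the given patient rows against all patients.

    Returns an array of shape (len(rows), m); pairs with < 2 co-observed
    cells or zero variance get 0.  Co-observation handled pairwise.
    """
    O = train.observed_mask.astype(float)
    X = np.where(train.observed_mask, train.values, 0.0)
    Ou, Xu = O[rows], X[rows]
    n_uv = Ou @ O.T
    s_x = Xu @ O.T
    s_y = Ou @ X.T
    s_xx = (Xu**2) @ O.T
    s_yy = Ou @ (X**2).T
    s_xy = Xu @ X.T
    cov = n_uv * s_xy - s_x * s_y
    var_x = n_uv * s_xx - s_x**2
    var_y = n_uv * s_yy - s_y**2
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = cov / np.sqrt(var_x * var_y)
    eps = 1e-12
    bad = (n_uv < 2) | (var_x <= eps * np.maximum(n_uv * s_xx, 1.0)) | (
        var_y <= eps * np.maximum(n_uv * s_yy, 1.0)
    )
    sim = np.where(bad | ~np.isfinite(sim), 0.0, sim)
    return np.clip(sim, -1.0, 1.0)


def _patient_means(train: PatientHealthMatrix) -> np.ndarray:
    O = train.observed_mask
    X0 = np.where(O, train.values, 0.0)
    counts = O.sum(axis=1)
    return np.divide(X0.sum(axis=1), counts, out=np.zeros(train.m), where=counts > 0)


def upcc_predict(
    train: PatientHealthMatrix,
    cell: tuple[str, str],
    top_n: int = 10,
) -> float:
    """Mean-centred Pearson-weighted prediction for one cell."""
    if top_n < 1:
        raise EvaluationError("top_n must be at least 1")
    pid, did = cell
    u = train.patient_index(pid)
    j = train.disease_index(did)
    sims = _pearson_rows(train, np.array([u]))[0]
    value, _ = _upcc_cell(train, u, j, sims, _patient_means(train), top_n)
    return value


def _upcc_cell(
    train: PatientHealthMatrix,
    u: int,
    j: int,
    sims_u: np.ndarray,
    patient_means: np.ndarray,
    top_n: int,
) -> tuple[float, bool]:
    O = train.observed_mask
    eligible = np.nonzero(O[:, j] & (sims_u > 0.0))[0]
    eligible = eligible[eligible != u]
    if eligible.size == 0:
        _, overall = _fallback_means(train)
        col = O[:, j].copy()
        col[u] = False
        if col.sum() > 0:
            return float(train.values[col, j].mean()), True
        return overall, True
    # rank by similarity, ties broken by patient position for determinism
    order = np.lexsort((eligible, -sims_u[eligible]))
    top = eligible[order[:top_n]]
    w = sims_u[top]
    dev = train.values[top, j] - patient_means[top]
    pred = patient_means[u] + float(w @ dev) / float(np.abs(w).sum())
    return pred, False


def _upcc_bulk(
    train: PatientHealthMatrix,
    cells: Sequence[tuple[str, str, float]],
    top_n: int,
) -> tuple[np.ndarray, int, int]:
    """UPCC predictions for many cells; returns (preds, n_fallback, sim_ops)."""
    pidx = {p: i for i, p in enumerate(train.patient_ids)}
    didx = {d: j for j, d in enumerate(train.disease_ids)}
    test_rows = sorted({pidx[pid] for pid, _, _ in cells})
    row_pos = {r: t for t, r in enumerate(test_rows)}
    sims = _pearson_rows(train, np.array(test_rows))
    means = _patient_means(train)
    preds = np.empty(len(cells))
    n_fallback = 0
    for t, (pid, did, _) in enumerate(cells):
        u, j = pidx[pid], didx[did]
        preds[t], fb = _upcc_cell(train, u, j, sims[row_pos[u]], means, top_n)
        n_fallback += fb
    sim_ops = len(test_rows) * (train.m - 1)
    return preds, n_fallback, sim_ops


# ---------------------------------------------------------------------------
# full harness


def _lsh_seed(config: LSHConfig, run_seed: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(config.seed), int(run_seed)))
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_once(
    matrix: PatientHealthMatrix,
    config: LSHConfig,
    mask_fraction: float,
    run_seed: int,
    methods: Sequence[str] = ("pcm", "upcc"),
    top_n: int = 10,
    missing_policy: str = "zero",
) -> dict[str, EvalReport]:
    """One masked evaluation run; returns a report per method."""
    masked = mask_observed_cells(matrix, mask_fraction, seed=run_seed)
    train, cells = masked.train_matrix, masked.test_cells
    truth = np.array([v for _, _, v in cells])
    reports: dict[str, EvalReport] = {}
    for method in methods:
        if method == "pcm":
            cfg = replace(config, seed=_lsh_seed(config, run_seed))
            tables = index_patients(train, cfg, missing_policy=missing_policy)
            ops = collision_op_count(tables)
            clusters = cluster_from_tables(tables)
            preds, n_fb = _predict_lsh_bulk(train, clusters, cells)
        elif method == "upcc":
            preds, n_fb, ops = _upcc_bulk(train, cells, top_n)
        else:
            raise EvaluationError(f"unknown method {method!r}; expected 'pcm' or 'upcc'")
        reports[method] = EvalReport(
            mae=mae(preds, truth),
            rmse=rmse(preds, truth),
            n_predicted=len(cells),
            n_fallback=n_fb,
            similarity_ops=ops,
        )
    return reports


def run_evaluation(
    matrix: PatientHealthMatrix,
    config: LSHConfig,
    mask_fraction: float = 0.2,
    methods: Sequence[str] = ("pcm", "upcc"),
    seeds: Iterable[int] = (0,),
    top_n: int = 10,
    missing_policy: str = "zero",
) -> dict[str, EvalReport]:
    """Repeat the masked evaluation over seeds and average the reports.

    Each seed draws its own mask and its own LSH bank (derived
    deterministically from the configured seed and the run seed), so the
    whole experiment is exactly reproducible.
    """
    seeds = list(seeds)
    if not seeds:
        raise EvaluationError("at least one seed is required")
    per_seed = [
        evaluate_once(matrix, config, mask_fraction, s, methods, top_n, missing_policy)
        for s in seeds
    ]
    out: dict[str, EvalReport] = {}
    for method in methods:
        rs = [p[method] for p in per_seed]
        out[method] = EvalReport(
            mae=float(np.mean([r.mae for r in rs])),
            rmse=float(np.mean([r.rmse for r in rs])),
            n_predicted=float(np.mean([r.n_predicted for r in rs])),
            n_fallback=float(np.mean([r.n_fallback for r in rs])),
            similarity_ops=float(np.mean([r.similarity_ops for r in rs])),
        )
    return out
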