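"""Ground-truth metrics for every pipeline stage.

Detection quality uses distance-based (not IOU) matching: a predicted spot
counts as a true positive if its center of mass can be paired one-to-one
with a ground-truth center closer than ``d`` pixels, the pairing chosen by
an optimal assignment. Tracking quality is the per-track fraction of frames
within a tolerance of the matched ground-truth trajectory. Spike timing
uses greedy chronological one-to-one matching within a frame tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DetectionMetrics",
    "match_detections",
    "f1_score",
    "tracking_accuracy",
    "spike_f1",
]


@dataclass
class DetectionMetrics:
    n_true: int
    n_pred: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    d: float


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall; 0 when tp = 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def match_detections(
    pred: np.ndarray, truth: np.ndarray, d: float
) -> DetectionMetrics:
    """Optimal one-to-one matching of predicted to true centroids.

    Maximizes the number of pairs at distance < ``d`` (ties resolved toward
    smaller total distance); matched pairs are true positives, unmatched
    predictions false positives, unmatched truths false negatives.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    n_pred, n_true = len(pred), len(truth)
    tp = 0
    if n_pred and n_true:
        dist = np.linalg.norm(pred[:, None, :] - truth[None, :, :], axis=2)
        eligible = dist < d
        # large-but-finite penalty keeps the problem feasible while making
        # every eligible pair preferable to any ineligible one
        penalty = d * (min(n_pred, n_true) + 1.0)
        cost = np.where(eligible, dist, penalty)
        rows, cols = linear_sum_assignment(cost)
        tp = int(np.sum(eligible[rows, cols]))
    fp = n_pred - tp
    fn = n_true - tp
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_true if n_true else 0.0
    return DetectionMetrics(
        n_true=n_true,
        n_pred=n_pred,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1_score(tp, fp, fn) if (tp + fp + fn) else 0.0,
        d=d,
    )


def tracking_accuracy(
    tracks,
    truth_trajectories: np.ndarray,
    tol_px: float = 2.0,
    match_frames: int = 10,
) -> tuple[dict[int, float], float, float]:
    """Per-track fraction of correctly tracked frames, plus mean and SD.

    Each track is matched to the ground-truth cell whose trajectory it is
    closest to most often over its first ``match_frames`` frames; a frame is
    then correct iff the track position is within ``tol_px`` of that cell's
    true position. Returns ``(per_track, mean, sd)``.
    """
    truth = np.asarray(truth_trajectories, dtype=float)  # (n_cells, T, 2)
    n_cells, T, _ = truth.shape
    fractions: dict[int, float] = {}
    for track in tracks:
        k0 = min(match_frames, len(track))
        votes = np.zeros(n_cells, dtype=int)
        for k in range(k0):
            f = track.start_frame + k
            if not (0 <= f < T):
                continue
            dists = np.linalg.norm(truth[:, f, :] - track.positions[k], axis=1)
            votes[int(np.argmin(dists))] += 1
        if votes.sum() == 0:
            continue
        cell = int(np.argmax(votes))
        correct = 0
        total = 0
        for k in range(len(track)):
            f = track.start_frame + k
            if not (0 <= f < T):
                continue
            total += 1
            if np.linalg.norm(truth[cell, f, :] - track.positions[k]) <= tol_px:
                correct += 1
        if total:
            fractions[track.id] = correct / total
    vals = np.array(list(fractions.values()))
    mean = float(vals.mean()) if len(vals) else 0.0
    sd = float(vals.std()) if len(vals) else 0.0
    return fractions, mean, sd


def spike_f1(
    pred_frames: np.ndarray, true_frames: np.ndarray, tol_frames: int = 2
) -> tuple[float, float, float]:
    """Greedy chronological one-to-one spike matching within a tolerance.

    Returns ``(precision, recall, f1)``.
    """
    if tol_frames < 0:
        raise ValueError("tol_frames must be >= 0")
    pred = sorted(int(f) for f in np.asarray(pred_frames).ravel())
    true = sorted(int(f) for f in np.asarray(true_frames).ravel())
    tp = 0
    j = 0
    used = [False] * len(true)
    for p in pred:
        while j < len(true) and true[j] < p - tol_frames:
            j += 1
        for k in range(j, len(true)):
            if true[k] > p + tol_frames:
                break
            if not used[k]:
                used[k] = True
                tp += 1
                break
    fp = len(pred) - tp
    fn = len(true) - tp
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(true) if true else 0.0
    return precision, recall, f1_score(tp, fp, fn) if (tp + fp + fn) else 0.0
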