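"""Frame-to-frame linking of detections into tracklets.

A gated constant-velocity single-hypothesis tracker: each live track
predicts its next position with an alpha-beta filtered state, a global
one-to-one assignment (Jonker-Volgenant via the augmented non-link-cost
construction) pairs predictions with detections inside the gate, unmatched
detections seed new tracklets, and a track that misses detections for more
than ``max_missed`` consecutive frames is terminated at its last detected
frame — producing the short "tracklets" that the stitching stage re-joins.
The module boundary (detections in, tracklets out) allows an external
probabilistic tracker to be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detections

__all__ = ["Tracklet", "LinkerConfig", "solve_lap", "link_frames"]


@dataclass
class Tracklet:
    """A temporally contiguous fragment of one particle's trajectory.

    ``positions[k]`` is the (row, col) at frame ``start_frame + k``;
    ``interpolated[k]`` flags coasted (predicted, not detected) entries;
    ``detection_labels[k]`` is the within-frame detection label or -1.
    """

    id: int
    start_frame: int
    positions: np.ndarray  # (L, 2) float
    interpolated: np.ndarray  # (L,) bool
    detection_labels: np.ndarray  # (L,) int, -1 where coasted

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions) - 1

    def __len__(self) -> int:
        return len(self.positions)

    def position_at(self, frame: int) -> np.ndarray:
        return self.positions[frame - self.start_frame]


@dataclass
class LinkerConfig:
    gate_radius: float = 10.0
    max_missed: int = 5
    process_noise: float = 1.0
    measurement_noise: float = 1.0
    min_length: int = 2

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be > 0")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    def alpha_beta_gains(self) -> tuple[float, float]:
        """Steady-state alpha-beta filter gains from the noise ratio."""
        lam = self.process_noise / max(self.measurement_noise, 1e-12)
        r = (4 + lam - np.sqrt(8 * lam + lam**2)) / 4
        alpha = 1 - r**2
        beta = 2 * (2 - alpha) - 4 * np.sqrt(1 - alpha)
        return float(alpha), float(beta)


def solve_lap(
    cost: np.ndarray, non_link_cost: float
) -> list[tuple[int, int]]:
    """Globally optimal partial assignment with per-item non-link cost.

    Solves the augmented square assignment problem in which every row and
    every column may, instead of linking, pay ``non_link_cost`` (eta). A link
    (i, j) appears in the optimum only if it is globally worthwhile, which
    implies cost(i, j) <= 2 * eta. Costs may be ``inf`` (forbidden); NaN is
    an error.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if np.isnan(cost).any():
        raise ValueError("NaN costs are not allowed")
    eta = float(non_link_cost)
    if eta <= 0:
        raise ValueError("non_link_cost must be > 0")
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    big = np.full((n + m, n + m), np.inf)
    big[:n, :m] = cost
    big[np.arange(n), m + np.arange(n)] = eta  # row i unlinked
    big[n + np.arange(m), np.arange(m)] = eta  # col j unlinked
    big[n:, m:] = 0.0  # dummy-dummy completions
    rows, cols = linear_sum_assignment(big)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and np.isfinite(cost[i, j])
    ]


class _LiveTrack:
    __slots__ = (
        "positions", "interpolated", "labels", "start_frame",
        "pos", "vel", "misses", "last_detected_idx",
    )

    def __init__(self, frame: int, position: np.ndarray, label: int) -> None:
        self.start_frame = frame
        self.positions = [np.asarray(position, dtype=float)]
        self.interpolated = [False]
        self.labels = [label]
        self.pos = np.asarray(position, dtype=float)
        self.vel = np.zeros(2)
        self.misses = 0
        self.last_detected_idx = 0

    def predict(self) -> np.ndarray:
        return self.pos + self.vel

    def update(self, detection: np.ndarray, label: int,
               alpha: float, beta: float) -> None:
        pred = self.predict()
        residual = detection - pred
        self.pos = pred + alpha * residual
        self.vel = self.vel + beta * residual
        self.positions.append(np.asarray(detection, dtype=float))
        self.interpolated.append(False)
        self.labels.append(label)
        self.misses = 0
        self.last_detected_idx = len(self.positions) - 1

    def coast(self) -> None:
        self.pos = self.predict()
        self.positions.append(self.pos.copy())
        self.interpolated.append(True)
        self.labels.append(-1)
        self.misses += 1

    def finalize(self, tracklet_id: int, min_length: int) -> Tracklet | None:
        # truncate trailing coasted entries back to the last detection
        L = self.last_detected_idx + 1
        if L < min_length:
            return None
        return Tracklet(
            id=tracklet_id,
            start_frame=self.start_frame,
            positions=np.asarray(self.positions[:L]),
            interpolated=np.asarray(self.interpolated[:L]),
            detection_labels=np.asarray(self.labels[:L], dtype=int),
        )


def link_frames(
    detections: list[Detections], config: LinkerConfig | None = None
) -> list[Tracklet]:
    """Link per-frame detections into tracklets.

    Per frame, each live track's constant-velocity prediction is paired with
    at most one detection by a global assignment whose costs are the
    prediction-to-detection distances (infinite beyond ``gate_radius``).
    Unassigned detections start new tracklets; tracks coast on predictions
    during misses and terminate after more than ``max_missed`` consecutive
    missed frames, truncated back to the last detected frame.
    """
    if config is None:
        config = LinkerConfig()
    alpha, beta = config.alpha_beta_gains()
    live: list[_LiveTrack] = []
    done: list[Tracklet] = []
    next_id = 0

    def retire(track: _LiveTrack) -> None:
        nonlocal next_id
        tk = track.finalize(next_id, config.min_length)
        if tk is not None:
            done.append(tk)
            next_id += 1

    for det in detections:
        frame = det.frame
        pts = det.centroids
        n_tracks, n_dets = len(live), len(pts)
        assigned_tracks: set[int] = set()
        assigned_dets: set[int] = set()
        if n_tracks and n_dets:
            preds = np.stack([trk.predict() for trk in live])
            dist = np.linalg.norm(preds[:, None, :] - pts[None, :, :], axis=2)
            dist[dist > config.gate_radius] = np.inf
            links = solve_lap(dist, config.gate_radius)
            for i, j in links:
                live[i].update(pts[j], int(det.labels[j]), alpha, beta)
                assigned_tracks.add(i)
                assigned_dets.add(j)
        survivors: list[_LiveTrack] = []
        for i, trk in enumerate(live):
            if i in assigned_tracks:
                survivors.append(trk)
                continue
            trk.coast()
            if trk.misses > config.max_missed:
                retire(trk)
            else:
                survivors.append(trk)
        live = survivors
        for j in range(n_dets):
            if j not in assigned_dets:
                live.append(_LiveTrack(frame, pts[j], int(det.labels[j])))

    for trk in live:
        retire(trk)
    done.sort(key=lambda t: (t.start_frame, t.id))
    for new_id, tk in enumerate(done):
        tk.id = new_id
    return done
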