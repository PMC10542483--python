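"""Tracklet stitching by thin-plate-spline propagation and global assignment.

When a particle goes undetected for several frames its track is prematurely
terminated and a new tracklet starts on re-detection. To re-join fragments
of the same cell, the position of the undetected cell is propagated forward
from each tracklet's end (and backward from each tracklet's start) through
the deformation field interpolated — frame by frame — from the displacements
of all tracklets alive across that frame transition, using a regularized
thin-plate spline. The stitching cost between tracklets i (ending first) and
j is the minimum distance between i's forward-propagated and j's
backward-propagated positions over the frames both reach; a global linear
assignment with non-link cost eta selects the joins, and linked chains merge
transitively into full tracks whose gap frames are filled with the average
of the forward and backward estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .tracking import Tracklet, solve_lap

__all__ = [
    "StitchConfig",
    "Track",
    "TPSMap",
    "fit_tps",
    "propagate_positions",
    "stitch_tracklets",
]


@dataclass
class StitchConfig:
    """``alpha`` is the TPS smoothness, ``eta`` the non-linking cost in
    pixels, ``max_gap`` the longest bridgeable dropout in frames."""

    alpha: float = 10.0
    eta: float = 5.0
    max_gap: int = 50

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class Track:
    """Stitched track: temporally disjoint member tracklets plus gap-filled
    positions covering every frame of the span."""

    id: int
    tracklet_ids: list[int]
    start_frame: int
    positions: np.ndarray  # (L, 2)
    gap_filled: np.ndarray  # (L,) bool: True on synthesized gap frames
    interpolated: np.ndarray  # (L,) bool: gap-filled OR coasted within tracklet

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions) - 1

    def __len__(self) -> int:
        return len(self.positions)

    def position_at(self, frame: int) -> np.ndarray:
        return self.positions[frame - self.start_frame]


class TPSMap:
    """Smooth 2-D -> 2-D displacement map.

    Thin-plate spline (r^2 log r radial basis plus affine part) with bending
    regularization weight ``alpha``; degenerates to a least-squares affine
    fit when fewer than 3 non-collinear control points are available
    (``degenerate`` is then True).
    """

    def __init__(
        self,
        control_points: np.ndarray,
        displacements: np.ndarray,
        alpha: float = 0.0,
    ) -> None:
        pts = np.asarray(control_points, dtype=float).reshape(-1, 2)
        disp = np.asarray(displacements, dtype=float).reshape(-1, 2)
        if len(pts) != len(disp):
            raise ValueError("control_points and displacements disagree in length")
        self.degenerate = False
        self._rbf = None
        self._affine = None
        if len(pts) == 0:
            self.degenerate = True
            self._affine = (np.zeros((2, 2)), np.zeros(2), np.zeros(2))
            return
        centered = pts - pts.mean(axis=0)
        rank = np.linalg.matrix_rank(centered, tol=1e-9)
        if len(pts) < 3 or rank < 2:
            self.degenerate = True
            self._affine = self._fit_affine(pts, disp)
            return
        try:
            self._rbf = RBFInterpolator(
                pts, disp, kernel="thin_plate_spline", smoothing=float(alpha),
                degree=1,
            )
        except np.linalg.LinAlgError:
            self.degenerate = True
            self._affine = self._fit_affine(pts, disp)

    @staticmethod
    def _fit_affine(
        pts: np.ndarray, disp: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        center = pts.mean(axis=0)
        if len(pts) < 3:
            # translation only: mean displacement
            return np.zeros((2, 2)), disp.mean(axis=0), center
        # centered minimal-norm fit so collinear controls degrade to a
        # translation instead of extrapolating a rank-deficient solution
        A = np.column_stack([pts - center, np.ones(len(pts))])
        coef, *_ = np.linalg.lstsq(A, disp, rcond=None)
        return coef[:2].T, coef[2], center

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._rbf is not None:
            return self._rbf(pts)
        M, b, center = self._affine
        return (pts - center) @ M.T + b


def fit_tps(
    control_points: np.ndarray, displacements: np.ndarray, alpha: float = 0.0
) -> TPSMap:
    """Fit a regularized thin-plate-spline displacement map.

    With ``alpha = 0`` the map interpolates the controls exactly; as
    ``alpha`` grows it approaches the least-squares affine fit. Degenerate
    control sets (n < 3 or collinear) fall back to an affine/translation
    fit, flagged on the returned map.
    """
    return TPSMap(control_points, displacements, alpha)


class _FieldCache:
    """Per-transition TPS displacement maps shared by all propagations."""

    def __init__(self, tracklets: list[Tracklet], alpha: float) -> None:
        self.tracklets = tracklets
        self.alpha = alpha
        self._cache: dict[tuple[int, int], TPSMap] = {}
        # index tracklets by covered frame for fast lookup
        self._by_frame: dict[int, list[Tracklet]] = {}
        for tk in tracklets:
            for f in range(tk.start_frame, tk.end_frame + 1):
                self._by_frame.setdefault(f, []).append(tk)

    def transition(self, f_from: int, f_to: int) -> TPSMap:
        key = (f_from, f_to)
        if key not in self._cache:
            pts, disp = [], []
            for tk in self._by_frame.get(f_from, []):
                if tk.start_frame <= f_to <= tk.end_frame:
                    p0 = tk.position_at(f_from)
                    pts.append(p0)
                    disp.append(tk.position_at(f_to) - p0)
            self._cache[key] = TPSMap(
                np.asarray(pts).reshape(-1, 2),
                np.asarray(disp).reshape(-1, 2),
                self.alpha,
            )
        return self._cache[key]


def propagate_positions(
    tracklets: list[Tracklet],
    config: StitchConfig | None = None,
    frame_range: tuple[int, int] | None = None,
) -> tuple[dict[int, dict[int, np.ndarray]], dict[int, dict[int, np.ndarray]]]:
    """Forward/backward ghost positions for every tracklet.

    For a tracklet ending at frame t, the forward ghost is advanced
    iteratively through frames t+1 .. t+max_gap, each step applying the TPS
    displacement map fitted on all tracklets alive at both ends of the
    transition (rigid/translation fallback below 3 controls, identity with
    none). The backward pass is symmetric from each tracklet's start.

    Returns ``(forward, backward)``: per tracklet id, a dict frame -> (2,)
    position. The dicts also contain the tracklet's own endpoint frames so a
    stitching cost can be evaluated at the partner's boundary frames.
    """
    if config is None:
        config = StitchConfig()
    if frame_range is None:
        if not tracklets:
            return {}, {}
        lo = min(tk.start_frame for tk in tracklets)
        hi = max(tk.end_frame for tk in tracklets)
    else:
        lo, hi = frame_range
    cache = _FieldCache(tracklets, config.alpha)
    forward: dict[int, dict[int, np.ndarray]] = {}
    backward: dict[int, dict[int, np.ndarray]] = {}
    for tk in tracklets:
        fwd: dict[int, np.ndarray] = {tk.end_frame: tk.positions[-1].copy()}
        ghost = tk.positions[-1].copy()
        for f in range(tk.end_frame, min(tk.end_frame + config.max_gap, hi)):
            ghost = ghost + cache.transition(f, f + 1)(ghost)[0]
            fwd[f + 1] = ghost.copy()
        forward[tk.id] = fwd
        bwd: dict[int, np.ndarray] = {tk.start_frame: tk.positions[0].copy()}
        ghost = tk.positions[0].copy()
        for f in range(tk.start_frame, max(tk.start_frame - config.max_gap, lo), -1):
            ghost = ghost + cache.transition(f, f - 1)(ghost)[0]
            bwd[f - 1] = ghost.copy()
        backward[tk.id] = bwd
    return forward, backward


def _pair_cost(
    tk_i: Tracklet,
    tk_j: Tracklet,
    fwd_i: dict[int, np.ndarray],
    bwd_j: dict[int, np.ndarray],
    max_gap: int,
) -> float:
    gap = tk_j.start_frame - tk_i.end_frame - 1
    if gap < 0 or gap > max_gap:
        return np.inf
    frames = set(fwd_i) & set(bwd_j)
    frames = {f for f in frames if tk_i.end_frame <= f <= tk_j.start_frame}
    if not frames:
        return np.inf
    return min(
        float(np.linalg.norm(fwd_i[f] - bwd_j[f])) for f in sorted(frames)
    )


def stitch_tracklets(
    tracklets: list[Tracklet], config: StitchConfig | None = None
) -> list[Track]:
    """Stitch tracklets into full tracks via one global assignment round.

    The (i, j) cost is the minimal forward/backward ghost distance over
    shared frames (infinite unless i ends before j starts within
    ``max_gap``); the assignment is solved with the non-link cost ``eta``
    and accepted links are merged transitively. Positions on detected frames
    are never altered; gap frames are filled with the mean of the forward
    and backward ghosts and flagged.
    """
    if config is None:
        config = StitchConfig()
    if not tracklets:
        return []
    forward, backward = propagate_positions(tracklets, config)
    n = len(tracklets)
    cost = np.full((n, n), np.inf)
    for a, tk_i in enumerate(tracklets):
        for b, tk_j in enumerate(tracklets):
            if a == b:
                continue
            cost[a, b] = _pair_cost(
                tk_i, tk_j, forward[tk_i.id], backward[tk_j.id], config.max_gap
            )
    links = solve_lap(cost, config.eta)
    successor = {a: b for a, b in links}
    has_pred = {b for _, b in links}

    tracks: list[Track] = []
    for a in range(n):
        if a in has_pred:
            continue
        chain = [a]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        members = [tracklets[idx] for idx in chain]
        start = members[0].start_frame
        end = members[-1].end_frame
        L = end - start + 1
        positions = np.zeros((L, 2))
        gap_filled = np.ones(L, dtype=bool)
        interp = np.ones(L, dtype=bool)
        for tk in members:
            s = tk.start_frame - start
            positions[s : s + len(tk)] = tk.positions
            gap_filled[s : s + len(tk)] = False
            interp[s : s + len(tk)] = tk.interpolated
        for prev, nxt in zip(members[:-1], members[1:]):
            fwd = forward[prev.id]
            bwd = backward[nxt.id]
            for f in range(prev.end_frame + 1, nxt.start_frame):
                if f in fwd and f in bwd:
                    pos = 0.5 * (fwd[f] + bwd[f])
                elif f in fwd:
                    pos = fwd[f]
                elif f in bwd:
                    pos = bwd[f]
                else:  # pragma: no cover - max_gap guarantees coverage
                    w = (f - prev.end_frame) / (nxt.start_frame - prev.end_frame)
                    pos = (1 - w) * prev.positions[-1] + w * nxt.positions[0]
                positions[f - start] = pos
        tracks.append(
            Track(
                id=len(tracks),
                tracklet_ids=[tk.id for tk in members],
                start_frame=start,
                positions=positions,
                gap_filled=gap_filled,
                interpolated=interp | gap_filled,
            )
        )
    return tracks
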