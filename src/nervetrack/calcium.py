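"""Sub-ROI tracking of the green-channel soma around each tracked nucleus.

Optics and biology misalign the two channels: the calcium-emitting
cytoplasm sits at a smoothly varying offset from the nucleus, and a naive
large-ROI mean often mixes neighboring cells. For each track, a small
window around the nucleus is searched for local maxima (after Gaussian
smoothing and a Gaussian prior pulling toward the nucleus); the soma
position is followed over time by nearest-candidate association damped with
an exponential moving average, and the raw trace is the disc mean around
that position. A control trace is read from the red channel at the nucleus
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stitching import Track

__all__ = [
    "SubROIConfig",
    "CalciumTrace",
    "find_candidates",
    "track_calcium_roi",
    "extract_control",
    "extract_traces",
]


@dataclass
class SubROIConfig:
    roi_size: int = 25
    n_maxima: int = 5
    smooth_sigma: float = 1.0
    prior_sigma: float = 5.0
    intensity_radius: float = 5.0
    ema_factor: float = 0.5
    suppression_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.roi_size % 2 != 1:
            raise ValueError("roi_size must be odd")
        if self.n_maxima < 1:
            raise ValueError("n_maxima must be >= 1")
        if max(self.intensity_radius, self.suppression_radius) >= self.roi_size / 2:
            raise ValueError("radii must be < roi_size / 2")
        if not (0.0 < self.ema_factor <= 1.0):
            raise ValueError("ema_factor must be in (0, 1]")


@dataclass
class CalciumTrace:
    """Aligned per-track signals over the track's frame span."""

    track_id: int
    start_frame: int
    raw_green: np.ndarray  # (L,)
    control_red: np.ndarray  # (L,)
    calcium_position: np.ndarray  # (L, 2)
    processed: np.ndarray | None = None
    clamped: np.ndarray | None = None  # frames where the ROI hit the border
    flags: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.raw_green)


def _extract_roi(image: np.ndarray, center: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Centered window with out-of-image pixels set to 0.

    Returns ``(roi, origin, clipped)`` with origin the image coordinate of
    roi[0, 0].
    """
    half = size // 2
    cr, cc = int(round(center[0])), int(round(center[1]))
    H, W = image.shape
    roi = np.zeros((size, size), dtype=float)
    r0, r1 = cr - half, cr + half + 1
    c0, c1 = cc - half, cc + half + 1
    rs, re = max(r0, 0), min(r1, H)
    cs, ce = max(c0, 0), min(c1, W)
    clipped = (rs != r0) or (re != r1) or (cs != c0) or (ce != c1)
    if rs < re and cs < ce:
        roi[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return roi, np.array([r0, c0], dtype=float), clipped


def find_candidates(
    green_roi: np.ndarray,
    nucleus_center_in_roi: np.ndarray,
    config: SubROIConfig | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Up to ``n_maxima`` soma candidates inside one ROI, best first.

    The ROI is Gaussian-smoothed, multiplied by a Gaussian prior centered on
    the nucleus, and local maxima are extracted iteratively: record the
    global maximum, zero a disc of ``suppression_radius`` around it, repeat.
    An all-zero ROI yields the nucleus center with score 0.
    """
    if config is None:
        config = SubROIConfig()
    roi = np.asarray(green_roi, dtype=float)
    if not np.any(roi):
        return [(np.asarray(nucleus_center_in_roi, dtype=float), 0.0)]
    smoothed = ndimage.gaussian_filter(roi, config.smooth_sigma)
    rr, cc = np.mgrid[0 : roi.shape[0], 0 : roi.shape[1]]
    nr, nc = nucleus_center_in_roi
    prior = np.exp(-((rr - nr) ** 2 + (cc - nc) ** 2) / (2 * config.prior_sigma**2))
    weighted = smoothed * prior
    out: list[tuple[np.ndarray, float]] = []
    for _ in range(config.n_maxima):
        idx = np.unravel_index(np.argmax(weighted), weighted.shape)
        score = float(weighted[idx])
        if score <= 0 and out:
            break
        out.append((np.array(idx, dtype=float), score))
        disc = (rr - idx[0]) ** 2 + (cc - idx[1]) ** 2 <= config.suppression_radius**2
        weighted[disc] = 0.0
    return out


_DISC_OFFSETS: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    if radius not in _DISC_OFFSETS:
        r = int(np.floor(radius))
        dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
        m = dr**2 + dc**2 <= radius * radius
        _DISC_OFFSETS[radius] = (dr[m], dc[m])
    return _DISC_OFFSETS[radius]


def _disc_mean(image: np.ndarray, center: np.ndarray, radius: float) -> float:
    """Mean over integer-grid pixels within ``radius`` of the rounded center
    (81 pixels for radius 5); pixels outside the image are excluded."""
    cr, cc = int(round(center[0])), int(round(center[1]))
    dr, dc = _disc_offsets(radius)
    rr, cw = cr + dr, cc + dc
    H, W = image.shape
    m = (rr >= 0) & (rr < H) & (cw >= 0) & (cw < W)
    if not m.any():
        return 0.0
    return float(image[rr[m], cw[m]].mean())


def track_calcium_roi(
    green_stack: np.ndarray, track: Track, config: SubROIConfig | None = None
) -> CalciumTrace:
    """Follow the soma in the green channel along one track.

    On the first frame of the span the top candidate is taken; on every
    later frame the candidate closest to the previous calcium position wins,
    and the position is updated with an exponential moving average
    (``ema_factor`` weighting the new pick) to damp wrong associations.
    ``raw_green`` is the disc mean of radius ``intensity_radius`` at the
    calcium position. Frames whose ROI hits the image border are flagged.
    """
    if config is None:
        config = SubROIConfig()
    T_span = len(track)
    H, W = green_stack.shape[1:]
    raw = np.zeros(T_span)
    positions = np.zeros((T_span, 2))
    clamped = np.zeros(T_span, dtype=bool)
    prev: np.ndarray | None = None
    for k in range(T_span):
        frame = track.start_frame + k
        nucleus = np.clip(track.positions[k], [0, 0], [H - 1, W - 1])
        clamped[k] = bool(np.any(nucleus != track.positions[k]))
        roi, origin, clipped = _extract_roi(
            green_stack[frame], nucleus, config.roi_size
        )
        clamped[k] |= clipped
        cands = find_candidates(roi, nucleus - origin, config)
        cand_pts = np.stack([origin + c for c, _ in cands])
        if prev is None:
            pick = cand_pts[0]
            pos = pick
        else:
            d = np.linalg.norm(cand_pts - prev, axis=1)
            pick = cand_pts[int(np.argmin(d))]
            pos = config.ema_factor * pick + (1 - config.ema_factor) * prev
        pos = np.clip(pos, [0, 0], [H - 1, W - 1])
        positions[k] = pos
        raw[k] = _disc_mean(green_stack[frame], pos, config.intensity_radius)
        prev = pos
    return CalciumTrace(
        track_id=track.id,
        start_frame=track.start_frame,
        raw_green=raw,
        control_red=np.zeros(T_span),
        calcium_position=positions,
        clamped=clamped,
    )


def extract_control(
    red_stack: np.ndarray, track: Track, intensity_radius: float = 5.0
) -> np.ndarray:
    """Disc-mean control trace at the nucleus position in the red channel."""
    H, W = red_stack.shape[1:]
    out = np.zeros(len(track))
    for k in range(len(track)):
        frame = track.start_frame + k
        nucleus = np.clip(track.positions[k], [0, 0], [H - 1, W - 1])
        out[k] = _disc_mean(red_stack[frame], nucleus, intensity_radius)
    return out


def extract_traces(
    green_stack: np.ndarray,
    red_stack: np.ndarray,
    tracks: list[Track],
    config: SubROIConfig | None = None,
) -> list[CalciumTrace]:
    """Raw calcium + control traces for every track."""
    if config is None:
        config = SubROIConfig()
    traces = []
    for track in tracks:
        tr = track_calcium_roi(green_stack, track, config)
        tr.control_red = extract_control(red_stack, track, config.intensity_radius)
        traces.append(tr)
    return traces
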