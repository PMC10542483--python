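"""Spot detection in the nuclear channel.

The workhorse is the analytical à-trous (undecimated) B3-spline wavelet
transform: detail planes isolate spot-like structure at a chosen scale, a
robust statistical threshold suppresses noise coefficients, and connected
components of the surviving coefficients yield sub-pixel centroids. The
detector has exactly two hyperparameters — the wavelet scale and the noise
threshold — which can be calibrated by grid search against annotated frames.

Any callable ``frame -> Detections`` can stand in for the wavelet detector
(e.g. a wrapper around an external deep-learning segmenter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "Detections",
    "DetectorConfig",
    "atrous_decompose",
    "wavelet_detect",
    "calibrate_detector",
    "Detector",
]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class Detections:
    """Per-frame spot detections: sub-pixel centroids, areas and labels."""

    frame: int
    centroids: np.ndarray  # (n, 2) float (row, col)
    areas: np.ndarray  # (n,) int
    labels: np.ndarray  # (n,) int, unique within the frame

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def empty(cls, frame: int) -> "Detections":
        return cls(
            frame=frame,
            centroids=np.zeros((0, 2)),
            areas=np.zeros(0, dtype=int),
            labels=np.zeros(0, dtype=int),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "label": self.labels,
                "row": self.centroids[:, 0],
                "col": self.centroids[:, 1],
                "area": self.areas,
            }
        )


Detector = Callable[[np.ndarray], Detections]


@dataclass
class DetectorConfig:
    """Wavelet detector hyperparameters.

    ``threshold`` is expressed in units of the robust noise SD of the
    selected detail plane; components smaller than ``min_area`` pixels are
    discarded as noise.
    """

    scale: int = 2
    threshold: float = 3.0
    min_area: int = 5

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if shape is not None:
            max_scale = int(np.floor(np.log2(min(shape)))) - 1
            if self.scale > max_scale:
                raise ValueError(
                    f"scale {self.scale} too large for image of shape {shape} "
                    f"(max {max_scale})"
                )


def atrous_decompose(
    image: np.ndarray, num_scales: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Undecimated B3-spline à-trous wavelet transform.

    ``smooth_0 = image``; each ``smooth_k`` convolves ``smooth_{k-1}`` with
    the separable kernel (1/16)[1, 4, 6, 4, 1] dilated by ``2**(k-1)`` along
    both axes (mirror boundary); ``detail_k = smooth_{k-1} - smooth_k``.
    Returns ``(details, smooth)`` with ``details[k-1]`` the detail plane at
    scale k. The planes telescope: ``sum(details) + smooth == image``.
    """
    if num_scales < 1:
        raise ValueError("num_scales must be >= 1")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    support = 4 * 2 ** (num_scales - 1) + 1
    if min(image.shape) < support:
        raise ValueError(
            f"image of shape {image.shape} smaller than the dilated kernel "
            f"support ({support}) at scale {num_scales}"
        )
    smooth = image
    details: list[np.ndarray] = []
    for k in range(1, num_scales + 1):
        step = 2 ** (k - 1)
        kernel = np.zeros(4 * step + 1)
        kernel[::step] = _B3
        nxt = ndimage.correlate1d(smooth, kernel, axis=0, mode="mirror")
        nxt = ndimage.correlate1d(nxt, kernel, axis=1, mode="mirror")
        details.append(smooth - nxt)
        smooth = nxt
    return details, smooth


def _robust_sigma(plane: np.ndarray) -> float:
    """Noise SD via the median absolute deviation (Gaussian-consistent)."""
    med = np.median(plane)
    return float(np.median(np.abs(plane - med)) / 0.6745)


def wavelet_detect(
    image: np.ndarray, config: DetectorConfig, frame: int = 0
) -> Detections:
    """Detect bright spots by thresholding one à-trous detail plane.

    The plane at ``config.scale`` is thresholded at
    ``threshold * MAD/0.6745``; surviving coefficients are grouped into
    8-connected components, components below ``min_area`` pixels are
    dropped, and each centroid is the intensity-weighted center of mass of
    the thresholded coefficients.
    """
    config.validate(image.shape)
    details, _ = atrous_decompose(image, config.scale)
    plane = details[config.scale - 1]
    thr = config.threshold * _robust_sigma(plane)
    kept = np.where(plane >= max(thr, 1e-12), plane, 0.0)
    mask = kept > 0
    if not mask.any():
        return Detections.empty(frame)
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab, intensity_image=kept)
    centroids, areas, labels = [], [], []
    next_label = 0
    for p in props:
        if p.area < config.min_area:
            continue
        centroids.append(p.centroid_weighted)
        areas.append(int(p.area))
        labels.append(next_label)
        next_label += 1
    if not labels:
        return Detections.empty(frame)
    return Detections(
        frame=frame,
        centroids=np.asarray(centroids, dtype=float),
        areas=np.asarray(areas, dtype=int),
        labels=np.asarray(labels, dtype=int),
    )


def detect_stack(
    stack: np.ndarray, config: DetectorConfig, detector: Detector | None = None
) -> list[Detections]:
    """Run a detector over every frame of a (T, H, W) stack."""
    out = []
    for t in range(stack.shape[0]):
        if detector is not None:
            det = detector(stack[t])
            det.frame = t
            out.append(det)
        else:
            out.append(wavelet_detect(stack[t], config, frame=t))
    return out


def calibrate_detector(
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    scale_grid: Sequence[int],
    threshold_grid: Sequence[float],
    d: float = 1.0,
    min_area: int = 5,
) -> DetectorConfig:
    """Grid-search the (scale, threshold) pair maximizing mean f1.

    ``truths[i]`` holds the (n, 2) ground-truth centroids of ``images[i]``;
    matching uses the distance-``d`` metric from :mod:`nervetrack.evaluation`.
    Ties break deterministically toward smaller scale, then smaller
    threshold.
    """
    from .evaluation import match_detections

    if not len(images) or len(images) != len(truths):
        raise ValueError("need >= 1 annotated image with matching truth")
    if not len(scale_grid) or not len(threshold_grid):
        raise ValueError("grids must be non-empty")
    if all(len(t) == 0 for t in truths):
        raise ValueError("empty ground truth: f1 undefined")

    best: tuple[float, int, float] | None = None  # (-f1, scale, threshold)
    best_cfg = None
    for scale in sorted(scale_grid):
        for lam in sorted(threshold_grid):
            cfg = DetectorConfig(scale=scale, threshold=lam, min_area=min_area)
            f1s = []
            for img, truth in zip(images, truths):
                det = wavelet_detect(img, cfg)
                m = match_detections(det.centroids, np.asarray(truth, float), d)
                f1s.append(m.f1)
            key = (-float(np.mean(f1s)), scale, lam)
            if best is None or key < best:
                best = key
                best_cfg = cfg
    assert best_cfg is not None
    return best_cfg
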