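"""Synthetic two-channel movie generator with full ground truth.

Emulates the statistical structure of dual-label (nuclear red, cytoplasmic
green calcium) fluorescence movies of a deforming animal: a shared smooth
body deformation with fast contraction episodes, a frozen smooth red-to-green
misalignment field, AR(2) calcium transients driven by Poisson spikes,
channel-specific photobleaching, common-mode motion-artifact intensity dips,
nematocyte-like cells whose green signal is pure noise, and mixed
Gaussian/Poisson sensor noise.

Coordinates are (row, col), 0-based, with pixel centers at integer
coordinates; sub-pixel positions are floats. Identical config + seed yields
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ContractionConfig",
    "DeformationConfig",
    "MisalignmentConfig",
    "KernelConfig",
    "BleachConfig",
    "ArtifactConfig",
    "NoiseConfig",
    "SyntheticConfig",
    "GroundTruth",
    "TwoChannelMovie",
    "generate_trajectories",
    "generate_spikes_and_calcium",
    "render_movie",
    "generate_movie",
]


@dataclass
class ContractionConfig:
    """Fast longitudinal contraction episodes.

    During an episode the body compresses along the row axis toward its
    center; the fastest cells move ``max_displacement_px_per_frame`` per
    frame, deliberately exceeding the tracker's gate to reproduce the regime
    where motion outruns the acquisition rate.
    """

    n_events: int = 2
    duration_frames: int = 20
    max_displacement_px_per_frame: float = 6.0


@dataclass
class DeformationConfig:
    """Shared smooth slow deformation of the body.

    A sum of ``n_modes`` spatial cosine modes (wavelength >= smoothness_px)
    whose coefficients drift smoothly in time; the same field displaces every
    cell, so it is representable by a thin-plate spline. ``drift_px_per_frame``
    adds a rigid translation component.
    """

    amplitude_px: float = 6.0
    smoothness_px: float = 60.0
    max_displacement_px_per_frame: float = 1.0
    n_modes: int = 6
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)


@dataclass
class MisalignmentConfig:
    """Frozen smooth red-to-green channel offset field.

    The green soma of each cell is rendered at the nucleus position plus the
    field value at the cell's initial position. Non-uniform across the field
    of view, so a single global shift cannot undo it.
    """

    amplitude_px: float = 5.0
    smoothness_px: float = 80.0
    n_modes: int = 4


@dataclass
class KernelConfig:
    """Stable AR(2) calcium transient kernel (per-frame coefficients)."""

    g1: float = 1.7
    g2: float = -0.712

    @classmethod
    def from_time_constants(
        cls, tau_rise: float, tau_decay: float, frame_rate: float
    ) -> "KernelConfig":
        """Build from rise/decay time constants in seconds."""
        r1 = float(np.exp(-1.0 / (tau_decay * frame_rate)))
        r2 = float(np.exp(-1.0 / (tau_rise * frame_rate)))
        return cls(g1=r1 + r2, g2=-r1 * r2)

    def roots(self) -> np.ndarray:
        return np.roots([1.0, -self.g1, -self.g2])

    def validate(self) -> None:
        if np.any(np.abs(self.roots()) >= 1.0):
            raise ValueError(
                f"unstable AR(2) kernel (g1={self.g1}, g2={self.g2}): "
                "roots of z^2 - g1 z - g2 must lie inside the unit circle"
            )

    def impulse_response(self, length: int) -> np.ndarray:
        s = np.zeros(length)
        s[0] = 1.0
        return sps.lfilter([1.0], [1.0, -self.g1, -self.g2], s)


@dataclass
class BleachConfig:
    """Per-frame multiplicative photobleaching factors, one per channel."""

    rate_red: float = 0.9995
    rate_green: float = 0.9998


@dataclass
class ArtifactConfig:
    """Common-mode motion-artifact dips.

    Each event multiplies BOTH channels' spot intensity of one cell by
    ``1 - depth_fraction`` for ``duration_frames`` frames. ``rate`` is the
    per-cell per-frame probability of an event starting.
    """

    rate: float = 0.001
    depth_fraction: float = 0.5
    duration_frames: int = 6


@dataclass
class NoiseConfig:
    """Sensor noise: Poisson shot noise (gain 0 disables) then Gaussian read noise."""

    gaussian_sd: float = 2.0
    poisson_gain: float = 1.0


@dataclass
class SyntheticConfig:
    n_neurons: int = 100
    n_nematocytes: int = 10
    T: int = 500
    H: int = 256
    W: int = 256
    frame_rate: float = 10.0
    psf_sigma: float = 2.0
    spike_rate: float = 0.01
    calcium_amplitude: float = 60.0
    baseline_glow: float = 20.0
    red_amplitude: float = 80.0
    background: float = 100.0
    min_separation_px: float = 8.0
    green_sigma_factor: float = 1.5
    nematocyte_scale: float = 1.5
    nematocyte_noise_sd: float = 4.0
    contraction: ContractionConfig = field(default_factory=ContractionConfig)
    deformation: DeformationConfig = field(default_factory=DeformationConfig)
    misalignment: MisalignmentConfig = field(default_factory=MisalignmentConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    bleach: BleachConfig = field(default_factory=BleachConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_neurons", "n_nematocytes", "T", "H", "W"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rate_red", "rate_green"):
            r = getattr(self.bleach, name)
            if not (0.0 < r <= 1.0):
                raise ValueError(f"bleach {name} must be in (0, 1]")
        self.kernel.validate()

    @property
    def n_cells(self) -> int:
        return self.n_neurons + self.n_nematocytes

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        sub = {
            "contraction": ContractionConfig,
            "deformation": DeformationConfig,
            "misalignment": MisalignmentConfig,
            "kernel": KernelConfig,
            "bleach": BleachConfig,
            "artifact": ArtifactConfig,
            "noise": NoiseConfig,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                val = dict(d[key])
                if key == "deformation" and "drift_px_per_frame" in val:
                    val["drift_px_per_frame"] = tuple(val["drift_px_per_frame"])
                d[key] = typ(**val)
        return cls(**d)


@dataclass
class TwoChannelMovie:
    """Paired nuclear (red) and calcium (green) uint16 image stacks."""

    red: np.ndarray  # (T, H, W) uint16
    green: np.ndarray  # (T, H, W) uint16
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green stacks must share shape (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red.shape


@dataclass
class GroundTruth:
    """Per-cell ground truth for a synthetic movie.

    ``cell_types`` holds "neuron" or "nematocyte"; ``trajectories`` is
    (n_cells, T, 2) sub-pixel nucleus positions; ``offsets`` the frozen
    (n_cells, 2) green-channel displacement; ``spike_frames`` a list of sorted
    frame-index arrays (empty for nematocytes); ``calcium_traces`` the
    (n_cells, T) noiseless green spot amplitude; ``artifact_masks`` a
    (n_cells, T) boolean mask of frames under a motion artifact.
    """

    cell_types: list[str]
    trajectories: np.ndarray
    offsets: np.ndarray
    spike_frames: list[np.ndarray]
    calcium_traces: np.ndarray
    artifact_masks: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cell_types)

    def neuron_ids(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.cell_types) == "neuron")


def _cosine_field(
    rng: np.random.Generator,
    n_modes: int,
    min_wavelength: float,
    max_wavelength: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 2-D cosine modes: wavevectors (n,2), phases (n,2), amplitudes (n,2).

    The second axis indexes the displacement component (row, col).
    """
    wavelengths = rng.uniform(min_wavelength, max_wavelength, size=n_modes)
    angles = rng.uniform(0, 2 * np.pi, size=n_modes)
    kvecs = (2 * np.pi / wavelengths)[:, None] * np.stack(
        [np.cos(angles), np.sin(angles)], axis=1
    )
    phases = rng.uniform(0, 2 * np.pi, size=(n_modes, 2))
    amplitudes = rng.uniform(0.5, 1.0, size=(n_modes, 2))
    return kvecs, phases, amplitudes


def _evaluate_static_field(
    points: np.ndarray,
    kvecs: np.ndarray,
    phases: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Evaluate a frozen cosine displacement field at (n, 2) points."""
    proj = points @ kvecs.T  # (n_pts, n_modes)
    out = np.zeros_like(points, dtype=float)
    for c in range(2):
        out[:, c] = np.sum(amplitudes[:, c] * np.cos(proj + phases[:, c]), axis=1)
    return out


def sample_misalignment(
    config: SyntheticConfig, points: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Frozen smooth red->green offset field evaluated at (n, 2) points."""
    mis = config.misalignment
    if mis.amplitude_px == 0 or mis.n_modes == 0:
        return np.zeros_like(points, dtype=float)
    kvecs, phases, amps = _cosine_field(
        rng, mis.n_modes, mis.smoothness_px, 4 * mis.smoothness_px
    )
    raw = _evaluate_static_field(points, kvecs, phases, amps)
    peak = np.max(np.abs(raw)) if raw.size else 0.0
    if peak > 0:
        raw *= mis.amplitude_px / peak
    return raw


def _contraction_scale(config: SyntheticConfig, rng: np.random.Generator,
                       d_max: float) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-frame row-axis compression factor and the event windows."""
    T = config.T
    con = config.contraction
    scale = np.ones(T)
    windows: list[tuple[int, int]] = []
    if con.n_events <= 0 or con.duration_frames <= 0 or d_max <= 0:
        return scale, windows
    dur = min(con.duration_frames, T)
    # non-overlapping random windows
    starts: list[int] = []
    for _ in range(200):
        if len(starts) >= con.n_events:
            break
        s = int(rng.integers(0, max(1, T - dur)))
        if all(abs(s - s0) >= dur + 2 for s0 in starts):
            starts.append(s)
    dstep = con.max_displacement_px_per_frame / d_max  # scale change per frame
    for s in sorted(starts):
        half = max(dur // 2, 1)
        prev = 1.0
        for i in range(dur):
            t = s + i
            if t >= T:
                break
            prev = max(prev - dstep, 0.1) if i < half else min(prev + dstep, 1.0)
            scale[t] = prev
        windows.append((s, min(s + dur, T) - 1))
        # finish releasing back to 1 after the window for odd-length ramps
        t = min(s + dur, T)
        while t < T and prev < 1.0:
            prev = min(prev + dstep, 1.0)
            scale[t] = prev
            t += 1
    return scale, windows


def _place_cells(
    rng: np.random.Generator,
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_separation: float,
) -> np.ndarray:
    """Uniform placement with hard-core exclusion (nuclei do not overlap)."""
    if n == 0:
        return np.zeros((0, 2))
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(500):
            cand = np.array(
                [rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1])]
            )
            if not pts or np.min(
                np.linalg.norm(np.asarray(pts) - cand, axis=1)
            ) >= min_separation:
                pts.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {n} cells with separation "
                f"{min_separation} px; enlarge the image or reduce counts"
            )
    return np.asarray(pts)


def generate_trajectories(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Sample shared-deformation nucleus trajectories.

    Returns ``(trajectories, contraction_windows)`` with trajectories of
    shape (n_cells, T, 2). All cells ride one smooth low-frequency
    displacement field (plus optional rigid drift); contraction episodes
    compress the row axis toward the body center with per-frame steps up to
    the configured contraction speed. Outside contraction episodes the
    per-frame displacement never exceeds
    ``deformation.max_displacement_px_per_frame``.

    Raises ``RuntimeError`` if, after a bounded number of redraws, some cell
    still leaves the image (minus a PSF-width margin).
    """
    if config.T < 2:
        raise ValueError("T must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, T = config.n_cells, config.T
    defo = config.deformation
    margin = 4.0 * config.psf_sigma + 2.0
    place_margin = margin + defo.amplitude_px + 1.0
    drift = np.asarray(defo.drift_px_per_frame, dtype=float)
    total_drift = np.abs(drift) * (T - 1)
    lo = np.array([place_margin, place_margin]) + np.maximum(-drift * (T - 1), 0)
    hi = (
        np.array([config.H - 1 - place_margin, config.W - 1 - place_margin])
        - np.maximum(drift * (T - 1), 0)
    )
    if np.any(hi <= lo):
        raise ValueError(
            "image too small for the requested margins/drift "
            f"(H={config.H}, W={config.W}, total drift {total_drift})"
        )

    for _attempt in range(20):
        base = _place_cells(rng, n, lo, hi, config.min_separation_px)
        traj = np.repeat(base[:, None, :], T, axis=1)

        if defo.amplitude_px > 0 and defo.n_modes > 0 and n > 0:
            kvecs, phases, amps = _cosine_field(
                rng, defo.n_modes, defo.smoothness_px, 4 * defo.smoothness_px
            )
            # smooth per-mode temporal coefficients in [-1, 1]
            steps = rng.normal(size=(defo.n_modes, T))
            walk = np.cumsum(steps, axis=1)
            kern = np.ones(21) / 21.0
            walk = np.apply_along_axis(
                lambda v: np.convolve(v, kern, mode="same"), 1, walk
            )
            walk /= np.maximum(np.max(np.abs(walk), axis=1, keepdims=True), 1e-12)
            proj = base @ kvecs.T  # (n, n_modes)
            disp = np.zeros((n, T, 2))
            for c in range(2):
                spatial = amps[:, c] * np.cos(proj + phases[:, c])  # (n, n_modes)
                disp[:, :, c] = spatial @ walk  # (n, T)
            peak = np.max(np.abs(disp))
            if peak > 0:
                disp *= defo.amplitude_px / peak
            step_peak = np.max(np.abs(np.diff(disp, axis=1))) if T > 1 else 0.0
            if step_peak > defo.max_displacement_px_per_frame > 0:
                disp *= defo.max_displacement_px_per_frame / step_peak
            traj = traj + disp

        if np.any(drift != 0):
            traj = traj + np.arange(T)[None, :, None] * drift[None, None, :]

        windows: list[tuple[int, int]] = []
        if config.contraction.n_events > 0 and n > 0:
            center = 0.5 * (config.H - 1)
            d_max = float(np.max(np.abs(traj[:, :, 0] - center))) if n else 0.0
            scale, windows = _contraction_scale(config, rng, d_max)
            traj = traj.copy()
            traj[:, :, 0] = center + scale[None, :] * (traj[:, :, 0] - center)

        ok = (
            np.all(traj[:, :, 0] >= margin - 1e-9)
            and np.all(traj[:, :, 0] <= config.H - 1 - margin + 1e-9)
            and np.all(traj[:, :, 1] >= margin - 1e-9)
            and np.all(traj[:, :, 1] <= config.W - 1 - margin + 1e-9)
        ) or n == 0
        if ok:
            return traj, windows
    raise RuntimeError(
        "could not draw trajectories that stay inside the image after 20 "
        "attempts; reduce deformation amplitude or enlarge the image"
    )


def generate_spikes_and_calcium(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_neurons: int | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Poisson spikes and noiseless AR(2) calcium fluorescence per neuron.

    The trace obeys ``c_t = g1 c_{t-1} + g2 c_{t-2} + s_t`` with ``s_t`` the
    Poisson spike count, then is scaled by ``calcium_amplitude``, offset by
    ``baseline_glow`` and multiplied by the green bleach curve. Returns
    ``(spike_frames, traces)`` with traces of shape (n_neurons, T).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_neurons is None:
        n_neurons = config.n_neurons
    T = config.T
    g1, g2 = config.kernel.g1, config.kernel.g2
    bleach = config.bleach.rate_green ** np.arange(T)
    spike_frames: list[np.ndarray] = []
    traces = np.zeros((n_neurons, T))
    for i in range(n_neurons):
        s = rng.poisson(config.spike_rate, size=T).astype(float)
        spike_frames.append(np.flatnonzero(s > 0))
        c = sps.lfilter([1.0], [1.0, -g1, -g2], s)
        traces[i] = (config.calcium_amplitude * c + config.baseline_glow) * bleach
    return spike_frames, traces


def _sample_artifacts(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-cell boolean artifact masks, shape (n_cells, T)."""
    art = config.artifact
    n, T = config.n_cells, config.T
    masks = np.zeros((n, T), dtype=bool)
    if art.rate <= 0 or art.depth_fraction <= 0 or n == 0:
        return masks
    starts = rng.random((n, T)) < art.rate
    for i, t in zip(*np.nonzero(starts)):
        masks[i, t : t + art.duration_frames] = True
    return masks


def _stamp_spots(
    stack: np.ndarray,
    frame: int,
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigmas: np.ndarray,
) -> None:
    """Add Gaussian spots (peak amplitude) into ``stack[frame]`` in place."""
    H, W = stack.shape[1:]
    for (r, c), amp, sig in zip(positions, amplitudes, sigmas):
        if amp <= 0:
            continue
        rad = int(np.ceil(4 * sig))
        r0, r1 = max(int(np.floor(r)) - rad, 0), min(int(np.floor(r)) + rad + 2, H)
        c0, c1 = max(int(np.floor(c)) - rad, 0), min(int(np.floor(c)) + rad + 2, W)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None] - r
        cc = np.arange(c0, c1)[None, :] - c
        stack[frame, r0:r1, c0:c1] += amp * np.exp(
            -(rr**2 + cc**2) / (2 * sig**2)
        )


def render_movie(
    config: SyntheticConfig,
    trajectories: np.ndarray,
    traces: np.ndarray,
    cell_types: list[str] | None = None,
    offsets: np.ndarray | None = None,
    artifact_masks: np.ndarray | None = None,
    spike_frames: list[np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TwoChannelMovie, GroundTruth]:
    """Render red/green uint16 stacks from trajectories and green amplitudes.

    ``traces`` holds the noiseless green spot amplitude of every cell
    (n_cells, T). The red channel draws constant-amplitude Gaussian nuclei
    (times bleaching and artifacts); the green channel draws somas at
    nucleus + offset. Sensor noise is applied last and the stacks are clipped
    to the unsigned 16-bit range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, T = config.n_cells, config.T
    if trajectories.shape != (n, T, 2):
        raise ValueError(
            f"trajectories shape {trajectories.shape} does not match config "
            f"({n} cells, {T} frames)"
        )
    if traces.shape != (n, T):
        raise ValueError(f"traces shape {traces.shape} does not match config")
    if cell_types is None:
        cell_types = ["neuron"] * config.n_neurons + [
            "nematocyte"
        ] * config.n_nematocytes
    if offsets is None:
        start_pts = trajectories[:, 0, :] if n else np.zeros((0, 2))
        offsets = sample_misalignment(config, start_pts, rng)
    if artifact_masks is None:
        artifact_masks = _sample_artifacts(config, rng)
    if spike_frames is None:
        spike_frames = [
            np.array([], dtype=int) for _ in range(n)
        ]

    is_nema = np.asarray(cell_types) == "nematocyte"
    red_sig = np.where(is_nema, config.nematocyte_scale, 1.0) * config.psf_sigma
    green_sig = red_sig * config.green_sigma_factor
    red_amp0 = np.where(is_nema, config.nematocyte_scale, 1.0) * config.red_amplitude

    red = np.full((T, config.H, config.W), float(config.background))
    green = np.full((T, config.H, config.W), float(config.background))
    art_factor = np.where(artifact_masks, 1.0 - config.artifact.depth_fraction, 1.0)
    bleach_red = config.bleach.rate_red ** np.arange(T)
    for t in range(T):
        if n:
            _stamp_spots(
                red, t, trajectories[:, t, :],
                red_amp0 * bleach_red[t] * art_factor[:, t], red_sig,
            )
            _stamp_spots(
                green, t, trajectories[:, t, :] + offsets,
                traces[:, t] * art_factor[:, t], green_sig,
            )

    for stack in (red, green):
        if config.noise.poisson_gain > 0:
            gain = config.noise.poisson_gain
            stack[:] = rng.poisson(np.clip(stack, 0, None) * gain) / gain
        if config.noise.gaussian_sd > 0:
            stack += rng.normal(0.0, config.noise.gaussian_sd, size=stack.shape)

    movie = TwoChannelMovie(
        red=np.rint(np.clip(red, 0, 65535)).astype(np.uint16),
        green=np.rint(np.clip(green, 0, 65535)).astype(np.uint16),
        frame_rate=config.frame_rate,
    )
    truth = GroundTruth(
        cell_types=list(cell_types),
        trajectories=trajectories,
        offsets=offsets,
        spike_frames=spike_frames,
        calcium_traces=traces,
        artifact_masks=artifact_masks,
    )
    return movie, truth


def generate_movie(
    config: SyntheticConfig,
) -> tuple[TwoChannelMovie, GroundTruth]:
    """End-to-end generation: trajectories, spikes, traces, rendering.

    All randomness flows from ``config.seed`` through one generator, so the
    output is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    trajectories, _windows = generate_trajectories(config, rng)
    spike_frames, neuron_traces = generate_spikes_and_calcium(
        config, rng, config.n_neurons
    )
    bleach = config.bleach.rate_green ** np.arange(config.T)
    nema_traces = np.clip(
        config.baseline_glow
        + rng.normal(
            0.0, config.nematocyte_noise_sd, size=(config.n_nematocytes, config.T)
        ),
        0.0,
        None,
    ) * bleach
    traces = (
        np.vstack([neuron_traces, nema_traces])
        if config.n_cells
        else np.zeros((0, config.T))
    )
    all_spikes = spike_frames + [
        np.array([], dtype=int) for _ in range(config.n_nematocytes)
    ]
    return render_movie(
        config,
        trajectories,
        traces,
        spike_frames=all_spikes,
        rng=rng,
    )
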