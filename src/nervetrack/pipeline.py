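"""End-to-end orchestration: detection -> tracking -> stitching ->
calcium extraction -> signal processing -> spike inference.

The run is a pure function of (inputs, config, seed): one seeded generator
feeds every stochastic stage, every intermediate is persisted as CSV/TIFF,
and a manifest records the config hash and seed so outputs are byte-stable
across identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as ntio
from .calcium import SubROIConfig, extract_traces
from .detection import DetectorConfig, detect_stack
from .signals import ProcessingConfig, process_traces
from .spikes import ClusterConfig, build_raster, infer_spikes
from .stitching import StitchConfig, stitch_tracklets
from .synthetic import SyntheticConfig, TwoChannelMovie, generate_movie
from .tracking import LinkerConfig, link_frames

logger = logging.getLogger("nervetrack")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage configs plus I/O paths.

    Either ``red_path``/``green_path`` point at existing TIFF stacks, or a
    ``synthetic`` config triggers movie generation in-run.
    """

    red_path: str | None = None
    green_path: str | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str = "nervetrack_out"
    frame_rate: float = 10.0
    seed: int = 0
    log_level: str = "INFO"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    linker: LinkerConfig = field(default_factory=LinkerConfig)
    stitch: StitchConfig = field(default_factory=StitchConfig)
    subroi: SubROIConfig = field(default_factory=SubROIConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "detector": DetectorConfig,
            "linker": LinkerConfig,
            "stitch": StitchConfig,
            "subroi": SubROIConfig,
            "processing": ProcessingConfig,
            "cluster": ClusterConfig,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("synthetic") is not None and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    out_dir: Path
    detections: list
    tracklets: list
    tracks: list
    traces: list
    kept_traces: list
    removed: list
    trains: list
    raster: object
    truth: object | None = None


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and persist all intermediates under ``out_dir``.

    Any stage failure aborts with the stage name; partial outputs written so
    far are preserved. When ground truth is available (synthetic input) a
    metrics file is written alongside the outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = None

    stage = "input"
    try:
        if config.synthetic is not None:
            movie, truth = generate_movie(config.synthetic)
            ntio.write_stack(out / "red.tif", movie.red)
            ntio.write_stack(out / "green.tif", movie.green)
            _write_truth(out, truth)
        else:
            for name in ("red_path", "green_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} does not exist: {p!r}")
            movie = TwoChannelMovie(
                red=ntio.read_stack(config.red_path),
                green=ntio.read_stack(config.green_path),
                frame_rate=config.frame_rate,
            )
        logger.info("input: %d frames of %dx%d", *movie.shape)

        stage = "detection"
        detections = detect_stack(movie.red, config.detector)
        ntio.detections_to_csv(detections, out / "detections.csv")
        logger.info("detection: %d spots total", sum(len(d) for d in detections))

        stage = "tracking"
        tracklets = link_frames(detections, config.linker)
        ntio.tracklets_to_csv(tracklets, out / "tracklets.csv")
        logger.info("tracking: %d tracklets", len(tracklets))

        stage = "stitching"
        tracks = stitch_tracklets(tracklets, config.stitch)
        ntio.tracks_to_csv(tracks, out / "tracks.csv")
        logger.info("stitching: %d tracks", len(tracks))

        stage = "calcium_linking"
        traces = extract_traces(movie.green, movie.red, tracks, config.subroi)
        ntio.traces_to_csv(traces, out / "traces_raw.csv")

        stage = "signal_processing"
        kept, removed = process_traces(traces, config.processing, rng)
        ntio.traces_to_csv(kept, out / "traces_processed.csv", processed=True)
        _write_removed(out, removed)
        logger.info(
            "signal processing: kept %d traces, removed %d", len(kept), len(removed)
        )

        stage = "spike_inference"
        trains = infer_spikes(kept, config.cluster)
        ntio.spikes_to_csv(trains, out / "spikes.csv")
        raster = build_raster(
            [_shifted_to_zero(t) for t in trains], movie.n_frames
        )
        ntio.raster_to_csv(raster, out / "raster.csv")
        _plot_raster(raster, movie.n_frames, out / "raster.png")
        logger.info(
            "spike inference: %d trains, %d spikes",
            len(trains),
            int(raster.matrix.sum()),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "stages": [
            "detection", "tracking", "stitching", "calcium_linking",
            "signal_processing", "spike_inference",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    if truth is not None:
        _write_metrics(out, tracks, truth)

    return PipelineResult(
        out_dir=out,
        detections=detections,
        tracklets=tracklets,
        tracks=tracks,
        traces=traces,
        kept_traces=kept,
        removed=removed,
        trains=trains,
        raster=raster,
        truth=truth,
    )


def _shifted_to_zero(train):
    return train  # frames already absolute


def _plot_raster(raster, n_frames: int, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for i, row in enumerate(raster.matrix):
        frames = np.flatnonzero(row)
        ax.vlines(frames, i + 0.6, i + 1.4, color="k", lw=1)
    ax.set_xlim(0, n_frames)
    ax.set_ylim(0.5, max(raster.n_neurons, 1) + 0.5)
    ax.set_xlabel("frame")
    ax.set_ylabel("neuron")
    ax.set_title("predicted spikes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_truth(out: Path, truth) -> None:
    import pandas as pd

    rows = []
    for i in range(truth.n_cells):
        for t in range(truth.trajectories.shape[1]):
            rows.append(
                {
                    "cell_id": i,
                    "frame": t,
                    "row": truth.trajectories[i, t, 0],
                    "col": truth.trajectories[i, t, 1],
                    "cell_type": truth.cell_types[i],
                }
            )
    pd.DataFrame(rows).to_csv(out / "ground_truth_tracks.csv", index=False)
    rows = [
        {"cell_id": i, "frame": int(f)}
        for i in range(truth.n_cells)
        for f in truth.spike_frames[i]
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame"]).to_csv(
        out / "ground_truth_spikes.csv", index=False
    )


def _write_removed(out: Path, removed) -> None:
    import pandas as pd

    pd.DataFrame(
        removed, columns=["track_id", "reason", "p_value"]
    ).to_csv(out / "removed_cells.csv", index=False)


def _write_metrics(out: Path, tracks, truth) -> None:
    from .evaluation import tracking_accuracy

    _, mean, sd = tracking_accuracy(tracks, truth.trajectories, tol_px=3.0)
    with open(out / "metrics.json", "w") as fh:
        json.dump(
            {"tracking_accuracy_mean": mean, "tracking_accuracy_sd": sd},
            fh,
            indent=2,
        )
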