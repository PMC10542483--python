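"""Readers and writers for the standard on-disk formats.

Image stacks travel as multi-page uint16 TIFF; every tabular intermediate
(detections, tracklets, tracks, traces, spikes, raster) is a typed CSV so
each stage can be inspected or re-entered independently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calcium import CalciumTrace
from .detection import Detections
from .spikes import SpikeMatrix, SpikeTrain
from .stitching import Track
from .tracking import Tracklet

__all__ = [
    "read_stack",
    "write_stack",
    "detections_to_csv",
    "detections_from_csv",
    "tracklets_to_csv",
    "tracklets_from_csv",
    "tracks_to_csv",
    "tracks_from_csv",
    "traces_to_csv",
    "traces_from_csv",
    "spikes_to_csv",
    "spikes_from_csv",
    "raster_to_csv",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Multi-page TIFF -> (T, H, W) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))


def detections_to_csv(detections: list[Detections], path: str | Path) -> None:
    frames = [d.to_frame() for d in detections if len(d)]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["frame", "label", "row", "col", "area"])
    df.to_csv(path, index=False)


def detections_from_csv(path: str | Path, n_frames: int | None = None) -> list[Detections]:
    df = pd.read_csv(path)
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out = []
    for t in range(n_frames):
        sub = df[df["frame"] == t]
        if len(sub):
            out.append(
                Detections(
                    frame=t,
                    centroids=sub[["row", "col"]].to_numpy(float),
                    areas=sub["area"].to_numpy(int),
                    labels=sub["label"].to_numpy(int),
                )
            )
        else:
            out.append(Detections.empty(t))
    return out


def tracklets_to_csv(tracklets: list[Tracklet], path: str | Path) -> None:
    rows = []
    for tk in tracklets:
        for k in range(len(tk)):
            rows.append(
                {
                    "tracklet_id": tk.id,
                    "frame": tk.start_frame + k,
                    "row": tk.positions[k, 0],
                    "col": tk.positions[k, 1],
                    "is_interpolated": bool(tk.interpolated[k]),
                    "detection_label": int(tk.detection_labels[k]),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "tracklet_id", "frame", "row", "col", "is_interpolated",
            "detection_label",
        ],
    ).to_csv(path, index=False)


def tracklets_from_csv(path: str | Path) -> list[Tracklet]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("tracklet_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(
            Tracklet(
                id=int(tid),
                start_frame=int(sub["frame"].iloc[0]),
                positions=sub[["row", "col"]].to_numpy(float),
                interpolated=sub["is_interpolated"].to_numpy(bool),
                detection_labels=sub["detection_label"].to_numpy(int),
            )
        )
    return out


def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.id,
                    "frame": tr.start_frame + k,
                    "row": tr.positions[k, 0],
                    "col": tr.positions[k, 1],
                    "is_gap_filled": bool(tr.gap_filled[k]),
                }
            )
    pd.DataFrame(
        rows, columns=["track_id", "frame", "row", "col", "is_gap_filled"]
    ).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        gap = sub["is_gap_filled"].to_numpy(bool)
        out.append(
            Track(
                id=int(tid),
                tracklet_ids=[],
                start_frame=int(sub["frame"].iloc[0]),
                positions=sub[["row", "col"]].to_numpy(float),
                gap_filled=gap,
                interpolated=gap.copy(),
            )
        )
    return out


def traces_to_csv(traces: list[CalciumTrace], path: str | Path,
                  processed: bool = False) -> None:
    rows = []
    for tr in traces:
        for k in range(len(tr)):
            row = {
                "track_id": tr.track_id,
                "frame": tr.start_frame + k,
                "raw_green": tr.raw_green[k],
                "control_red": tr.control_red[k],
                "cal_row": tr.calcium_position[k, 0],
                "cal_col": tr.calcium_position[k, 1],
            }
            if processed:
                row["processed"] = (
                    tr.processed[k] if tr.processed is not None else np.nan
                )
            rows.append(row)
    cols = ["track_id", "frame", "raw_green", "control_red", "cal_row", "cal_col"]
    if processed:
        cols.append("processed")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def traces_from_csv(path: str | Path) -> list[CalciumTrace]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tr = CalciumTrace(
            track_id=int(tid),
            start_frame=int(sub["frame"].iloc[0]),
            raw_green=sub["raw_green"].to_numpy(float),
            control_red=sub["control_red"].to_numpy(float),
            calcium_position=sub[["cal_row", "cal_col"]].to_numpy(float),
        )
        if "processed" in sub.columns:
            tr.processed = sub["processed"].to_numpy(float)
        out.append(tr)
    return out


def spikes_to_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = []
    for tr in trains:
        for f, i in zip(tr.frames, tr.intensities):
            rows.append({"track_id": tr.track_id, "frame": int(f), "intensity": i})
    pd.DataFrame(rows, columns=["track_id", "frame", "intensity"]).to_csv(
        path, index=False
    )


def spikes_from_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        out.append(
            SpikeTrain(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(int),
                intensities=sub["intensity"].to_numpy(float),
            )
        )
    return out


def raster_to_csv(raster: SpikeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(raster.matrix)
    df.insert(0, "track_id", raster.track_ids)
    df.to_csv(path, index=False)
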