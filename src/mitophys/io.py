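"""CSV (and TIFF) readers and writers for the pipeline's table formats.

Tidy CSV dialects:

* traces:   group, cell_id, roi_type[cell|background], roi_id, t_s,
            intensity, area_um2
* tracks:   group, track_id, frame, t_s, x_um, y_um, true_phase
* spindles: group, cell_id, pole[a|b], x_um, y_um, z_um
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mt import MTTrack
from .roi import IntensityTrace
from .spindle import SpindlePolePair

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_tracks_csv", "read_tracks_csv",
    "write_spindles_csv", "read_spindles_csv",
    "read_stack",
]


def write_traces_csv(traces: list[IntensityTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "group": tr.group or "",
                    "cell_id": tr.cell_id,
                    "roi_type": "cell",
                    "roi_id": 0,
                    "t_s": tr.t,
                    "intensity": tr.integrated_intensity,
                    "area_um2": tr.area,
                }
            )
        )
        for ri, bg in enumerate(tr.background):
            frames.append(
                pd.DataFrame(
                    {
                        "group": tr.group or "",
                        "cell_id": tr.cell_id,
                        "roi_type": "background",
                        "roi_id": ri,
                        "t_s": tr.t,
                        "intensity": bg,
                        "area_um2": np.nan,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    required = {"cell_id", "roi_type", "roi_id", "t_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"traces CSV missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    df["group"] = df["group"].fillna("")
    traces = []
    for (group, cell_id), sub in df.groupby(["group", "cell_id"], sort=True):
        cell = sub[sub.roi_type == "cell"].sort_values("t_s")
        if cell.empty:
            raise ValueError(f"cell {cell_id!r}: no 'cell' ROI rows")
        bg = sub[sub.roi_type == "background"]
        if bg.empty:
            raise ValueError(f"cell {cell_id!r}: no background ROI rows")
        background = np.stack(
            [
                b.sort_values("t_s")["intensity"].to_numpy()
                for _, b in bg.groupby("roi_id")
            ]
        )
        traces.append(
            IntensityTrace(
                cell_id=str(cell_id),
                t=cell["t_s"].to_numpy(),
                integrated_intensity=cell["intensity"].to_numpy(),
                area=cell["area_um2"].to_numpy(),
                background=background,
                group=str(group) or None,
            )
        )
    return traces


def write_tracks_csv(tracks: list[MTTrack], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        phase = [""] * tr.n_frames
        if tr.phase is not None:
            phase = list(tr.phase) + [""]  # label of interval starting here
        frames.append(
            pd.DataFrame(
                {
                    "group": tr.group or "",
                    "track_id": tr.track_id,
                    "frame": np.arange(tr.n_frames),
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                    "true_phase": phase,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path: str | Path, frame_interval: float | None = None) -> list[MTTrack]:
    """Read comet tracks; ``frame_interval`` (s) overrides/supplies ``t_s``."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    df["group"] = df["group"].fillna("")
    tracks = []
    for (group, track_id), sub in df.groupby(["group", "track_id"], sort=True):
        sub = sub.sort_values("frame")
        if frame_interval is not None:
            t = sub["frame"].to_numpy(dtype=float) * frame_interval
        elif "t_s" in sub.columns:
            t = sub["t_s"].to_numpy(dtype=float)
        else:
            raise ValueError("tracks CSV has no t_s column; pass frame_interval")
        phase = None
        if "true_phase" in sub.columns:
            labels = sub["true_phase"].fillna("").astype(str).to_numpy()[:-1]
            if np.all(labels != ""):
                phase = labels.astype(object)
        tracks.append(
            MTTrack(
                track_id=str(track_id),
                t=t,
                x=sub["x_um"].to_numpy(dtype=float),
                y=sub["y_um"].to_numpy(dtype=float),
                phase=phase,
                group=str(group) or None,
            )
        )
    return tracks


def write_spindles_csv(pairs: list[SpindlePolePair], path: str | Path) -> None:
    rows = []
    for pr in pairs:
        for pole, coords in (("a", pr.pole_a), ("b", pr.pole_b)):
            rows.append(
                {
                    "group": pr.group or "",
                    "cell_id": pr.cell_id,
                    "pole": pole,
                    "x_um": coords[0],
                    "y_um": coords[1],
                    "z_um": coords[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spindles_csv(path: str | Path, voxel_z: float = 1.0) -> list[SpindlePolePair]:
    """Read pole pairs; ``voxel_z`` rescales z for anisotropic acquisitions."""
    df = pd.read_csv(path)
    required = {"cell_id", "pole", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spindles CSV missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    df["group"] = df["group"].fillna("")
    pairs = []
    for (group, cell_id), sub in df.groupby(["group", "cell_id"], sort=True):
        poles = {}
        for _, row in sub.iterrows():
            poles[str(row["pole"]).lower()] = np.array(
                [row["x_um"], row["y_um"], row["z_um"] * voxel_z]
            )
        if set(poles) != {"a", "b"}:
            raise ValueError(f"cell {cell_id!r}: expected exactly poles 'a' and 'b'")
        pairs.append(
            SpindlePolePair(
                cell_id=str(cell_id),
                pole_a=poles["a"],
                pole_b=poles["b"],
                group=str(group) or None,
            )
        )
    return pairs


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single-channel, time-major TIFF stack as a (T, Y, X) array."""
    import tifffile

    stack = np.asarray(tifffile.imread(str(path)))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a T x Y x X stack, got shape {stack.shape}")
    return stack
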