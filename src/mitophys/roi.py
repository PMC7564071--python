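"""ROI quantification: corrected total cell fluorescence (CTCF).

The unit of raw data is one region of interest (ROI) drawn around a cell in a
time-lapse recording, accompanied by a small number of background ROIs placed
on cell-free areas of the same field.  The corrected total cell fluorescence
at each frame is

    CTCF(t) = integrated_intensity(t) - area * mean_background(t),

i.e. the cell's integrated density minus the background level expected over an
area equal to the cell ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityTrace",
    "CTCFTrace",
    "compute_ctcf",
    "extract_roi_traces",
]

#: maximum relative deviation from uniform sample spacing tolerated on input
_GRID_RTOL = 1e-6


def _check_uniform_grid(t: np.ndarray) -> float:
    """Validate that ``t`` is a strictly increasing uniform grid; return dt."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time vector must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time vector must be strictly increasing")
    step = dt.mean()
    if np.max(np.abs(dt - step)) > _GRID_RTOL * step:
        raise ValueError("time vector must be uniformly spaced")
    return float(step)


@dataclass
class IntensityTrace:
    """Raw per-ROI fluorescence time series for one cell.

    Parameters
    ----------
    cell_id :
        Identifier of the cell.
    t :
        Acquisition times in seconds, strictly increasing uniform grid.
    integrated_intensity :
        Integrated density of the cell ROI per frame (sum of pixel values),
        arbitrary fluorescence units.
    area :
        Cell ROI area in µm².  A scalar is broadcast to all frames; a vector
        allows the ROI to change size (e.g. mitotic rounding).
    background :
        Background ROI intensities, shape ``(n_rois, n_frames)`` — the mean
        pixel value of each background ROI per frame.  A 1-D vector is
        treated as a single background ROI.
    group :
        Optional experimental group label (e.g. treatment condition).
    """

    cell_id: str
    t: np.ndarray
    integrated_intensity: np.ndarray
    area: np.ndarray
    background: np.ndarray
    group: str | None = None
    dt: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.integrated_intensity = np.asarray(self.integrated_intensity, dtype=float)
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        self.area = np.broadcast_to(
            np.asarray(self.area, dtype=float), self.t.shape
        ).copy()
        self.dt = _check_uniform_grid(self.t)
        n = self.t.size
        if self.integrated_intensity.shape != (n,):
            raise ValueError("integrated_intensity length does not match time grid")
        if self.background.shape[1] != n:
            raise ValueError("background series length does not match time grid")
        if np.any(self.area <= 0):
            raise ValueError("ROI area must be positive")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def mean_background(self) -> np.ndarray:
        """Per-frame unweighted mean over the background ROIs."""
        return self.background.mean(axis=0)


@dataclass
class CTCFTrace:
    """Background-corrected fluorescence time series for one cell."""

    cell_id: str
    t: np.ndarray
    ctcf: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ctcf = np.asarray(self.ctcf, dtype=float)
        if self.ctcf.shape != self.t.shape:
            raise ValueError("ctcf length does not match time grid")


def compute_ctcf(trace: IntensityTrace) -> CTCFTrace:
    """Corrected total cell fluorescence of a raw ROI trace.

    ``ctcf(t) = integrated_intensity(t) - area(t) * mean_background(t)``
    elementwise; the background ROIs are averaged with equal weight (they are
    drawn at constant, equal size).
    """
    ctcf = trace.integrated_intensity - trace.area * trace.mean_background
    return CTCFTrace(cell_id=trace.cell_id, t=trace.t, ctcf=ctcf, group=trace.group)


def extract_roi_traces(
    stack: np.ndarray,
    cell_masks: dict[str, np.ndarray],
    background_masks: list[np.ndarray],
    sample_interval: float,
    pixel_area: float = 1.0,
) -> list[IntensityTrace]:
    """Measure ROI time series directly from an image stack.

    Parameters
    ----------
    stack :
        Single-channel time series, shape ``(T, Y, X)``.
    cell_masks :
        Mapping from cell id to boolean mask of shape ``(Y, X)``.
    background_masks :
        Boolean masks of the background ROIs, same shape.
    sample_interval :
        Frame interval in seconds.
    pixel_area :
        Area of one pixel in µm².

    Returns
    -------
    One :class:`IntensityTrace` per cell mask; every trace carries the same
    background ROI series (mean pixel value per background mask per frame).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be a T x Y x X array")
    frame_shape = stack.shape[1:]
    t = np.arange(stack.shape[0]) * float(sample_interval)

    def _validate(mask: np.ndarray, what: str) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frame_shape:
            raise ValueError(f"{what} mask shape {mask.shape} != frame {frame_shape}")
        if not mask.any():
            raise ValueError(f"{what} mask is empty")
        return mask

    bg_masks = [_validate(m, "background") for m in background_masks]
    if not bg_masks:
        raise ValueError("at least one background mask is required")
    background = np.stack([stack[:, m].mean(axis=1) for m in bg_masks])

    traces = []
    for cell_id, mask in cell_masks.items():
        mask = _validate(mask, f"cell {cell_id!r}")
        integrated = stack[:, mask].sum(axis=1)
        area = mask.sum() * pixel_area
        traces.append(
            IntensityTrace(
                cell_id=str(cell_id),
                t=t,
                integrated_intensity=integrated,
                area=area,
                background=background,
            )
        )
    return traces
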