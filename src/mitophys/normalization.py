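"""Photobleach detrending and percent-change normalization of CTCF traces.

Photobleaching of the calcium indicator produces a slow, approximately linear
decay of the corrected total cell fluorescence over a two-hour recording.  A
straight line fitted to the whole trace estimates that drift; removing the
slope and expressing the result as percent change relative to the first time
point yields traces that are comparable across cells and experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import CTCFTrace, _check_uniform_grid

__all__ = ["NormalizedTrace", "UnusableCellError", "fit_baseline", "normalize_trace"]


class UnusableCellError(ValueError):
    """The reference level at time zero is too close to zero (or negative)
    for a percent-change normalization to be meaningful; the cell should be
    excluded from downstream analysis."""


@dataclass
class NormalizedTrace:
    """Detrended trace in percent change relative to time zero.

    ``value[0] == 0`` by construction; ``baseline_fit`` records the
    ``(slope, intercept)`` of the photobleaching line that was removed.
    """

    cell_id: str
    t: np.ndarray
    value: np.ndarray
    baseline_fit: tuple[float, float]
    group: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.t.shape:
            raise ValueError("value length does not match time grid")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("normalized values must be finite")

    @property
    def dt(self) -> float:
        return _check_uniform_grid(self.t)


def fit_baseline(trace: CTCFTrace) -> tuple[float, float]:
    """Ordinary least-squares line through the full CTCF trace.

    Returns ``(slope, intercept)`` in fluorescence units per second and
    fluorescence units.  Raises ``ValueError`` for fewer than two points or a
    constant time vector.
    """
    t = np.asarray(trace.t, dtype=float)
    y = np.asarray(trace.ctcf, dtype=float)
    if t.size < 2:
        raise ValueError("baseline fit requires at least 2 time points")
    if np.ptp(t) == 0:
        raise ValueError("time vector is constant; cannot fit a baseline")
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def normalize_trace(
    trace: CTCFTrace,
    *,
    mode: str = "anchored",
    reference: float | None = None,
    epsilon: float | None = None,
) -> NormalizedTrace:
    """Remove the photobleaching slope and convert to percent change vs t=0.

    In the default ``"anchored"`` mode only the slope component of the fitted
    line is subtracted, so the fluorescence level at the first time point is
    preserved and serves as the reference for the percent transform:

        detrended(t) = ctcf(t) - slope * (t - t0)
        value(t)     = 100 * (detrended(t) - detrended(t0)) / detrended(t0)

    Subtracting the whole fitted line would leave residuals centred on zero,
    making "percent change relative to time zero" ill-defined; anchoring the
    fit at t=0 keeps that semantics while avoiding division by ≈0.  The
    ``"literal"`` mode performs the full-line subtraction and requires an
    explicit ``reference`` level (e.g. the fitted intercept) for the percent
    scaling.

    Raises
    ------
    UnusableCellError
        If the reference level is ≤ 0 or smaller in magnitude than
        ``epsilon`` (default ``1e-6 * |intercept|``).
    """
    slope, intercept = fit_baseline(trace)
    t = np.asarray(trace.t, dtype=float)
    y = np.asarray(trace.ctcf, dtype=float)

    if mode == "anchored":
        detrended = y - slope * (t - t[0])
        ref = detrended[0]
    elif mode == "literal":
        if reference is None:
            raise ValueError("literal mode requires an explicit reference level")
        detrended = y - (slope * t + intercept)
        ref = float(reference)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    if epsilon is None:
        epsilon = 1e-6 * abs(intercept)
    if ref <= 0 or abs(ref) <= epsilon:
        raise UnusableCellError(
            f"cell {trace.cell_id!r}: reference level {ref:.4g} at t=0 is "
            "non-positive or indistinguishable from zero"
        )

    value = 100.0 * (detrended - detrended[0]) / ref
    return NormalizedTrace(
        cell_id=trace.cell_id,
        t=t,
        value=value,
        baseline_fit=(slope, intercept),
        group=trace.group,
    )
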