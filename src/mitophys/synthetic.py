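"""Synthetic recordings with known ground truth for every analysis stage.

Three generators emulate the data the pipeline consumes:

* **Calcium traces** — 120-min Fluo-4 recordings sampled every 10 s: a
  constant baseline, a linear photobleaching drift, sinusoidal oscillation
  components in the mHz range, optional Gaussian-shaped calcium transients,
  Gaussian sample noise, and a set of background ROIs.
* **Microtubule tracks** — two-state dynamic instability: a plus tip moves
  along a straight axis at a constant growth speed, switches to shrinkage at
  an exponential catastrophe rate, back at the rescue rate, and is sampled at
  the frame interval with isotropic position noise.  Ground-truth phase
  labels are retained per interval.
* **Spindle pole pairs** — two 3D centroids separated by a given distance at
  a given tilt to the substrate plane, with a random azimuth.

All generators are deterministic given their seed; cohorts derive per-cell
seeds from the master seed with an order-independent scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .mt import GROWTH, SHRINK, MTTrack
from .roi import IntensityTrace
from .spindle import SpindlePolePair

__all__ = [
    "TraceSimParams",
    "DynamicsSimParams",
    "SpindleSimParams",
    "simulate_trace",
    "simulate_cohort",
    "simulate_mt_tracks",
    "simulate_spindles",
]

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _derive_seed(*entropy: int) -> int:
    """Deterministic child seed from a tuple of integers (< 2**31).

    Uses :class:`numpy.random.SeedSequence` so that per-cell streams are
    well separated and independent of generation order.
    """
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of one simulated calcium recording.

    Defaults emulate the study conditions: a 2-h recording sampled every
    10 s, a dominant oscillation at the control-group frequency of
    9.19 mHz with an amplitude of 5% of baseline, sample noise at 20% of
    that amplitude, and a linear bleach losing ~10% of the baseline over
    the recording.  Three background ROIs of constant mean are emitted.
    """

    duration: float = 7200.0          # s
    sample_interval: float = 10.0     # s
    baseline_f0: float = 100.0        # fluorescence units
    bleach_slope: float = -100.0 * 0.10 / 7200.0  # units / s (≤ 0)
    oscillation_components: tuple[tuple[float, float, float], ...] = (
        (9.19e-3, 5.0, 0.0),          # (frequency Hz, amplitude, phase rad)
    )
    transient_peaks: tuple[tuple[float, float, float], ...] = ()
    # (center_time s, height units, fwhm s)
    noise_sd: float = 1.0             # units
    cell_area: float = 400.0          # µm²
    n_background_rois: int = 3
    background_mean: float = 10.0     # units (per-pixel mean level)
    # SD of a background ROI's *mean* intensity.  A cell-sized ROI of ~400
    # pixels whose integrated noise is noise_sd has per-pixel noise
    # noise_sd/sqrt(400) and mean noise noise_sd/400 — so the default keeps
    # the background term area*mean_background at the same noise scale as
    # the cell ROI rather than amplifying it by the area.
    background_noise_sd: float = 1.0 / 400.0  # units
    background_bleach: bool = False   # background shares the cell's drift
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.noise_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.bleach_slope > 0:
            raise ValueError("bleach_slope must be <= 0 (photobleaching decays)")
        if self.n_background_rois < 1:
            raise ValueError("need at least one background ROI")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        nyquist = 0.5 / self.sample_interval
        for f, _, _ in self.oscillation_components:
            if f >= nyquist:
                raise ValueError(
                    f"oscillation at {f} Hz is at or above the Nyquist "
                    f"frequency {nyquist} Hz and would alias"
                )

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sample_interval))
        return np.arange(n) * self.sample_interval


def cell_signal(params: TraceSimParams, t: np.ndarray) -> np.ndarray:
    """Noise-free cell signal component (ground truth for CTCF recovery)."""
    y = params.baseline_f0 + params.bleach_slope * t
    for f, amp, phase in params.oscillation_components:
        y = y + amp * np.sin(2.0 * np.pi * f * t + phase)
    for center, height, fwhm in params.transient_peaks:
        sigma = fwhm / FWHM_PER_SIGMA
        y = y + height * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return y


def simulate_trace(params: TraceSimParams) -> IntensityTrace:
    """One cell trace plus its background ROIs on the uniform time grid.

    The cell ROI's integrated intensity is the cell signal plus Gaussian
    sample noise plus the background level under the cell (background mean ×
    ROI area), so that CTCF correction recovers the cell signal.  Background
    ROIs report the background mean plus independent noise.
    """
    params.validate()
    t = params.time_grid
    rng = np.random.default_rng(params.seed)

    bg_level = np.full(t.size, params.background_mean)
    if params.background_bleach:
        # drift expressed per unit area so CTCF still isolates the cell term
        bg_level = bg_level + (params.bleach_slope / params.cell_area) * t

    cell = cell_signal(params, t) + rng.normal(0.0, params.noise_sd, t.size)
    integrated = cell + params.cell_area * bg_level
    background = bg_level + rng.normal(
        0.0, params.background_noise_sd, (params.n_background_rois, t.size)
    )
    return IntensityTrace(
        cell_id="sim",
        t=t,
        integrated_intensity=integrated,
        area=params.cell_area,
        background=background,
    )


def simulate_cohort(
    params_per_group: dict[str, TraceSimParams], n_cells: int
) -> list[IntensityTrace]:
    """``n_cells`` independent traces per experimental group.

    Per-cell seeds are derived from each group's master seed and the group
    and cell indices, so any subset of the cohort is reproducible without
    regenerating the rest.
    """
    if not params_per_group:
        raise ValueError("params_per_group must contain at least one group")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    traces = []
    for gi, (group, params) in enumerate(sorted(params_per_group.items())):
        for ci in range(n_cells):
            cell_params = replace(
                params, seed=_derive_seed(params.seed, gi, ci)
            )
            trace = simulate_trace(cell_params)
            trace.cell_id = f"{group}_{ci:03d}"
            trace.group = group
            traces.append(trace)
    return traces


@dataclass(frozen=True)
class DynamicsSimParams:
    """Two-state dynamic-instability simulation parameters.

    Defaults match prometaphase imaging conditions: 0.5-s frames over 1 min,
    a growth speed at the control-group value of 19.12 µm·min⁻¹, and a
    faster shrinkage, as is typical of dynamic instability.  With symmetric
    catastrophe/rescue rates λ the switch count over a recording of length T
    is Poisson(λ·T) — whichever phase is active, the next switch arrives at
    rate λ — so the default rates of 2 min⁻¹ give an expected dynamicity of
    2 events·min⁻¹.  For unequal rates the long-run switching rate is the
    alternating-renewal value 2/(1/λ_cat + 1/λ_res).
    """

    growth_speed: float = 19.12       # µm·min⁻¹
    shrink_speed: float = 30.0        # µm·min⁻¹
    catastrophe_rate: float = 2.0     # growth→shrink events·min⁻¹
    rescue_rate: float = 2.0          # shrink→growth events·min⁻¹
    frame_interval: float = 0.5       # s
    duration: float = 60.0            # s
    n_tracks: int = 50
    position_noise_sd: float = 0.02   # µm, isotropic per frame
    start_phase: str = GROWTH
    seed: int = 0

    def validate(self) -> None:
        if min(self.growth_speed, self.shrink_speed) < 0:
            raise ValueError("speeds must be >= 0")
        if min(self.catastrophe_rate, self.rescue_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")
        if self.start_phase not in (GROWTH, SHRINK):
            raise ValueError("start_phase must be 'growth' or 'shrink'")


def _simulate_phase_segments(
    params: DynamicsSimParams, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Continuous-time (start, stop, phase) segments covering the recording."""
    segments = []
    t_cur, phase = 0.0, params.start_phase
    while t_cur < params.duration:
        rate = (
            params.catastrophe_rate if phase == GROWTH else params.rescue_rate
        ) / 60.0  # per second
        hold = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_next = min(t_cur + hold, params.duration)
        segments.append((t_cur, t_next, phase))
        t_cur = t_next
        phase = SHRINK if phase == GROWTH else GROWTH
    return segments


def _sample_track(
    params: DynamicsSimParams, rng: np.random.Generator, track_id: str
) -> MTTrack:
    segments = _simulate_phase_segments(params, rng)
    t = np.arange(int(math.floor(params.duration / params.frame_interval)) + 1)
    t = t * params.frame_interval

    def pos_at(time: float) -> float:
        s = 0.0
        for start, stop, phase in segments:
            dt_in = max(0.0, min(time, stop) - start)
            v = params.growth_speed if phase == GROWTH else -params.shrink_speed
            s += (v / 60.0) * dt_in
        return s

    s = np.array([pos_at(ti) for ti in t])

    # ground-truth interval label: phase occupying the majority of the interval
    labels = np.empty(t.size - 1, dtype=object)
    for k in range(t.size - 1):
        t0, t1 = t[k], t[k + 1]
        time_in_growth = sum(
            max(0.0, min(t1, stop) - max(t0, start))
            for start, stop, phase in segments
            if phase == GROWTH
        )
        labels[k] = GROWTH if time_in_growth >= 0.5 * (t1 - t0) else SHRINK

    theta = rng.uniform(0.0, 2.0 * np.pi)
    origin = rng.uniform(0.0, 20.0, size=2)
    x = origin[0] + s * np.cos(theta)
    y = origin[1] + s * np.sin(theta)
    if params.position_noise_sd > 0:
        x = x + rng.normal(0.0, params.position_noise_sd, t.size)
        y = y + rng.normal(0.0, params.position_noise_sd, t.size)
    return MTTrack(track_id=track_id, t=t, x=x, y=y, phase=labels)


def simulate_mt_tracks(params: DynamicsSimParams) -> list[MTTrack]:
    """Simulate ``n_tracks`` plus-end trajectories with ground-truth phases."""
    params.validate()
    tracks = []
    for i in range(params.n_tracks):
        rng = np.random.default_rng(_derive_seed(params.seed, i))
        tracks.append(_sample_track(params, rng, track_id=f"track_{i:04d}"))
    return tracks


@dataclass(frozen=True)
class SpindleSimParams:
    """Spindle pole-pair geometry simulation.

    ``tilt_angle_deg`` may be a single angle in [0, 90] applied to every
    cell, a sequence of per-cell angles, or a callable ``f(rng, n) ->
    array`` sampling a distribution over tilt.
    """

    n_cells: int = 50
    pole_distance: float = 10.0       # µm
    tilt_angle_deg: float | Sequence[float] | Callable = 9.68
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pole_distance <= 0:
            raise ValueError("pole_distance must be positive")


def _tilt_values(params: SpindleSimParams, rng: np.random.Generator) -> np.ndarray:
    tilt = params.tilt_angle_deg
    if callable(tilt):
        values = np.asarray(tilt(rng, params.n_cells), dtype=float)
    elif np.isscalar(tilt):
        values = np.full(params.n_cells, float(tilt))
    else:
        values = np.asarray(tilt, dtype=float)
        if values.shape != (params.n_cells,):
            raise ValueError("per-cell tilt sequence must have length n_cells")
    if np.any((values < 0) | (values > 90)):
        raise ValueError("tilt angles must lie in [0, 90] degrees")
    return values


def simulate_spindles(params: SpindleSimParams) -> list[SpindlePolePair]:
    """Pole pairs at the requested distance and tilt, random azimuth.

    Pole A sits on the substrate plane at the origin; pole B is offset by
    ``pole_distance·cos(tilt)`` in-plane (random direction) and
    ``pole_distance·sin(tilt)`` in z.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    tilts = _tilt_values(params, rng)
    pairs = []
    for i, tilt in enumerate(tilts):
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        r = math.radians(tilt)
        dxy = params.pole_distance * math.cos(r)
        dz = params.pole_distance * math.sin(r)
        pole_a = np.zeros(3)
        pole_b = np.array(
            [dxy * math.cos(azimuth), dxy * math.sin(azimuth), dz]
        )
        pairs.append(
            SpindlePolePair(cell_id=f"cell_{i:03d}", pole_a=pole_a, pole_b=pole_b)
        )
    return pairs
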