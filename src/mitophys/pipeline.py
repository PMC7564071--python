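"""End-to-end per-cell analysis: raw ROI trace → time- and frequency-domain
metrics, assembled into tidy per-cell tables ready for group statistics."""

from __future__ import annotations

import logging

import pandas as pd

from . import peaks as peaks_mod
from .normalization import UnusableCellError, normalize_trace
from .roi import IntensityTrace, compute_ctcf
from .spectral import DEFAULT_TOP_K, spectral_summary

log = logging.getLogger(__name__)

__all__ = ["analyze_trace", "analyze_cohort"]


def analyze_trace(
    trace: IntensityTrace,
    *,
    min_prominence: float | None = None,
    k: int = DEFAULT_TOP_K,
) -> dict:
    """All per-cell metrics for one raw trace.

    Runs CTCF correction, photobleach normalization, peak metrics and the
    spectral summary; returns one flat record.  The weighted average
    frequency is reported in mHz, the unit in which mitotic calcium
    oscillations are conventionally quoted.
    """
    ctcf = compute_ctcf(trace)
    norm = normalize_trace(ctcf)
    pk = peaks_mod.find_peaks(norm, min_prominence)
    summary = peaks_mod.summarize_trace(norm, pk)
    spectrum = spectral_summary(norm, k=k)
    return {
        "group": trace.group,
        "cell_id": trace.cell_id,
        "auc_pct_s": summary.auc,
        "median_prominence_pct": summary.median_prominence,
        "median_fwhm_s": summary.median_fwhm,
        "n_peaks": summary.n_peaks,
        "weighted_avg_freq_mHz": spectrum.weighted_average_frequency * 1e3,
    }


def analyze_cohort(
    traces: list[IntensityTrace],
    *,
    min_prominence: float | None = None,
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Per-cell metric table for a cohort; unusable cells are dropped with a
    logged warning (mirroring manual exclusion of cells whose baseline
    fluorescence is indistinguishable from background)."""
    rows = []
    n_excluded = 0
    for trace in traces:
        try:
            rows.append(analyze_trace(trace, min_prominence=min_prominence, k=k))
        except UnusableCellError as exc:
            n_excluded += 1
            log.warning("excluded: %s", exc)
    if not rows:
        raise ValueError("no usable cells in the cohort")
    if n_excluded:
        log.info("excluded %d of %d cells", n_excluded, len(traces))
    return pd.DataFrame(rows)
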