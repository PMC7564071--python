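"""Nonparametric group comparisons and percent-difference report tables.

All group contrasts in this package are pairwise two-sided Mann–Whitney
U-tests with median/IQR summaries, the standard choice for the skewed
per-cell distributions these assays produce.  Percent differences are
reported relative to an explicit reference group in both directions, because
the convention (treated vs control or control vs treated) is a frequent
source of ambiguity in published effect sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["mann_whitney", "percent_difference", "build_report"]

#: exact null distribution is enumerated when the smaller sample is this
#: small and there are no ties; otherwise the normal approximation with tie
#: and continuity corrections is used
EXACT_N_MAX = 8


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U-test.

    Returns ``(U, p)`` where U is the statistic of the first sample.  The
    exact permutation null is used when ``min(n_a, n_b) <= 8`` and the
    pooled data contain no ties; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference of ``value`` relative to ``reference``.

    ``100 * (value - reference) / reference`` — a result of −62.5 reads as
    "62.5% lower than the reference".  Raises for a zero reference.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def _summary_stats(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.nanpercentile(x, [25, 50, 75])
    n_valid = int(np.sum(~np.isnan(x)))
    sem = float(np.nanstd(x, ddof=1) / np.sqrt(n_valid)) if n_valid > 1 else np.nan
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "mean": float(np.nanmean(x)),
        "sem": sem,
    }


def build_report(
    summaries: pd.DataFrame,
    *,
    metrics: list[str] | None = None,
    group_col: str = "group",
    reference: str | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Tidy comparison table over per-cell (or per-track) metric columns.

    Parameters
    ----------
    summaries :
        One row per cell/track with a group-label column and numeric metric
        columns.
    metrics :
        Metric columns to report; default: every numeric column.
    reference :
        Reference group for the comparisons; default: first group in sorted
        order.  With a single group only the summaries are produced.
    bonferroni :
        Multiply p-values by the number of comparisons (off by default; the
        pairwise tests here are conventionally reported uncorrected).

    Returns
    -------
    One row per (metric, group) with n, median, IQR, mean ± SEM, and — for
    non-reference groups — U, p, and percent difference of the group median
    in both conventions (vs the reference and the reference vs the group).
    """
    if group_col not in summaries.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if metrics is None:
        metrics = [
            c
            for c in summaries.columns
            if c != group_col and pd.api.types.is_numeric_dtype(summaries[c])
        ]
    groups = sorted(summaries[group_col].unique())
    if reference is None:
        reference = groups[0]
    elif reference not in groups:
        raise ValueError(f"reference group {reference!r} not present in data")

    rows = []
    for metric in metrics:
        by_group = {
            g: summaries.loc[summaries[group_col] == g, metric].to_numpy(dtype=float)
            for g in groups
        }
        ref_x = by_group[reference][~np.isnan(by_group[reference])]
        ref_median = float(np.median(ref_x)) if ref_x.size else np.nan
        for g in groups:
            x = by_group[g][~np.isnan(by_group[g])]
            row = {"metric": metric, "group": g, "reference": reference, "n": x.size}
            row.update(_summary_stats(x) if x.size else
                       dict.fromkeys(["median", "q1", "q3", "mean", "sem"], np.nan))
            if g != reference and x.size and ref_x.size:
                u, p = mann_whitney(x, ref_x)
                row["U"] = u
                row["p_value"] = min(1.0, p * (len(groups) - 1)) if bonferroni else p
                if ref_median != 0:
                    row["pct_diff_vs_reference"] = percent_difference(
                        row["median"], ref_median
                    )
                if row["median"] != 0:
                    row["pct_diff_reference_vs_group"] = percent_difference(
                        ref_median, row["median"]
                    )
            rows.append(row)
    return pd.DataFrame(rows)
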