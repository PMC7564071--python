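# mitophys

Quantitative analysis of mitotic-cell physiology from live-cell imaging:

* **Calcium oscillations** — per-cell Fluo-4 ROI time series are converted to
  corrected total cell fluorescence (CTCF), detrended for photobleaching,
  expressed as percent change relative to time zero, and summarized in the
  time domain (trapezoidal AUC, peak prominence, FWHM) and in the frequency
  domain (single-sided power spectral density and the PSD-weighted mean of
  the 15 strongest components — the *weighted average frequency* of the
  oscillation, typically a few mHz in cells at the G2/M boundary).
* **Microtubule plus-end dynamics** — EB3 comet tracks (x, y positions at
  0.5-s frames) yield the dynamic-instability metrics: growth speed
  (µm·min⁻¹), growth length per excursion (µm), and dynamicity
  (growth↔shrink switches·min⁻¹).
* **Mitotic spindle geometry** — two 3D centrosome centroids per cell give
  the spindle tilt angle to the growth substrate, θ = atan2(|Δz|, √(Δx²+Δy²)),
  and the inter-pole distance.
* **Group statistics** — median/IQR summaries, two-sided Mann–Whitney
  U-tests (exact for small tie-free samples), and percent differences with
  an explicit reference group.
* **Synthetic data** — seeded generators emulate 120-min recordings sampled
  every 10 s (baseline, linear bleach, mHz sinusoids, Gaussian transients,
  noise, background ROIs), two-state dynamic-instability tracks with
  ground-truth phase labels, and tilted spindle pole pairs — so every
  analysis stage can be validated against known ground truth.

The core spectral estimator: for a normalized trace x(t) on a uniform grid,
the single-sided PSD is P(f) = |X(f)|²/(N·fs) (interior bins doubled), the
top K = 15 non-DC components are selected by descending PSD, and

    f̄ = Σ fᵢ·P(fᵢ) / Σ P(fᵢ)

is reported as the weighted average oscillation frequency.

## Worked example

Simulate a two-condition calcium cohort (a vehicle control oscillating at
9.19 mHz and an ORAI1-blocked condition at 3.45 mHz), analyze every cell,
and compare the groups:

```python
import mitophys as mp

groups = {
    "DMSO":   mp.TraceSimParams(oscillation_components=((9.19e-3, 5.0, 0.0),), seed=1),
    "AnCoA4": mp.TraceSimParams(oscillation_components=((3.45e-3, 5.0, 0.0),), seed=2),
}
traces = mp.simulate_cohort(groups, n_cells=10)
cells = mp.analyze_cohort(traces)
report = mp.build_report(
    cells, metrics=["weighted_avg_freq_mHz"], reference="DMSO"
)
print(report[["group", "n", "median", "U", "p_value", "pct_diff_vs_reference"]])
```

```
    group   n    median    U   p_value  pct_diff_vs_reference
0  AnCoA4  10  3.622294  0.0  0.000183             -61.051569
1    DMSO  10  9.300230  NaN       NaN                    NaN
```

The ORAI1-blocked cells oscillate about 61% slower than the vehicle
controls (medians 3.62 vs 9.30 mHz, Mann–Whitney p ≈ 2·10⁻⁴), recovering
the injected ~62% contrast. The same workflow is available from the shell:

```bash
mitophys simulate traces --config cohort.yaml --seed 1 --out sim/
mitophys analyze-traces  --in sim/traces.csv --out cells.csv
mitophys report          --in cells.csv --out report.csv --reference DMSO
```

with analogous `simulate tracks` / `analyze-tracks` and
`simulate spindles` / `spindle-angle` commands for the microtubule and
spindle-geometry pipelines.

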