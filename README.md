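# flicrhythm

Feeding-rhythm analysis for FLIC capacitance monitors, from raw CSV to
circadian statistics.

The Fly Liquid-food Interaction Counter (FLIC) records, at millisecond
resolution, the capacitance change produced every time a *Drosophila*
touches the liquid food in one of a monitor's 12 wells. Those raw traces
carry three components: a high, slowly drifting sensor baseline; short
positive deflections during food contacts; and sensor noise. Turning
them into biology — how much a fly eats, when it eats, and whether its
feeding free-runs with a circadian period — requires a pipeline:

1. **Baselining** — estimate and subtract the drifting baseline, by a
   centered running median (RM, default 5-min window) or by asymmetric
   least squares (ALS): the baseline *z* minimizes
   `Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²zᵢ)²` with weights iterated to
   `wᵢ = p` where `yᵢ > zᵢ` and `1−p` otherwise, so that for small *p*
   the fit hugs the underside of the trace and feeding peaks survive
   subtraction.
2. **Event calling** — the four classic FLIC parameters: samples at or
   above the *feeding minimum* are interactions; maximal interaction
   runs at least *consecutive licks* long whose peak reaches the
   *feeding threshold* are feeding events; events closer than the *gap*
   (link) are merged into one bout.
3. **Summaries** — per-well totals, per-condition mean ± SD/SEM, binned
   time series (1 min / 30 min / 1 h), per-well normalization (by total
   or by maximum), events per calendar day, day/night splits against a
   light schedule, average daily profiles, and Tukey-fence outlier
   flags.
4. **Circadian analysis** — on the constant-darkness (DD) window, the
   autocorrelation periodogram: power at candidate period `τ = k·Δ` is
   the lag-k autocorrelation
   `r_k = Σ_{t≤N−k}(x_t−x̄)(x_{t+k}−x̄) / Σ(x_t−x̄)²`; the peak over the
   searched band (default 16–32 h) estimates the free-running period,
   with the white-noise per-lag significance line `z₁₋α/√N` and p-value
   `1 − Φ(r_peak·√N)`.

A synthetic-signal generator (`flicrhythm.synth`) produces raw
FLIC-dialect traces with known ground truth — drifting baseline,
rectangular feeding bouts from an inhomogeneous Poisson process with
flat, bimodal (peaks at the light transitions) or sinusoidal rate
profiles, and Gaussian noise — so every stage of the pipeline is
testable end to end without hardware.

Intended users: chronobiology and feeding-behavior labs who want the
interactive FLIC workflow as a scriptable, reproducible library and CLI.

## Worked example

Simulate the standard assay — 12 wells, 3 days of 12:12 LD (lights on
09:00) then 4 days of DD, wells 1–6 an arrhythmic "clock-mutant" (flat
bout rate), wells 7–12 wild type (bimodal rate peaking at the light
transitions) — then run the full pipeline:

```sh
flicrhythm simulate -c experiment.toml
flicrhythm run -c experiment.toml
```

with `experiment.toml` containing, e.g.:

```toml
[input]
paths = ["DFM_1.csv"]
[input.dialect]
sample_interval_ms = 1000
[conditions.1]
clk-mutant = [1, 2, 3, 4, 5, 6]
wild-type = [7, 8, 9, 10, 11, 12]
[light]
lights_on = "09:00"
lights_off = "21:00"
[baseline]
method = "rm"
[events]
feeding_minimum = 5
feeding_threshold = 15
consecutive_licks = 2
gap = "5 samples"
[circadian]
dd_start = 2021-07-04
dd_end = 2021-07-07
[simulate]
n_wells = 12
n_ld_days = 3
n_dd_days = 4
seed = 1
[output]
dir = "out"
```

The output directory then holds the full CSV set (events, individual
and group stats, binned series, events per day, day/night table, daily
profile, periodogram tables, plus a provenance copy of the config and a
run log). With the config above, `out/group_stats.csv` reads

```
condition,n,mean,sd,sem
clk-mutant,6,385.167,14.5797,5.95212
wild-type,6,298.333,15.3058,6.24856
```

i.e. each mutant well produced ~385 feeding events over the week and
each wild-type well ~298, and `out/periodogram_summary.csv` shows every
wild-type well with a significant free-running period at ~24 h
(`signif_threshold = 0.1187` for N = 192 half-hour bins):

```
monitor,well,condition,peak_period_h,peak_power,p_value,signif_threshold,outlier
1,7,wild-type,23.5,0.342498,1.03845e-06,0.118707,False
1,8,wild-type,24,0.258477,0.000170771,0.118707,False
1,9,wild-type,24,0.343231,9.87597e-07,0.118707,False
```

while the flat-rate mutant wells peak at essentially arbitrary periods
with powers an order of magnitude closer to the noise line. The pipeline
also warns that a 4-day DD window gives fragile rhythm statistics
(longer DD windows are recommended).

Every stage is equally usable as a library:

```python
from flicrhythm import (SimulationParams, simulate_experiment,
                        BaselineParams, baseline_table,
                        EventParams, call_all_events)
table, truth = simulate_experiment(SimulationParams(seed=1))
events = call_all_events(baseline_table(table, BaselineParams()), EventParams())
```

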