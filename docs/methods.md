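# Methods

This note documents the models, conventions and numerical choices behind
`flicrhythm`, and what the simulation-based tests do and do not
demonstrate about real recordings.

## Input model and conventions

A FLIC monitor file is one CSV per Drosophila Feeding Monitor with a
header row `Sample, Date, Time, MSec, W1..W12`, wall-clock timestamps at
second resolution plus a millisecond column, and integer capacitance
readings for 12 wells at a nominal 5 Hz (200 ms). Firmware revisions
differ, so every aspect of this layout is a `Dialect` field; the pinned
default is documented, not assumed universal. The monitor number is
parsed from the filename (first integer after the token `DFM`, falling
back to the first integer anywhere; an explicit override always wins).

Wells are 1-based (W1–W12) throughout, matching the hardware labels.
Date trimming is whole-day inclusive on both ends, matching date-picker
semantics. All bin grids are anchored at the midnight preceding the
first sample, so a bin labelled 09:00 is 09:00 wall clock regardless of
when the recording started; zeitgeber-time display offsets are a
presentation concern, not a data one.

## Baselining

**Running median (RM).** The window is given in minutes and converted
to an odd sample count (round half up), so the median is well defined;
default 5 min. At the recording edges the centered window shrinks
(truncated) rather than padding, which avoids phantom deflections at
the boundaries. RM is exactly invariant to adding a constant to integer
raw counts.

**Asymmetric least squares (ALS).** The baseline z minimizes
`Σ w_i (y_i − z_i)² + λ Σ (Δ²z_i)²` with `w_i = p` above the fit and
`1 − p` below, iterated until the weight vector stops changing (at most
`max_iter = 20` rounds; non-convergence warns and returns the last
iterate, which in practice differs from the fixed point only where
residuals sit at rounding level). Defaults: `λ = 1e8` at 5 Hz sampling
and `p = 0.01` — the smoother's equivalent bandwidth (~λ^{1/4} samples
≈ 20 s at 5 Hz) sits far above the ~1–10 s bout timescale while the
asymmetry pins the fit under the feeding peaks; ALS therefore needs no
per-experiment tuning. The solve uses a symmetric pentadiagonal
(banded Cholesky) factorization, O(n) per iteration.

Two numerical points worth knowing:

* The signal is median-centered before solving. The fit is
  translation-equivariant, and removing the large DC offset both keeps
  the ill-conditioned system accurate and makes "add a constant to the
  input" a bit-exact no-op on integer data.
* The normal system's condition number is ≈ 16·λ/p (≈ 1.6e11 at the
  defaults), so *any* two double-precision solvers can disagree near
  1e-7 relative at λ = 1e8. The dense-oracle equivalence tests
  therefore assert 1e-8 agreement at λ ≤ 1e6, where float64 supports
  it, and 1e-6 at the default λ.

**Chunked processing.** Full-experiment ALS systems are large, so
tables are processed in 24 h chunks. Pieces are fitted on the chunk
plus an extension on each side and joined with complementary linear
cross-fades over a zone centered on every chunk boundary (zone width =
one RM window, or 10 min for ALS; extension = twice that). For RM this
is bit-identical to the one-shot result (every blended sample's window
lies inside both pieces); for ALS the chunked and global fits can
differ by ~1e-5 of range in the interior — both are valid smoother
outputs — but the joins add no discontinuity: the seam test asserts
that the sample-to-sample increments of the chunked output match the
one-shot fit to 1e-6 of the signal range.

## Event calling

Pinned algorithm, in order: (1) samples with baselined value ≥
`feeding_minimum` are interactions; (2) maximal consecutive interaction
runs are extracted; (3) a run qualifies if its length ≥
`consecutive_licks` and (default `threshold_mode="peak"`) its maximum ≥
`feeding_threshold` (mode `"all"` demands every sample pass); (4)
qualified events whose separation (next onset − previous end) is ≤ the
gap are merged. All comparisons are inclusive, so ties are
deterministic. The gap requires an explicit unit — `"5 samples"`
(monitor-code convention, the default preset `5/15/2/5 samples`) or
seconds (`"1.0 s"`). Qualification precedes merging because the gap is
defined as time *between events*; an event's time for binning is its
onset.

A caveat discovered while proving properties: the event *count* is not
globally monotone in the qualification parameters. Raising
`feeding_minimum` can split one run into two events, and — with merging
active — disqualifying the middle event of a merged bout can split it
in two. What is provable, and property-tested: the count is
non-increasing in the gap always, and non-increasing in
`feeding_threshold` and `consecutive_licks` when merging is off
(gap = 0). The caller itself is validated by exact equivalence with a
brute-force enumerator on ~800k exhaustive small series plus random
series.

Per-event durations are retained internally (onset and end), but all
shipped summaries use counts only.

## Summaries

* Group statistics use the sample SD (n−1); SEM = SD/√n; both reported
  as missing for single-well groups.
* Normalization divides each well's binned series by its total
  (default) or by its maximum bin; zero-total wells stay zero and are
  warned about. Normalizing is inherited: profiles and periodograms
  consume whatever series they are handed. Sum-normalization commutes
  with re-binning.
* Outlier flags use Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` with
  hinge quartiles (medians of the lower/upper halves, the halves
  sharing the middle value at odd n), the boxplot-whisker convention;
  groups of fewer than 4 wells are never flagged.
* Day/night assignment is by event onset against the half-open day
  interval `[lights_on, lights_off)`, over the entire loaded span —
  LD vs DD days are not distinguished; trim first when that matters.
* Daily profiles use only complete calendar days; per time-of-day bin,
  the per-day per-well values of a condition are pooled and summarized
  by mean ± SEM/SD. (With a single well this reduces to variation
  across days, which is what makes a perfectly periodic signal show
  zero error bars.)
* 1-min bins are supported but intended for sub-day recordings; a
  warning fires on longer spans, since short bins add noise that
  propagates into the rhythmicity statistics.

## Circadian analysis

The periodogram of a (DD-trimmed, 30-min binned by default) series is
the sample autocorrelation `r_k` (biased normalization, the
`stats::acf` convention: numerator summed over N−k terms, denominator
over all N) at lags spanning the searched band, default 16–32 h. The
peak `r_k` estimates the free-running period; ties break toward the
smaller period. Significance uses the large-lag white-noise
approximation `r_k ~ N(0, 1/N)`: one-sided per-lag line
`signif_threshold = z₁₋α/√N` (α = 0.05) and peak p-value
`1 − Φ(r_peak√N)`, floored at machine epsilon. DD windows shorter than
5 days trigger a warning — rhythm statistics on 4 DD days are fragile.

Two documented limitations of this (conventional) significance rule:

* **It is per-lag, not family-wise.** With ~33 lags in the default
  band, a genuinely arrhythmic (white-noise) well exceeds the line at
  *some* lag far more often than α — Monte Carlo puts the fraction of
  flat-rate wells whose *peak* stays below the line near 40–45% at
  N = 192, not 95%. Treat "peak above the line" as descriptive, not as
  a calibrated per-well rhythmicity test; a Šidák-style correction
  would be calibrated per well but is not what the conventional
  periodogram displays.
* **Peak localization is coarse at short windows.** At 4 DD days and
  30-min bins (N = 192) the cosine ACF peak is nearly flat across
  neighboring lags (per-lag curvature ~0.9% of the peak) while the
  estimator's triangular taper tilts it by ~0.5% per lag, so the argmax
  scatters over ±1–2 lags (±0.5–1 h) at any realistic event rate:
  about half of simulated 24 h-rhythmic wells peak within ±0.5 h, ~95%
  within ±1.5 h. Longer DD windows tighten this roughly as 1/N.

The per-lag exceedance rate itself is calibrated: on long white-noise
series (N ≫ max lag, where the 1/N variance approximation is accurate)
the measured rate matches α within Monte-Carlo error; at N = 192 with
lags up to k = 64 the true per-lag sd is √(N−k)/N < 1/√N and the rate
runs nearer 2.5–3%.

## The simulator

`synth.simulate_experiment` emulates one monitor:
`signal = baseline_level + drift + bout plateaus + noise`, rounded to
integer counts.

* **Bouts**: onsets from an inhomogeneous Poisson process, drawn by
  thinning against the profile's maximum rate (the draw order is
  documented, so an independent replay of the RNG stream reproduces the
  bout set — an oracle the tests use). Durations are 1 s + Exp(mean −
  1 s) (default mean 3 s; the 1 s floor reflects that a feeding bout
  spans multiple samples at 5 Hz). Overlapping candidates are dropped.
  Bout shape is a rectangular plateau of `bout_amplitude` (default 20
  a.u. against noise SD 2), the simplest shape consistent with the
  caller's threshold semantics.
* **Rate profiles**: `flat(r)`; `bimodal(r_base, peak_height,
  peak_width)` — circular Gaussians centered exactly at lights-on and
  lights-off, the crepuscular wild-type pattern, free-running unchanged
  in DD; `sinusoidal(mesor, amplitude, period, phase)` on absolute time
  so non-24 h periods free-run. Defaults for the two-genotype layout:
  wells 1–6 flat at 3/h (≈72 events/day, a realistic daily count),
  wells 7–12 bimodal (base 1/h, peak 6/h, width 1 h, ≈54/day). The
  rhythmic wells used in periodogram validation are sinusoidal with
  mesor 3/h and amplitude 2.5/h.
* **Drift**: a Gaussian random walk drawn on a 1-min grid, smoothed to
  a 1 h timescale, interpolated to sample resolution and scaled to an
  envelope of `drift_amplitude` (20 a.u.) per day — slow enough that
  both RM and ALS remove it.
* **Determinism**: one root generator per experiment (`seed`), spawned
  into independent per-well streams.

What the simulator does *not* model: capacitance physics, the
lick-level microstructure within a bout (tastings vs licks), negative
deflections, multi-fly interference, or electrode fouling that changes
noise over time. Passing tests therefore demonstrate the pipeline's
correctness on signals with the stated structure, not the adequacy of
any particular parameter set for a given rig — the event parameters
still "need to be determined empirically" per monitor.

## Problem sizes in the shipped tests

The validation suite runs scaled versions of the full assay chosen to
exercise every code path at sub-minute cost: unit fixtures use 1–3
simulated days at 0.5–1 s sampling; the event-recovery check uses the
native 200 ms sampling over one day (recall and precision ≥ 0.9 against
ground truth); periodogram statistics use 100 + 100 bout-level wells at
4 DD days; the end-to-end assay uses the full 12-well, 3 LD + 4 DD
layout at 500 ms sampling. `scripts/acceptance.py` re-runs all of these
from scratch in about half a minute.
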