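"""Event summaries: binned series, totals, group statistics, outlier
flags, day/night splits and average daily profiles.

Bin grids are anchored at the midnight preceding the first sample, so a
bin labelled 09:00 always means 09:00 wall clock regardless of when the
recording started. Per-well normalization (divide by the well's total,
or by its maximum bin) is applied here and inherited by everything
downstream that consumes the normalized series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import EventTable
from .flic_io import ConditionMap, LightSchedule

__all__ = [
    "BinSpec",
    "BinnedSeries",
    "bin_events",
    "normalize_wells",
    "rebin",
    "individual_totals",
    "group_stats",
    "events_per_day",
    "tukey_fences",
    "flag_outliers",
    "split_day_night",
    "daily_profile",
]

MS_PER_DAY = 86_400_000


@dataclass(frozen=True)
class BinSpec:
    """Binning choice: interval (must divide 24 h), function, error bar.

    1-min bins are intended for short (< 1 day) recordings; on longer
    spans they mostly add noise, which degrades the rhythmicity
    statistics, so a warning is emitted downstream in that case.
    """

    interval_minutes: int = 60  # 1, 30 or 60
    func: str = "sum"  # "sum" | "mean"
    error_bar: str = "SEM"  # "SEM" | "SD" | "None"

    def __post_init__(self):
        if self.interval_minutes <= 0 or (24 * 60) % self.interval_minutes:
            raise ValueError("bin interval must divide 24 h evenly")
        if self.func not in ("sum", "mean"):
            raise ValueError("func must be 'sum' or 'mean'")
        if self.error_bar not in ("SEM", "SD", "None"):
            raise ValueError("error_bar must be 'SEM', 'SD' or 'None'")

    @property
    def width_ms(self) -> int:
        return self.interval_minutes * 60_000


@dataclass
class BinnedSeries:
    """Per-well event counts (or per-sample rates) on a regular grid.

    ``values``: DataFrame indexed by bin start timestamp; one column per
    (monitor, well). ``coverage`` records the wall-clock span the
    recording actually observed — bins before the first sample exist on
    the midnight-anchored grid but were not recorded, which matters when
    deciding which calendar days are complete.
    """

    values: pd.DataFrame
    spec: BinSpec
    normalized: bool = False
    norm_mode: str | None = None
    coverage: tuple[pd.Timestamp, pd.Timestamp] | None = None

    @property
    def wells(self) -> list[tuple[int, int]]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.columns = [f"M{m}:W{w}" for m, w in out.columns]
        out.insert(0, "bin_start", self.values.index)
        return out.reset_index(drop=True)


def bin_events(events: EventTable, spec: BinSpec = BinSpec()) -> BinnedSeries:
    """Count event onsets into half-open bins [start, start + interval).

    ``func="sum"`` gives the count per bin; ``func="mean"`` divides by
    the nominal samples per bin, i.e. a per-sample rate.
    """
    width = spec.width_ms
    midnight = events.origin.normalize()
    offset = int((events.origin - midnight) / pd.Timedelta(milliseconds=1))
    span_lo, span_hi = events.span_ms
    r = events.records
    if len(r):
        if r["onset_ms"].min() < span_lo or r["onset_ms"].max() > span_hi:
            raise ValueError("event onsets fall outside the recording span")
    n_bins = max(int(np.ceil((span_hi + offset + 1) / width)), 1)
    index = midnight + pd.to_timedelta(np.arange(n_bins) * width, unit="ms")
    cols = {}
    for mon, well in events.wells:
        sub = r[(r["monitor"] == mon) & (r["well"] == well)]
        idx = ((sub["onset_ms"].to_numpy() + offset) // width).astype(np.int64)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        cols[(mon, well)] = counts
    values = pd.DataFrame(cols, index=index)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["monitor", "well"])
    values.index.name = "bin_start"
    if spec.func == "mean":
        values = values / (width / events.sample_interval_ms)
    # last sample covers [span_hi, span_hi + interval)
    coverage = (
        events.origin,
        events.origin
        + pd.Timedelta(milliseconds=int(span_hi) + events.sample_interval_ms),
    )
    span_days = (coverage[1] - coverage[0]) / pd.Timedelta(days=1)
    if spec.interval_minutes == 1 and span_days > 1:
        warnings.warn(
            "1-min bins on a multi-day recording: intended for short "
            "(< 1 day) data; expect noisy profiles",
            stacklevel=2,
        )
    return BinnedSeries(values=values, spec=spec, coverage=coverage)


def normalize_wells(binned: BinnedSeries, mode: str = "sum") -> BinnedSeries:
    """Scale each well by its total (``sum``) or its maximum bin (``max``).

    Wells with a zero total stay all-zero and are reported in a warning.
    Normalizing twice is an error. Downstream profiles and periodograms
    consume whichever series they are handed, so normalization is
    inherited by the rest of the analysis.
    """
    if binned.normalized:
        raise ValueError("series is already normalized")
    if mode not in ("sum", "max"):
        raise ValueError("mode must be 'sum' or 'max'")
    denom = binned.values.sum() if mode == "sum" else binned.values.max()
    dead = denom[denom == 0].index.tolist()
    if dead:
        warnings.warn(
            f"zero-total wells left as all zeros under normalization: {dead}",
            stacklevel=2,
        )
    denom = denom.replace(0, 1.0)
    return replace(
        binned, values=binned.values / denom, normalized=True, norm_mode=mode
    )


def rebin(binned: BinnedSeries, interval_minutes: int) -> BinnedSeries:
    """Aggregate a sum-binned series onto a coarser grid (sums of bins)."""
    if binned.spec.func != "sum":
        raise ValueError("rebinning is defined for sum-binned series")
    if interval_minutes % binned.spec.interval_minutes:
        raise ValueError("target interval must be a multiple of the current one")
    factor = interval_minutes // binned.spec.interval_minutes
    group = np.arange(len(binned.values)) // factor
    agg = binned.values.groupby(group).sum()
    agg.index = binned.values.index[::factor][: len(agg)]
    agg.index.name = "bin_start"
    return replace(
        binned, values=agg, spec=replace(binned.spec, interval_minutes=interval_minutes)
    )


def individual_totals(events: EventTable) -> pd.DataFrame:
    """Total events per analyzed well (zero-event wells keep their row)."""
    counts = events.records.groupby(["monitor", "well"]).size()
    rows = [
        (mon, well, int(counts.get((mon, well), 0))) for mon, well in events.wells
    ]
    return pd.DataFrame(rows, columns=["monitor", "well", "total"])


def group_stats(totals: pd.DataFrame, cmap: ConditionMap) -> pd.DataFrame:
    """Per-condition n, mean, sample SD and SEM of a per-well statistic.

    The statistic column is whichever column follows monitor/well
    (``total`` by default). SD uses the n-1 denominator; SD and SEM are
    reported as missing for single-well conditions. Conditions that end
    up with no wells are omitted with a warning.
    """
    value_col = [c for c in totals.columns if c not in ("monitor", "well")][0]
    labels = [
        cmap.label_of(int(m), int(w))
        for m, w in zip(totals["monitor"], totals["well"])
    ]
    df = totals.assign(condition=labels)
    rows = []
    for label in cmap.labels or sorted(set(labels)):
        vals = df.loc[df["condition"] == label, value_col].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            warnings.warn(f"condition {label!r} has no wells", stacklevel=2)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
        sem = sd / np.sqrt(n) if n >= 2 else np.nan
        rows.append((label, n, mean, sd, sem))
    return pd.DataFrame(rows, columns=["condition", "n", "mean", "sd", "sem"])


def events_per_day(events: EventTable) -> pd.DataFrame:
    """Events per calendar day (midnight-to-midnight) for each well.

    The day columns cover the full recorded span, so a fly that died
    mid-experiment shows trailing zero days — the basis of the dead-fly
    screen.
    """
    midnight = events.origin.normalize()
    offset = int((events.origin - midnight) / pd.Timedelta(milliseconds=1))
    n_days = max(int(np.ceil((events.span_ms[1] + offset + 1) / MS_PER_DAY)), 1)
    dates = [(midnight + pd.Timedelta(days=d)).date() for d in range(n_days)]
    r = events.records
    rows = []
    for mon, well in events.wells:
        sub = r[(r["monitor"] == mon) & (r["well"] == well)]
        idx = ((sub["onset_ms"].to_numpy() + offset) // MS_PER_DAY).astype(int)
        counts = np.bincount(idx, minlength=n_days)
        rows.append([mon, well, *counts.tolist()])
    return pd.DataFrame(rows, columns=["monitor", "well", *[str(d) for d in dates]])


def tukey_fences(values) -> tuple[float, float]:
    """Tukey boxplot fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles are Tukey hinges (medians of the lower/upper half, the
    halves sharing the middle value when n is odd), matching boxplot
    whisker convention.
    """
    a = np.sort(np.asarray(values, dtype=float))
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 values for fences")
    half = (n + 1) // 2
    q1 = float(np.median(a[:half]))
    q3 = float(np.median(a[n - half:]))
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def flag_outliers(totals: pd.DataFrame, cmap: ConditionMap) -> set[tuple[int, int]]:
    """Wells whose statistic falls outside the Tukey fences of their
    condition. Conditions with fewer than 4 wells yield no flags."""
    value_col = [c for c in totals.columns if c not in ("monitor", "well")][0]
    flags: set[tuple[int, int]] = set()
    labels = [
        cmap.label_of(int(m), int(w))
        for m, w in zip(totals["monitor"], totals["well"])
    ]
    df = totals.assign(condition=labels)
    for label, sub in df.groupby("condition"):
        if len(sub) < 4:
            continue
        lo, hi = tukey_fences(sub[value_col])
        bad = sub[(sub[value_col] < lo) | (sub[value_col] > hi)]
        flags.update((int(m), int(w)) for m, w in zip(bad["monitor"], bad["well"]))
    return flags


def split_day_night(events: EventTable, schedule: LightSchedule) -> pd.DataFrame:
    """Day/night event counts per well over the complete loaded span.

    An event belongs to the day iff its onset's time-of-day lies in
    [lights_on, lights_off). The split ignores whether the lights were
    actually on (LD vs DD is not distinguished); trim to the relevant
    dates first when that distinction matters.
    """
    onsets = events.onsets()
    is_day = np.array([schedule.is_day(ts.time()) for ts in onsets], dtype=bool)
    r = events.records
    rows = []
    for mon, well in events.wells:
        m = (r["monitor"] == mon) & (r["well"] == well)
        day = int(np.count_nonzero(is_day & m.to_numpy())) if len(r) else 0
        night = int(m.sum()) - day
        rows.append((mon, well, day, night))
    return pd.DataFrame(rows, columns=["monitor", "well", "day", "night"])


def daily_profile(
    binned: BinnedSeries, cmap: ConditionMap, error_bar: str | None = None
) -> pd.DataFrame:
    """Average daily profile per condition.

    Only complete calendar days (fully inside the recorded coverage) are
    used; partial leading/trailing days are dropped. For each
    time-of-day bin the per-day, per-well values of a condition are
    pooled; the profile is their mean, the error bar their SEM or SD
    (missing when only one day x well sample exists).

    Returns a tidy frame: condition, time_of_day (hours), mean, err.
    """
    error_bar = error_bar or binned.spec.error_bar
    if error_bar not in ("SEM", "SD", "None"):
        raise ValueError("error_bar must be 'SEM', 'SD' or 'None'")
    if binned.coverage is None:
        raise ValueError("binned series lacks coverage information")
    start, end = binned.coverage
    first_day = start.normalize()
    if first_day < start:
        first_day += pd.Timedelta(days=1)
    n_days = int((end - first_day) / pd.Timedelta(days=1))
    if n_days < 1:
        raise ValueError(
            "need at least one complete day for a daily profile; "
            "use the plain binned view for shorter recordings"
        )
    bins_per_day = MS_PER_DAY // binned.spec.width_ms
    start_bin = int(
        (first_day - binned.values.index[0]) / pd.Timedelta(milliseconds=1)
    ) // binned.spec.width_ms
    tod = (np.arange(bins_per_day) * binned.spec.width_ms) / 3_600_000.0
    rows = []
    for label in cmap.labels or ["Condition"]:
        wells = [w for w in binned.wells if cmap.label_of(*w) == label]
        if not wells:
            continue
        # (n_days * n_wells, bins_per_day) pooled samples
        stacks = []
        for w in wells:
            col = binned.values[w].to_numpy()
            seg = col[start_bin : start_bin + n_days * bins_per_day]
            stacks.append(seg.reshape(n_days, bins_per_day))
        pooled = np.vstack(stacks)
        mean = pooled.mean(axis=0)
        n = pooled.shape[0]
        if error_bar == "None" or n < 2:
            err = np.full(bins_per_day, np.nan)
        else:
            sd = pooled.std(axis=0, ddof=1)
            err = sd / np.sqrt(n) if error_bar == "SEM" else sd
        for t, m_, e_ in zip(tod, mean, err):
            rows.append((label, float(t), float(m_), float(e_)))
    return pd.DataFrame(rows, columns=["condition", "time_of_day", "mean", "err"])
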