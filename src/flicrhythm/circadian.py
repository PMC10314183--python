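"""Autocorrelation periodogram for feeding-rhythm estimation.

Rhythmicity is assessed on binned event series from the constant-
darkness (DD) window. For a candidate period tau = k * bin width, the
"power" is the lag-k sample autocorrelation

    r_k = sum_{t<=N-k} (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2

The free-running period estimate is the lag of maximum power inside the
searched band (default 16-32 h, covering the circadian range; ties break
toward the smaller period). Significance uses the large-lag white-noise
normal approximation: under the null each r_k is approximately
N(0, 1/N), so the one-sided per-lag line at level alpha is

    signif_threshold = z_{1-alpha} / sqrt(N)

and the peak's p-value is 1 - Phi(r_peak * sqrt(N)), floored at machine
epsilon. This is a per-lag criterion, not corrected for the number of
lags searched, matching the convention of R's ``stats::acf`` confidence
line; with many lags in the band, white-noise wells exceed it at one or
another lag more often than alpha (see the methods notes). Estimates on
fewer than 5 DD days are flagged with a warning — short windows give
fragile rhythm statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.tsa.stattools import acf as _acf

from .flic_io import ConditionMap
from .summary import BinnedSeries, tukey_fences

__all__ = [
    "PeriodogramParams",
    "PeriodogramResult",
    "ac_periodogram",
    "periodogram_table",
    "periodogram_summary",
    "select_dd_window",
]


@dataclass(frozen=True)
class PeriodogramParams:
    """DD window, period band (hours) and significance level."""

    dd_start: date | None = None
    dd_end: date | None = None
    period_min_h: float = 16.0
    period_max_h: float = 32.0
    alpha: float = 0.05

    def __post_init__(self):
        if not self.period_min_h < self.period_max_h:
            raise ValueError("period_min_h must be < period_max_h")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if (
            self.dd_start is not None
            and self.dd_end is not None
            and self.dd_start > self.dd_end
        ):
            raise ValueError("dd_start must not be after dd_end")


@dataclass
class PeriodogramResult:
    """One well's periodogram: power (= autocorrelation) per candidate
    period, the peak, and its white-noise significance quantities."""

    periods_h: np.ndarray
    power: np.ndarray
    peak_period_h: float
    peak_power: float
    p_value: float
    signif_threshold: float
    n: int


def select_dd_window(binned: BinnedSeries, params: PeriodogramParams) -> BinnedSeries:
    """Restrict a binned series to the DD dates (whole-day inclusive)."""
    if params.dd_start is None or params.dd_end is None:
        return binned
    idx = binned.values.index
    mask = (idx.normalize() >= pd.Timestamp(params.dd_start)) & (
        idx.normalize() <= pd.Timestamp(params.dd_end)
    )
    if not mask.any():
        raise ValueError("DD window contains no bins of the loaded span")
    n_days = (params.dd_end - params.dd_start).days + 1
    if n_days < 5:
        warnings.warn(
            f"DD window of {n_days} days: rhythm statistics are fragile on "
            "< 5 days of constant darkness",
            stacklevel=2,
        )
    from dataclasses import replace

    return replace(binned, values=binned.values.loc[mask])


def ac_periodogram(
    series,
    bin_interval_h: float,
    params: PeriodogramParams = PeriodogramParams(),
) -> PeriodogramResult:
    """Autocorrelation periodogram of one well's binned series.

    Raises on constant series (no rhythm estimate exists) and on series
    shorter than twice the maximum searched period.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    k_min = int(np.ceil(params.period_min_h / bin_interval_h))
    k_max = int(np.floor(params.period_max_h / bin_interval_h))
    required = int(np.ceil(2 * params.period_max_h / bin_interval_h))
    if n < required:
        raise ValueError(
            f"series too short for the period range: {n} bins < required {required}"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant series has no rhythm estimate")
    r = _acf(x, nlags=k_max, adjusted=False, fft=True)
    assert abs(r[0] - 1.0) < 1e-9
    lags = np.arange(k_min, k_max + 1)
    power = r[k_min : k_max + 1]
    peak_idx = int(np.argmax(power))  # argmax takes the first max: smaller period
    peak_power = float(power[peak_idx])
    threshold = float(norm.ppf(1 - params.alpha) / np.sqrt(n))
    p_value = float(max(1 - norm.cdf(peak_power * np.sqrt(n)), np.finfo(float).eps))
    return PeriodogramResult(
        periods_h=lags * bin_interval_h,
        power=power.copy(),
        peak_period_h=float(lags[peak_idx] * bin_interval_h),
        peak_power=peak_power,
        p_value=p_value,
        signif_threshold=threshold,
        n=n,
    )


def periodogram_table(
    binned: BinnedSeries, params: PeriodogramParams = PeriodogramParams()
) -> dict[tuple[int, int], PeriodogramResult]:
    """Run the periodogram on every well of a (DD-trimmed) binned series."""
    dd = select_dd_window(binned, params)
    interval_h = dd.spec.interval_minutes / 60.0
    out: dict[tuple[int, int], PeriodogramResult] = {}
    for well in dd.wells:
        try:
            out[well] = ac_periodogram(dd.values[well].to_numpy(), interval_h, params)
        except ValueError as exc:
            raise ValueError(f"well {well}: {exc}") from exc
    return out


def periodogram_summary(
    results: dict[tuple[int, int], PeriodogramResult],
    cmap: ConditionMap,
):
    """Condense per-well periodograms into the reporting tables.

    Returns ``(table, curves, outliers)``:

    * table — one row per well: monitor, well, condition, peak period,
      peak power, p-value, signif_threshold, and an outlier flag.
    * curves — per-condition mean power vs period with SEM across wells.
    * outliers — wells whose peak power falls outside the Tukey fences
      of their condition (>= 4 wells needed).
    """
    if not results:
        raise ValueError("no periodogram results")
    rows = []
    for (mon, well), res in results.items():
        rows.append(
            (
                mon,
                well,
                cmap.label_of(mon, well),
                res.peak_period_h,
                res.peak_power,
                res.p_value,
                res.signif_threshold,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "monitor",
            "well",
            "condition",
            "peak_period_h",
            "peak_power",
            "p_value",
            "signif_threshold",
        ],
    )
    outliers: set[tuple[int, int]] = set()
    for label, sub in table.groupby("condition"):
        if len(sub) < 4:
            continue
        lo, hi = tukey_fences(sub["peak_power"])
        bad = sub[(sub["peak_power"] < lo) | (sub["peak_power"] > hi)]
        outliers.update((int(m), int(w)) for m, w in zip(bad["monitor"], bad["well"]))
    table["outlier"] = [
        (int(m), int(w)) in outliers for m, w in zip(table["monitor"], table["well"])
    ]

    curve_rows = []
    for label in table["condition"].unique():
        wells = [
            (int(m), int(w))
            for m, w, c in zip(table["monitor"], table["well"], table["condition"])
            if c == label
        ]
        mat = np.vstack([results[w].power for w in wells])
        periods = results[wells[0]].periods_h
        mean = mat.mean(axis=0)
        sem = (
            mat.std(axis=0, ddof=1) / np.sqrt(len(wells))
            if len(wells) >= 2
            else np.full(mat.shape[1], np.nan)
        )
        for p_, m_, s_ in zip(periods, mean, sem):
            curve_rows.append((label, float(p_), float(m_), float(s_)))
    curves = pd.DataFrame(
        curve_rows, columns=["condition", "period_h", "mean_power", "sem"]
    )
    return table, curves, outliers
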