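"""Baseline removal for capacitance signals.

Feeding deflections ride on a high, slowly drifting sensor baseline
(electrode wetting, liquid-food level). Two estimators are provided:

* running median (RM) — the classic monitor-code approach; subtracts the
  median over a centered time window (default 5 min), which ignores the
  short positive bouts.
* asymmetric least squares (ALS) — a Whittaker smoother with asymmetric
  residual weights: the baseline z minimizes
  ``sum_i w_i (y_i - z_i)^2 + lambda * sum_i (d2 z_i)^2`` with
  ``w_i = p`` where ``y_i > z_i`` and ``1 - p`` otherwise, iterated to a
  fixed point. Small p keeps the baseline pinned under the feeding
  peaks, so subtracting it preserves the deflections. ALS needs no
  per-experiment window choice.

Long recordings are processed in chunks (default 24 h) with overlapping,
cross-faded joins so chunking introduces no seam artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .flic_io import RawSignalTable

__all__ = [
    "BaselineParams",
    "running_median_baseline",
    "als_smooth",
    "als_baseline",
    "baseline_table",
    "binned_preview",
]


@dataclass(frozen=True)
class BaselineParams:
    """Baselining configuration.

    ALS defaults (lambda=1e8 at 5 Hz sampling, p=0.01, 20 iterations,
    tol=0 i.e. iterate until the weight vector is unchanged) put the
    smoother's timescale far above bout duration while the asymmetry
    keeps the fit under the peaks; they are fixed so ALS runs without
    user input.
    """

    method: str = "rm"  # "rm" | "als"
    rm_window_minutes: float = 5.0
    als_lambda: float = 1e8
    als_p: float = 0.01
    als_max_iter: int = 20
    als_tol: float = 0.0
    chunk_hours: float = 24.0

    def __post_init__(self):
        if self.method not in ("rm", "als"):
            raise ValueError("method must be 'rm' or 'als'")
        if self.rm_window_minutes <= 0:
            raise ValueError("rm_window_minutes must be positive")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be positive")
        if not 0 < self.als_p < 1:
            raise ValueError("als_p must lie strictly between 0 and 1")
        if self.chunk_hours <= 0:
            raise ValueError("chunk_hours must be positive")


def window_samples(window_minutes: float, sample_interval_ms: int) -> int:
    """Convert a window in minutes to an odd sample count (round half up)."""
    n = int(np.floor(window_minutes * 60_000 / sample_interval_ms + 0.5))
    if n % 2 == 0:
        n += 1
    return max(n, 1)


def running_median_baseline(
    signal, times=None, window_minutes: float = 5.0, sample_interval_ms: int = 200
) -> np.ndarray:
    """Subtract the centered running median from one well's series.

    The window is ``window_minutes`` converted to an odd sample count;
    at the edges the window shrinks (truncated centered window), which
    avoids phantom deflections at recording boundaries. Exactly
    invariant to adding a constant to the input.
    """
    y = np.asarray(signal, dtype=float)
    if y.size == 0:
        return y.copy()
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    w = window_samples(window_minutes, sample_interval_ms)
    med = (
        pd.Series(y)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return y - med


def _banded_penalty(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3, n) of lam * D2' D2 for solveh_banded."""
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    ab = np.zeros((3, n))
    ab[0, 2:] = lam  # second superdiagonal
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0
    return ab


def _als_fit(
    signal,
    als_lambda: float,
    als_p: float,
    als_max_iter: int,
    als_tol: float,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Median-centered ALS iteration; returns (z_centered, center)."""
    y_in = np.asarray(signal, dtype=float)
    n = y_in.size
    if n < 3:
        raise ValueError("ALS needs at least 3 samples")
    if not np.all(np.isfinite(y_in)):
        raise ValueError("signal contains non-finite values")
    # center on the median: the fit is translation-equivariant, and
    # removing the large offset keeps the ill-conditioned solve accurate
    # (and makes adding a constant to the input shift z exactly)
    center = float(np.median(y_in))
    y = y_in - center
    ab = _banded_penalty(n, als_lambda)
    w = np.ones(n) if w0 is None else np.asarray(w0, dtype=float).copy()
    z = y
    for _ in range(als_max_iter):
        ab_iter = ab.copy()
        ab_iter[2, :] += w
        z = solveh_banded(ab_iter, w * y, lower=False)
        w_new = np.where(y > z, als_p, 1.0 - als_p)
        changed = np.mean(w_new != w)
        w = w_new
        if changed <= als_tol:
            break
    else:
        warnings.warn(
            f"ALS weights still changing after {als_max_iter} iterations; "
            "returning last iterate",
            stacklevel=2,
        )
    return z, center


def als_smooth(
    signal,
    als_lambda: float = 1e8,
    als_p: float = 0.01,
    als_max_iter: int = 20,
    als_tol: float = 0.0,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Asymmetric least squares baseline estimate (the smooth curve z).

    Solves the penalized weighted least-squares system with a banded
    Cholesky factorization each iteration; weights are re-set to p above
    the current fit and 1-p below it until the changed fraction is
    <= als_tol (default: until unchanged). Emits a warning when the
    weight iteration has not settled after ``als_max_iter`` rounds and
    returns the last iterate.
    """
    z, center = _als_fit(signal, als_lambda, als_p, als_max_iter, als_tol, w0)
    return z + center


def als_baseline(
    signal,
    als_lambda: float = 1e8,
    als_p: float = 0.01,
    als_max_iter: int = 20,
    als_tol: float = 0.0,
) -> np.ndarray:
    """Signal minus its asymmetric-least-squares baseline.

    Computed on the median-centered signal, so adding a constant to the
    input leaves the output bit-identical whenever the median shifts
    exactly (always true for integer raw counts).
    """
    y = np.asarray(signal, dtype=float)
    z, center = _als_fit(y, als_lambda, als_p, als_max_iter, als_tol)
    return (y - center) - z


def _chunk_layout(n: int, chunk: int, ext: int, fade: int):
    """Chunk cores plus extensions and linear cross-fade weights.

    Pieces are fitted on [core_start - ext, core_end + ext); adjacent
    pieces are blended with complementary linear ramps over a zone of
    ``fade`` samples centered on each core boundary. With ext >= fade,
    every blended sample sits well inside both pieces, so local
    estimators (RM) are bit-identical to the unchunked result and the
    global smoother's (ALS) pieces agree to within its own smoothness.
    """
    starts = list(range(0, n, chunk))
    for s in starts:
        core_end = min(s + chunk, n)
        lo = max(0, s - ext)
        hi = min(n, core_end + ext)
        yield s, core_end, lo, hi


def _baseline_one_well(y: np.ndarray, params: BaselineParams, interval_ms: int):
    n = y.size
    if params.method == "rm":
        win = window_samples(params.rm_window_minutes, interval_ms)
        fit = lambda seg: running_median_baseline(  # noqa: E731
            seg, window_minutes=params.rm_window_minutes, sample_interval_ms=interval_ms
        )
        fade = win
    else:
        fit = lambda seg: als_baseline(  # noqa: E731
            seg, params.als_lambda, params.als_p, params.als_max_iter, params.als_tol
        )
        fade = max(int(round(10 * 60_000 / interval_ms)), 3)  # 10 min
    chunk = max(int(round(params.chunk_hours * 3_600_000 / interval_ms)), 1)
    if n <= chunk:
        return fit(y)
    ext = 2 * fade
    out = np.zeros(n)
    wsum = np.zeros(n)
    for s, core_end, lo, hi in _chunk_layout(n, chunk, ext, fade):
        piece = fit(y[lo:hi])
        weight = np.ones(hi - lo)
        half = fade // 2
        if s > 0:  # ramp up across the left core boundary
            ramp_lo = max(lo, s - half)
            ramp_hi = min(hi, ramp_lo + fade)
            weight[: ramp_lo - lo] = 0.0
            k = ramp_hi - ramp_lo
            weight[ramp_lo - lo : ramp_hi - lo] = np.linspace(0, 1, k + 2)[1:-1]
        if core_end < n:  # ramp down across the right core boundary
            ramp_lo = max(lo, core_end - half)
            ramp_hi = min(hi, ramp_lo + fade)
            k = ramp_hi - ramp_lo
            weight[ramp_lo - lo : ramp_hi - lo] = np.linspace(1, 0, k + 2)[1:-1]
            weight[ramp_hi - lo :] = 0.0
        out[lo:hi] += weight * piece
        wsum[lo:hi] += weight
    return out / wsum


def baseline_table(raw: RawSignalTable, params: BaselineParams) -> RawSignalTable:
    """Apply the selected baseline method to every well of a table.

    Returns a table of the same shape whose values are raw minus the
    estimated baseline (float, may be negative — event thresholds handle
    sign downstream). Per-well failures are re-raised with the well name
    attached.
    """
    cols = {}
    for well in raw.signals.columns:
        try:
            cols[well] = _baseline_one_well(
                raw.signals[well].to_numpy(dtype=float),
                params,
                raw.sample_interval_ms,
            )
        except Exception as exc:
            raise type(exc)(f"well {well}: {exc}") from exc
    return RawSignalTable(
        monitor_id=raw.monitor_id,
        times=raw.times.copy(),
        signals=pd.DataFrame(cols),
        wall_clock_origin=raw.wall_clock_origin,
        sample_interval_ms=raw.sample_interval_ms,
    )


def binned_preview(
    baselined: RawSignalTable, interval_minutes: float = 60.0, func: str = "sum"
) -> pd.DataFrame:
    """Aggregate baselined samples into consecutive bins for QC plots.

    Bins are anchored at the first sample. This view exists purely for
    visual inspection of drift removal; event calling always runs on the
    full-resolution data. A recording shorter than one interval yields a
    single bin.
    """
    if interval_minutes <= 0:
        raise ValueError("interval must be positive")
    if func not in ("sum", "mean"):
        raise ValueError("func must be 'sum' or 'mean'")
    width_ms = int(round(interval_minutes * 60_000))
    bin_idx = baselined.times // width_ms
    grouped = baselined.signals.groupby(bin_idx)
    agg = grouped.sum() if func == "sum" else grouped.mean()
    agg.index = baselined.wall_clock_origin + pd.to_timedelta(
        agg.index * width_ms, unit="ms"
    )
    agg.index.name = "bin_start"
    return agg
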