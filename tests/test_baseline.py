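"""Running-median and asymmetric-least-squares baselining."""

import inspect

import numpy as np
import pandas as pd
import pytest

from flicrhythm import flic_io as fio
from flicrhythm.baseline import (
    BaselineParams,
    als_baseline,
    als_smooth,
    baseline_table,
    binned_preview,
    running_median_baseline,
    window_samples,
)


def dense_als(y, lam, p, max_iter=20, w0=None):
    """Independent dense-matrix ALS oracle (direct solve, same weights rule)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    D = np.diff(np.eye(n), n=2, axis=0)
    P = lam * D.T @ D
    w = np.ones(n) if w0 is None else np.asarray(w0, float).copy()
    for _ in range(max_iter):
        z = np.linalg.solve(np.diag(w) + P, w * y)
        w_new = np.where(y > z, p, 1 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


# ---------------------------------------------------------------- running median


def test_rm_constant_is_zero():
    out = running_median_baseline(np.full(500, 137.0), window_minutes=5,
                                  sample_interval_ms=200)
    np.testing.assert_array_equal(out, np.zeros(500))


def test_rm_hand_trace_spike():
    """[0,0,10,0,0] with a 3-sample window: every truncated/centered
    window's median is 0, so the spike survives untouched."""
    sig = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
    out = running_median_baseline(sig, window_minutes=0.01, sample_interval_ms=200)
    assert window_samples(0.01, 200) == 3
    np.testing.assert_array_equal(out, sig)


def test_rm_default_window_is_five_minutes():
    sig = inspect.signature(running_median_baseline)
    assert sig.parameters["window_minutes"].default == 5.0
    assert BaselineParams().rm_window_minutes == 5.0


def test_rm_constant_shift_invariance(rng):
    # raw capacitance readings are integer counts; medians of shifted
    # integers shift exactly, so the baselined output is bit-identical
    y = rng.integers(80, 130, 2000).astype(float)
    a = running_median_baseline(y, window_minutes=1, sample_interval_ms=200)
    b = running_median_baseline(y + 1000, window_minutes=1, sample_interval_ms=200)
    np.testing.assert_array_equal(a, b)


def test_rm_rejects_nonfinite():
    with pytest.raises(ValueError, match="non-finite"):
        running_median_baseline(np.array([1.0, np.nan, 2.0]))


def test_window_samples_odd():
    assert window_samples(5, 200) == 1501
    assert window_samples(1, 1000) == 61
    assert window_samples(0.005, 1000) == 1  # sub-sample window -> 1
    for minutes in (0.5, 1, 2, 5):
        assert window_samples(minutes, 200) % 2 == 1


# -------------------------------------------------------------------------- ALS


def test_als_constant_residual_zero():
    out = als_baseline(np.full(300, 55.0))
    assert np.max(np.abs(out)) < 1e-6


def test_als_linear_ramp():
    """A line is in the penalty's null space: residual ~ 0."""
    y = np.linspace(0, 100, 200)
    out = als_baseline(y)
    assert np.max(np.abs(out)) <= 1e-6 * np.ptp(y)


def test_als_ramp_plus_spike_preserved():
    """A rectangular deflection of height H on a ramp survives within 5%."""
    H = 200.0
    y = np.linspace(0, 50, 200)
    y[90:110] += H
    out = als_baseline(y)
    assert np.abs(out[95:105] - H).max() < 0.05 * H
    z_oracle = dense_als(y, 1e8, 0.01)
    scale = np.max(np.abs(z_oracle))
    assert np.max(np.abs(als_smooth(y) - z_oracle)) <= 1e-8 * scale


def test_als_matches_dense_oracle_random(rng):
    """Banded iterative solve == dense direct solve on random instances."""
    for n in (50, 200, 500):
        y = rng.normal(0, 1, n).cumsum() + 10 * (rng.uniform(size=n) > 0.95)
        lam, p = 1e6, 0.05
        z = als_smooth(y, lam, p)
        z_dense = dense_als(y, lam, p)
        scale = max(np.max(np.abs(z_dense)), 1.0)
        assert np.max(np.abs(z - z_dense)) <= 1e-8 * scale


def test_als_initial_weight_independence(rng):
    """The weight iteration lands on the same fixed point regardless of w0."""
    y = rng.normal(100, 3, 400)
    y[100:120] += 50
    z_ones = als_smooth(y, 1e6, 0.01, als_max_iter=50)
    w0 = rng.uniform(0.01, 0.99, size=400)
    z_rand = als_smooth(y, 1e6, 0.01, als_max_iter=50, w0=w0)
    np.testing.assert_allclose(z_ones, z_rand, atol=1e-6)


def test_als_shift_invariance(rng):
    # integer raw counts: the median (hence the centered problem) shifts
    # exactly, so the baselined output is unchanged to well below 1e-6
    y = rng.integers(95, 110, 300).astype(float)
    y[100:110] += 60
    a = als_baseline(y)
    b = als_baseline(y + 1000)
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_als_too_short():
    with pytest.raises(ValueError):
        als_smooth(np.array([1.0, 2.0]))


def test_als_nonconvergence_warns(rng):
    y = rng.normal(0, 1, 200)
    with pytest.warns(UserWarning, match="iterations"):
        als_smooth(y, 1e4, 0.3, als_max_iter=1)


# ----------------------------------------------------------------- table level


def _make_table(values, interval_ms=1000):
    n = len(values)
    return fio.RawSignalTable(
        monitor_id=1,
        times=np.arange(n, dtype=np.int64) * interval_ms,
        signals=pd.DataFrame({f"W{i}": values for i in range(1, 13)}),
        wall_clock_origin=pd.Timestamp("2021-07-01"),
        sample_interval_ms=interval_ms,
    )


def test_baseline_table_constant_all_zero():
    t = _make_table(np.full(1000, 42.0))
    for method in ("rm", "als"):
        out = baseline_table(t, BaselineParams(method=method))
        assert np.max(np.abs(out.signals.to_numpy())) < 1e-6
        np.testing.assert_array_equal(out.times, t.times)


def test_rm_chunking_is_seamless(rng):
    """Chunked RM with cross-faded overlaps is bit-identical to one-shot."""
    y = rng.normal(100, 5, 3 * 3600) + np.linspace(0, 40, 3 * 3600)
    t = _make_table(y)  # 3 h at 1 s
    whole = baseline_table(t, BaselineParams(method="rm", chunk_hours=100))
    chunked = baseline_table(t, BaselineParams(method="rm", chunk_hours=1))
    np.testing.assert_allclose(
        whole.signals.to_numpy(), chunked.signals.to_numpy(), rtol=0, atol=1e-9
    )


def test_als_chunking_seam_artifacts_tiny(rng):
    """Cross-faded ALS chunks agree with the one-shot fit to ~1e-6 of range."""
    n = 3 * 3600
    y = 100 + np.linspace(0, 30, n) + rng.normal(0, 2, n)
    y[5000:5020] += 80
    t = _make_table(y)
    whole = baseline_table(t, BaselineParams(method="als", chunk_hours=100))
    chunked = baseline_table(t, BaselineParams(method="als", chunk_hours=1))
    # chunked and one-shot global fits may differ slightly in the
    # interior; the seam contract is about discontinuities the joins
    # would add, i.e. the sample-to-sample increments must match
    d = whole.signals["W1"].to_numpy() - chunked.signals["W1"].to_numpy()
    assert np.abs(np.diff(d)).max() <= 1e-6 * np.ptp(y)


def test_baseline_error_names_well():
    t = _make_table(np.full(10, 1.0))
    t.signals.loc[5, "W3"] = np.nan
    with pytest.raises(ValueError, match="W3"):
        baseline_table(t, BaselineParams(method="rm"))


# ------------------------------------------------------------------- preview


def test_binned_preview_sum_exact(rng):
    y = rng.normal(0, 1, 7200)  # 2 h at 1 s
    t = _make_table(y)
    out = binned_preview(t, interval_minutes=60, func="sum")
    assert len(out) == 2
    np.testing.assert_allclose(out["W1"].to_numpy(),
                               [y[:3600].sum(), y[3600:].sum()])


def test_binned_preview_mean_constant():
    t = _make_table(np.full(7200, 3.5))
    out = binned_preview(t, interval_minutes=60, func="mean")
    np.testing.assert_allclose(out["W5"].to_numpy(), [3.5, 3.5])


def test_binned_preview_short_recording_single_bin():
    t = _make_table(np.ones(1800))  # 30 min at 1 s
    out = binned_preview(t, interval_minutes=60, func="sum")
    assert len(out) == 1
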