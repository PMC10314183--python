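"""Binning, normalization, group statistics, outliers, day/night, profiles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flicrhythm.events import EventTable
from flicrhythm.flic_io import ConditionMap, LightSchedule, assign_conditions
from flicrhythm.summary import (
    BinSpec,
    bin_events,
    daily_profile,
    events_per_day,
    flag_outliers,
    group_stats,
    individual_totals,
    normalize_wells,
    rebin,
    split_day_night,
    tukey_fences,
)

ORIGIN = pd.Timestamp("2021-07-01 00:00:00")
HOUR = 3_600_000


def make_events(onsets_by_well, span_hours=24, origin=ORIGIN, n_wells=None):
    """EventTable from {well: [onset_ms, ...]} on monitor 1."""
    rows = [
        (1, w, int(o), int(o) + 1000)
        for w, onsets in onsets_by_well.items()
        for o in onsets
    ]
    wells = sorted(onsets_by_well)
    if n_wells:
        wells = list(range(1, n_wells + 1))
    recs = pd.DataFrame(rows, columns=["monitor", "well", "onset_ms", "end_ms"])
    recs = recs.sort_values(["monitor", "well", "onset_ms"], ignore_index=True)
    return EventTable(
        records=recs,
        wells=[(1, w) for w in wells],
        origin=origin,
        span_ms=(0, int(span_hours * HOUR) - 1000),
        sample_interval_ms=1000,
    )


def test_bin_counts_hand_example():
    """Events at 00:10, 00:40, 01:10 with 1 h sum bins -> [2, 1]."""
    ev = make_events({1: [10 * 60_000, 40 * 60_000, 70 * 60_000]}, span_hours=2)
    b = bin_events(ev, BinSpec(interval_minutes=60, func="sum"))
    np.testing.assert_array_equal(b.values[(1, 1)].to_numpy(), [2, 1])


def test_bin_no_events_all_zero():
    ev = make_events({1: []}, span_hours=3)
    b = bin_events(ev)
    assert (b.values.to_numpy() == 0).all()
    assert len(b.values) == 3


def test_default_binspec_is_hour_sum():
    spec = BinSpec()
    assert spec.interval_minutes == 60 and spec.func == "sum"


def test_bin_mean_is_per_sample_rate():
    ev = make_events({1: [0, 1000, 2000, 3000]}, span_hours=1)
    b = bin_events(ev, BinSpec(interval_minutes=60, func="mean"))
    # 4 events over 3600 one-second samples
    assert b.values[(1, 1)].iloc[0] == pytest.approx(4 / 3600)


def test_bin_grid_anchored_at_midnight():
    late = ORIGIN + pd.Timedelta(hours=13, minutes=30)
    ev = make_events({1: [0]}, span_hours=2, origin=late)
    b = bin_events(ev, BinSpec(interval_minutes=60))
    assert b.values.index[0] == ORIGIN
    # the event at wall clock 13:30 lands in the 13:00 bin
    assert b.values[(1, 1)].iloc[13] == 1


def test_event_outside_span_is_error():
    ev = make_events({1: [10 * HOUR]}, span_hours=2)
    with pytest.raises(ValueError, match="outside"):
        bin_events(ev)


def test_normalize_modes():
    ev = make_events({1: [0, 1000, HOUR + 1, HOUR + 2000, 2 * HOUR + 1,
                          2 * HOUR + 2, 2 * HOUR + 3, 2 * HOUR + 4]},
                     span_hours=3)
    b = bin_events(ev)  # [2, 2, 4]
    np.testing.assert_array_equal(b.values[(1, 1)].to_numpy(), [2, 2, 4])
    ns = normalize_wells(b, "sum")
    np.testing.assert_allclose(ns.values[(1, 1)].to_numpy(), [0.25, 0.25, 0.5])
    nm = normalize_wells(b, "max")
    np.testing.assert_allclose(nm.values[(1, 1)].to_numpy(), [0.5, 0.5, 1.0])
    with pytest.raises(ValueError, match="already normalized"):
        normalize_wells(ns, "sum")


def test_normalize_single_bin_events():
    ev = make_events({1: [HOUR + 1, HOUR + 2, HOUR + 3]}, span_hours=3)
    ns = normalize_wells(bin_events(ev), "sum")
    np.testing.assert_allclose(ns.values[(1, 1)].to_numpy(), [0, 1, 0])


def test_normalize_zero_total_well_flagged():
    ev = make_events({1: [0], 2: []}, span_hours=2)
    b = bin_events(ev)
    with pytest.warns(UserWarning, match="zero-total"):
        ns = normalize_wells(b, "sum")
    np.testing.assert_array_equal(ns.values[(1, 2)].to_numpy(), [0, 0])


def test_normalization_commutes_with_binning():
    """Normalize-then-aggregate equals aggregate-then-normalize (sum mode)."""
    rng = np.random.default_rng(3)
    onsets = np.sort(rng.integers(0, 24 * HOUR, 200))
    ev = make_events({1: onsets.tolist()}, span_hours=24)
    fine = bin_events(ev, BinSpec(interval_minutes=30))
    a = rebin(normalize_wells(fine, "sum"), 60)
    b = normalize_wells(rebin(fine, 60), "sum")
    np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)
    assert a.values[(1, 1)].sum() == pytest.approx(1.0, abs=1e-9)


def test_individual_totals_keep_empty_wells():
    ev = make_events({1: [0, 1000], 2: []}, span_hours=1, n_wells=12)
    totals = individual_totals(ev)
    assert len(totals) == 12
    assert totals.set_index("well").loc[1, "total"] == 2
    assert totals.set_index("well").loc[2, "total"] == 0


def test_group_stats_closed_form():
    totals = pd.DataFrame({"monitor": [1, 1, 1], "well": [1, 2, 3],
                           "total": [10, 20, 30]})
    cmap = ConditionMap({(1, 1): "g", (1, 2): "g", (1, 3): "g"})
    out = group_stats(totals, cmap)
    row = out.iloc[0]
    assert row["mean"] == pytest.approx(20)
    assert row["sd"] == pytest.approx(10)
    assert row["sem"] == pytest.approx(5.773503, abs=1e-6)


def test_group_stats_single_well_missing_sd():
    totals = pd.DataFrame({"monitor": [1], "well": [1], "total": [7]})
    out = group_stats(totals, ConditionMap({(1, 1): "solo"}))
    assert out.iloc[0]["mean"] == 7
    assert np.isnan(out.iloc[0]["sd"]) and np.isnan(out.iloc[0]["sem"])


def test_group_stats_equal_totals_zero_sd():
    totals = pd.DataFrame({"monitor": [1] * 3, "well": [1, 2, 3],
                           "total": [5, 5, 5]})
    cmap = ConditionMap({(1, w): "g" for w in (1, 2, 3)})
    out = group_stats(totals, cmap)
    assert out.iloc[0]["sd"] == 0 and out.iloc[0]["sem"] == 0


def test_events_per_day_and_conservation():
    onsets = {1: [0, 30 * HOUR, 31 * HOUR, 6 * 24 * HOUR + 1], 2: [2 * HOUR]}
    ev = make_events(onsets, span_hours=7 * 24)
    per_day = events_per_day(ev)
    day_cols = [c for c in per_day.columns if c not in ("monitor", "well")]
    assert len(day_cols) == 7
    totals = individual_totals(ev)
    sums = per_day[day_cols].sum(axis=1).to_numpy()
    np.testing.assert_array_equal(sums, totals["total"].to_numpy())
    # all of well 2's events on one day
    w2 = per_day[per_day["well"] == 2][day_cols].to_numpy()[0]
    assert w2.tolist() == [1, 0, 0, 0, 0, 0, 0]


def test_tukey_hand_example():
    """[10,11,12,12,13,40]: hinges 11/13, fences [8,16] -> 40 flagged."""
    lo, hi = tukey_fences([10, 11, 12, 12, 13, 40])
    assert (lo, hi) == (8.0, 16.0)
    totals = pd.DataFrame({"monitor": [1] * 6, "well": range(1, 7),
                           "total": [10, 11, 12, 12, 13, 40]})
    cmap = ConditionMap({(1, w): "g" for w in range(1, 7)})
    assert flag_outliers(totals, cmap) == {(1, 6)}


def test_tukey_identical_totals_no_flags():
    totals = pd.DataFrame({"monitor": [1] * 5, "well": range(1, 6),
                           "total": [4] * 5})
    cmap = ConditionMap({(1, w): "g" for w in range(1, 6)})
    assert flag_outliers(totals, cmap) == set()


def test_small_condition_never_flagged():
    totals = pd.DataFrame({"monitor": [1] * 3, "well": [1, 2, 3],
                           "total": [1, 2, 1000]})
    cmap = ConditionMap({(1, w): "g" for w in (1, 2, 3)})
    assert flag_outliers(totals, cmap) == set()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.integers(0, 1000), min_size=4, max_size=12))
def test_tukey_matches_bruteforce(values):
    """Flags equal an independent fence evaluation with hinge quartiles."""
    totals = pd.DataFrame({"monitor": [1] * len(values),
                           "well": range(1, len(values) + 1),
                           "total": values})
    cmap = ConditionMap({(1, w): "g" for w in range(1, len(values) + 1)})
    flags = flag_outliers(totals, cmap)
    a = sorted(values)
    n = len(a)
    half = a[: (n + 1) // 2], a[-((n + 1) // 2):]
    q1, q3 = float(np.median(half[0])), float(np.median(half[1]))
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    expected = {(1, i + 1) for i, v in enumerate(values) if v < lo or v > hi}
    assert flags == expected


SCHED = LightSchedule(dt.time(9, 0), dt.time(21, 0))


def test_day_night_boundaries():
    ev = make_events(
        {1: [10 * HOUR, 22 * HOUR, 21 * HOUR]}, span_hours=24
    )  # 10:00 day; 22:00 night; 21:00 exactly lights-off -> night
    out = split_day_night(ev, SCHED)
    assert out.iloc[0]["day"] == 1
    assert out.iloc[0]["night"] == 2


def test_day_night_empty():
    ev = make_events({1: []}, span_hours=24)
    out = split_day_night(ev, SCHED)
    assert out.iloc[0]["day"] == 0 and out.iloc[0]["night"] == 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.integers(0, 48 * 3600 - 1), max_size=60))
def test_day_night_matches_bruteforce(onsets_s):
    onsets = [s * 1000 for s in sorted(onsets_s)]
    ev = make_events({1: onsets}, span_hours=48)
    out = split_day_night(ev, SCHED)
    day = sum(1 for s in onsets_s if 9 * 3600 <= (s % 86400) < 21 * 3600)
    assert out.iloc[0]["day"] == day
    assert out.iloc[0]["day"] + out.iloc[0]["night"] == len(onsets)


def test_daily_profile_two_day_example():
    """Per-day bins [1,3] then [3,5] (12 h bins) -> profile [2,4], SEM [1,1]."""
    onsets = (
        [1 * HOUR]  # day 1, first half: 1
        + [13 * HOUR, 14 * HOUR, 15 * HOUR]  # day 1, second half: 3
        + [25 * HOUR, 26 * HOUR, 27 * HOUR]  # day 2, first half: 3
        + [37 * HOUR, 38 * HOUR, 39 * HOUR, 40 * HOUR, 41 * HOUR]  # 5
    )
    ev = make_events({1: onsets}, span_hours=48)
    b = bin_events(ev, BinSpec(interval_minutes=720))
    cmap = assign_conditions({}, monitors=[1])
    prof = daily_profile(b, cmap)
    prof = prof[prof["condition"] == "Condition"]
    w = prof[prof["time_of_day"].isin([0.0, 12.0])]
    np.testing.assert_allclose(w["mean"].to_numpy(), [2.0, 4.0])
    np.testing.assert_allclose(w["err"].to_numpy(), [1.0, 1.0])


def test_daily_profile_single_day_err_missing():
    ev = make_events({1: [HOUR]}, span_hours=24)
    b = bin_events(ev, BinSpec(interval_minutes=720))
    prof = daily_profile(b, assign_conditions({}, monitors=[1]))
    assert np.isnan(prof["err"]).all()


def test_daily_profile_periodic_zero_error():
    onsets = [d * 24 * HOUR + 5 * HOUR for d in range(4)]
    ev = make_events({1: onsets}, span_hours=96)
    b = bin_events(ev, BinSpec(interval_minutes=60))
    prof = daily_profile(b, assign_conditions({}, monitors=[1]))
    np.testing.assert_allclose(prof["err"].to_numpy(), 0.0, atol=1e-12)


def test_daily_profile_requires_full_day():
    ev = make_events({1: [HOUR]}, span_hours=5)
    b = bin_events(ev, BinSpec(interval_minutes=60))
    with pytest.raises(ValueError, match="complete day"):
        daily_profile(b, assign_conditions({}, monitors=[1]))


def test_one_minute_bins_warn_on_long_data():
    ev = make_events({1: [0]}, span_hours=48)
    with pytest.warns(UserWarning, match="1-min bins"):
        bin_events(ev, BinSpec(interval_minutes=1))
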