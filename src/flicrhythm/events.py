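"""Feeding-event calling from baselined signals.

The four classic FLIC parameters define a feeding event:

* ``feeding_minimum`` — a baselined sample at or above this value is an
  *interaction* (the fly touches the food).
* ``consecutive_licks`` — minimum number of consecutive interaction
  samples for a run to count.
* ``feeding_threshold`` — level the run must pass to be *feeding* rather
  than tasting. By default (``threshold_mode="peak"``) the run's maximum
  must reach it; ``"all"`` requires every sample to.
* ``gap`` (a.k.a. *link*) — two qualified events closer than this are
  merged into one bout. Units must be explicit: ``"5 samples"`` (the
  monitor-code convention) or ``"1.0 s"``.

Algorithm, in order: mark interactions -> run-length encode maximal
interaction runs -> qualify runs (length and threshold) -> merge
qualified events whose separation (next onset minus previous end) is
<= gap. All comparisons are inclusive (>= / <=) so ties behave
deterministically.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["EventParams", "EventTable", "call_feeding_events", "call_all_events",
           "exclude_wells"]


def _parse_gap(gap) -> tuple[float, str]:
    """Parse a gap spec into (value, unit) with unit in {samples, s}."""
    if isinstance(gap, (int, float)):
        # bare numbers keep the monitor-code convention: samples
        return float(gap), "samples"
    m = re.fullmatch(r"\s*([0-9.]+)\s*(samples?|s|sec|seconds?)\s*", str(gap))
    if not m:
        raise ValueError(
            f"cannot parse gap {gap!r}; use e.g. '5 samples' or '1.0 s'"
        )
    value = float(m.group(1))
    unit = "samples" if m.group(2).startswith("sample") else "s"
    return value, unit


@dataclass(frozen=True)
class EventParams:
    """The four event-calling parameters (defaults = the standard preset:
    minimum 5, threshold 15, 2 consecutive licks, link 5 samples)."""

    feeding_minimum: float = 5.0
    feeding_threshold: float = 15.0
    consecutive_licks: int = 2
    gap: str | float = "5 samples"
    threshold_mode: str = "peak"  # "peak" | "all"

    def __post_init__(self):
        if self.feeding_minimum > self.feeding_threshold:
            raise ValueError("feeding_minimum must not exceed feeding_threshold")
        if self.consecutive_licks < 1:
            raise ValueError("consecutive_licks must be >= 1")
        value, _ = _parse_gap(self.gap)
        if value < 0:
            raise ValueError("gap must be nonnegative")
        if self.threshold_mode not in ("peak", "all"):
            raise ValueError("threshold_mode must be 'peak' or 'all'")

    def gap_ms(self, sample_interval_ms: int) -> float:
        value, unit = _parse_gap(self.gap)
        return value * sample_interval_ms if unit == "samples" else value * 1000.0


@dataclass
class EventTable:
    """Called feeding events plus the context needed by summaries.

    ``records`` columns: monitor, well, onset_ms, end_ms — sorted by
    (monitor, well, onset). ``wells`` lists every analyzed (monitor,
    well) pair, including those with zero events, so totals tables keep
    their rows. Events within a well are disjoint and separated by more
    than the merge gap, by construction.
    """

    records: pd.DataFrame
    wells: list[tuple[int, int]]
    origin: pd.Timestamp
    span_ms: tuple[int, int]
    sample_interval_ms: int = 200

    def __post_init__(self):
        cols = ["monitor", "well", "onset_ms", "end_ms"]
        if list(self.records.columns) != cols:
            self.records = self.records[cols]

    @property
    def n_events(self) -> int:
        return len(self.records)

    def onsets(self) -> pd.Series:
        """Absolute timestamps of event onsets."""
        return self.origin + pd.to_timedelta(self.records["onset_ms"], unit="ms")

    def for_well(self, monitor: int, well: int) -> pd.DataFrame:
        r = self.records
        return r[(r["monitor"] == monitor) & (r["well"] == well)]


def call_feeding_events(
    baselined: Sequence[float],
    times: Sequence[int],
    params: EventParams,
    sample_interval_ms: int = 200,
) -> np.ndarray:
    """Call events on one well; returns an (n_events, 2) array of
    [onset_ms, end_ms] (end = time of the last interaction sample)."""
    y = np.asarray(baselined, dtype=float)
    t = np.asarray(times, dtype=np.int64)
    if y.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    mask = y >= params.feeding_minimum
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]  # ends exclusive
    if starts.size == 0:
        return np.empty((0, 2), dtype=np.int64)

    ok = (ends - starts) >= params.consecutive_licks
    # per-run statistic over [start, end): reduceat on interleaved
    # boundaries, discarding the between-run segments
    bounds = np.empty(2 * starts.size, dtype=np.int64)
    bounds[0::2], bounds[1::2] = starts, ends
    if bounds[-1] == y.size:  # reduceat needs indices < len(y)
        bounds = bounds[:-1]
    op = np.maximum if params.threshold_mode == "peak" else np.minimum
    stat = op.reduceat(y, bounds)[0::2]
    ok &= stat >= params.feeding_threshold
    starts, ends = starts[ok], ends[ok]
    if starts.size == 0:
        return np.empty((0, 2), dtype=np.int64)

    onset_t = t[starts]
    end_t = t[ends - 1]
    gap_ms = params.gap_ms(sample_interval_ms)
    # merge events whose separation is <= gap
    sep = onset_t[1:] - end_t[:-1]
    new_event = np.concatenate(([True], sep > gap_ms))
    group = np.cumsum(new_event) - 1
    n_groups = group[-1] + 1
    merged_onset = onset_t[new_event]
    merged_end = np.empty(n_groups, dtype=np.int64)
    merged_end[group] = end_t  # last assignment per group wins (sorted)
    return np.column_stack([merged_onset, merged_end])


def call_all_events(
    baselined_table,
    params: EventParams,
    logger=None,
) -> EventTable:
    """Apply the event caller to every well of a baselined table."""
    rows = []
    wells = []
    mon = baselined_table.monitor_id
    n = baselined_table.n_samples
    for i, well in enumerate(baselined_table.signals.columns, start=1):
        try:
            ev = call_feeding_events(
                baselined_table.signals[well].to_numpy(dtype=float),
                baselined_table.times,
                params,
                baselined_table.sample_interval_ms,
            )
        except Exception as exc:
            raise type(exc)(f"well {well}: {exc}") from exc
        wells.append((mon, i))
        for onset, end in ev:
            rows.append((mon, i, int(onset), int(end)))
        if logger is not None:
            logger.info("monitor %d well %s: %d events", mon, well, len(ev))
    records = pd.DataFrame(rows, columns=["monitor", "well", "onset_ms", "end_ms"])
    records = records.sort_values(["monitor", "well", "onset_ms"], ignore_index=True)
    span = (0, int(baselined_table.times[-1]) if n else 0)
    return EventTable(
        records=records,
        wells=wells,
        origin=baselined_table.wall_clock_origin,
        span_ms=span,
        sample_interval_ms=baselined_table.sample_interval_ms,
    )


def merge_event_tables(tables: Iterable[EventTable]) -> EventTable:
    """Pool event tables from several monitors (origins must match to
    the day for calendar-based summaries; the earliest origin wins)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no event tables to merge")
    if len(tables) == 1:
        return tables[0]
    origin = min(t.origin for t in tables)
    recs = []
    wells = []
    span_end = 0
    for t in tables:
        shift = int((t.origin - origin) / pd.Timedelta(milliseconds=1))
        r = t.records.copy()
        r["onset_ms"] += shift
        r["end_ms"] += shift
        recs.append(r)
        wells.extend(t.wells)
        span_end = max(span_end, t.span_ms[1] + shift)
    records = pd.concat(recs, ignore_index=True).sort_values(
        ["monitor", "well", "onset_ms"], ignore_index=True
    )
    return EventTable(
        records=records,
        wells=wells,
        origin=origin,
        span_ms=(0, span_end),
        sample_interval_ms=tables[0].sample_interval_ms,
    )


def exclude_wells(
    events: EventTable, excluded: Iterable[tuple[int, int]]
) -> EventTable:
    """Drop excluded wells (dead flies, outliers) from the table.

    The exclusion propagates to every downstream summary and
    periodogram because those all consume the returned table. Excluding
    a well that was never analyzed only warns.
    """
    excluded = set(tuple(e) for e in excluded)
    unknown = excluded - set(events.wells)
    if unknown:
        warnings.warn(f"excluded wells not present: {sorted(unknown)}", stacklevel=2)
    keep_wells = [w for w in events.wells if w not in excluded]
    r = events.records
    key = list(zip(r["monitor"], r["well"]))
    mask = np.array([k not in excluded for k in key], dtype=bool)
    return EventTable(
        records=r[mask].reset_index(drop=True) if len(r) else r.copy(),
        wells=keep_wells,
        origin=events.origin,
        span_ms=events.span_ms,
        sample_interval_ms=events.sample_interval_ms,
    )
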