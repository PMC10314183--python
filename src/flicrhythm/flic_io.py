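"""Reading, validating, trimming and writing FLIC monitor tables.

A Drosophila Feeding Monitor (DFM) streams one CSV file of capacitance
readings for 12 food wells at millisecond-stamped, nominally 5 Hz sampling.
This module pins a documented default dialect for those files (header
``Sample, Date, Time, MSec, W1..W12``) while letting every aspect of the
layout be overridden through :class:`Dialect`, since firmware revisions
differ in column layout.

All well indices throughout the package are 1-based (``W1``–``W12``),
matching the labels printed on the monitors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import date, time
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "RawSignalTable",
    "ConditionMap",
    "LightSchedule",
    "DEFAULT_CONDITION",
    "read_flic_csv",
    "write_flic_csv",
    "trim_by_date",
    "assign_conditions",
    "write_table_csv",
    "parse_monitor_id",
]

DEFAULT_CONDITION = "Condition"

#: number of food wells on one monitor
N_WELLS = 12


class FlicFormatError(ValueError):
    """Raised when an input file does not match the configured dialect."""


@dataclass(frozen=True)
class Dialect:
    """Column layout and conventions of a FLIC CSV file.

    Parameters
    ----------
    well_columns
        Ordered names of the 12 well columns.
    time_column, date_column, msec_column
        Names of the wall-clock columns. Date and time are combined with
        ``datetime_format``; the millisecond column carries the
        sub-second part of each timestamp.
    datetime_format
        ``strptime`` format for ``"<date> <time>"``.
    monitor_pattern
        Regex whose first group extracts the monitor number from a
        filename. The default looks for an integer following the token
        ``DFM``; if that fails the reader falls back to the first
        integer anywhere in the name.
    sample_interval_ms
        Nominal milliseconds between consecutive samples (5 Hz -> 200).
    """

    well_columns: tuple[str, ...] = tuple(f"W{i}" for i in range(1, 13))
    time_column: str = "Time"
    date_column: str = "Date"
    msec_column: str = "MSec"
    sample_column: str = "Sample"
    datetime_format: str = "%m/%d/%Y %H:%M:%S"
    monitor_pattern: str = r"DFM[^0-9]*(\d+)"
    sample_interval_ms: int = 200

    def __post_init__(self) -> None:
        if len(self.well_columns) != N_WELLS:
            raise ValueError(
                f"dialect must name exactly {N_WELLS} well columns, "
                f"got {len(self.well_columns)}"
            )
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")


DEFAULT_DIALECT = Dialect()


@dataclass
class RawSignalTable:
    """Time-indexed capacitance readings for the 12 wells of one monitor.

    Attributes
    ----------
    monitor_id
        Positive monitor number (parsed from the filename by default).
    times
        int64 milliseconds since the first sample, strictly increasing.
    signals
        One column per well (``W1``..``W12``), same length as ``times``.
        Integer for raw data; float tables reuse this container for
        baselined signals.
    wall_clock_origin
        Calendar timestamp of the first sample.
    sample_interval_ms
        Nominal sampling interval inherited from the dialect.
    """

    monitor_id: int
    times: np.ndarray
    signals: pd.DataFrame
    wall_clock_origin: pd.Timestamp
    sample_interval_ms: int = 200

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if len(self.signals) != len(self.times):
            raise ValueError("signals and times must have equal length")
        if self.signals.shape[1] != N_WELLS:
            raise ValueError(f"expected {N_WELLS} well columns")
        if self.monitor_id <= 0:
            raise ValueError("monitor_id must be a positive integer")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(
                f"timestamps are not strictly increasing (first offending row {bad})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def well_names(self) -> list[str]:
        return list(self.signals.columns)

    def wall_clock_times(self) -> pd.DatetimeIndex:
        """Absolute timestamp of every sample."""
        return self.wall_clock_origin + pd.to_timedelta(self.times, unit="ms")


@dataclass(frozen=True)
class LightSchedule:
    """Daily light transitions; day is the half-open interval [on, off)."""

    lights_on: time
    lights_off: time

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    def is_day(self, t: time) -> bool:
        on, off = self.lights_on, self.lights_off
        if on < off:
            return on <= t < off
        # schedule wrapping midnight
        return t >= on or t < off

    @classmethod
    def from_strings(cls, lights_on: str, lights_off: str) -> "LightSchedule":
        return cls(time.fromisoformat(lights_on), time.fromisoformat(lights_off))


@dataclass
class ConditionMap:
    """Mapping (monitor, well) -> experimental condition label.

    The same label may appear on several monitors; those wells are pooled
    in every group-level summary. ``excluded`` holds wells dropped from
    all downstream analysis (dead flies, outliers).
    """

    entries: dict[tuple[int, int], str] = field(default_factory=dict)
    excluded: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for mon, well in self.entries:
            if not 1 <= well <= N_WELLS:
                raise ValueError(f"well index {well} outside 1..{N_WELLS}")
        unknown = self.excluded - set(self.entries)
        if unknown:
            raise ValueError(f"excluded wells not in the map: {sorted(unknown)}")

    def label_of(self, monitor: int, well: int) -> str:
        return self.entries.get((monitor, well), DEFAULT_CONDITION)

    def wells_for(self, label: str) -> list[tuple[int, int]]:
        return sorted(k for k, v in self.entries.items() if v == label)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.entries.values():
            seen.setdefault(v)
        return list(seen)


def parse_monitor_id(filename: str, dialect: Dialect = DEFAULT_DIALECT) -> int:
    """Extract the monitor number from a filename.

    Tries the dialect's ``monitor_pattern`` first, then the first integer
    anywhere in the basename.
    """
    base = Path(filename).name
    m = re.search(dialect.monitor_pattern, base)
    if m is None:
        m = re.search(r"(\d+)", base)
    if m is None:
        raise FlicFormatError(
            f"cannot parse a monitor number from {base!r}; "
            "pass an explicit monitor_id override"
        )
    return int(m.group(1))


def read_flic_csv(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    monitor_id: int | None = None,
) -> RawSignalTable:
    """Read one FLIC CSV file into a validated :class:`RawSignalTable`.

    Rows are kept in file order; times are converted to milliseconds
    since the first sample and the wall-clock origin is recorded.

    Raises
    ------
    FlicFormatError
        If well columns are missing or the monitor number cannot be
        determined.
    ValueError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in dialect.well_columns if c not in df.columns]
    if missing:
        raise FlicFormatError(
            f"{path.name}: missing well columns {missing}; "
            f"expected {list(dialect.well_columns)}"
        )
    for col in (dialect.date_column, dialect.time_column):
        if col not in df.columns:
            raise FlicFormatError(f"{path.name}: missing column {col!r}")
    if monitor_id is None:
        monitor_id = parse_monitor_id(path.name, dialect)

    if len(df) == 0:
        return RawSignalTable(
            monitor_id=monitor_id,
            times=np.empty(0, dtype=np.int64),
            signals=pd.DataFrame(
                {c: pd.Series(dtype=np.int64) for c in dialect.well_columns}
            ),
            wall_clock_origin=pd.Timestamp(0),
            sample_interval_ms=dialect.sample_interval_ms,
        )

    stamp = pd.to_datetime(
        df[dialect.date_column].astype(str) + " " + df[dialect.time_column].astype(str),
        format=dialect.datetime_format,
    )
    if dialect.msec_column in df.columns:
        stamp = stamp + pd.to_timedelta(df[dialect.msec_column], unit="ms")
    times = ((stamp - stamp.iloc[0]) / pd.Timedelta(milliseconds=1)).round()
    times = times.to_numpy(dtype=np.int64)

    signals = df[list(dialect.well_columns)].copy()
    return RawSignalTable(
        monitor_id=monitor_id,
        times=times,
        signals=signals,
        wall_clock_origin=pd.Timestamp(stamp.iloc[0]),
        sample_interval_ms=dialect.sample_interval_ms,
    )


def write_flic_csv(
    table: RawSignalTable, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write a signal table back out in the FLIC CSV dialect.

    Round-trips losslessly through :func:`read_flic_csv` for integer
    signals (float signals are written at 6 significant digits).
    """
    stamps = table.wall_clock_times()
    out = pd.DataFrame({dialect.sample_column: np.arange(1, table.n_samples + 1)})
    date_fmt, time_fmt = dialect.datetime_format.split(" ", 1)
    out[dialect.date_column] = stamps.strftime(date_fmt)
    out[dialect.time_column] = stamps.strftime(time_fmt)
    out[dialect.msec_column] = (stamps.microsecond // 1000).astype(np.int64)
    for src, dst in zip(table.signals.columns, dialect.well_columns):
        out[dst] = table.signals[src].to_numpy()
    out.to_csv(path, index=False, float_format="%.6g")


def concat_tables(tables: Sequence[RawSignalTable]) -> RawSignalTable:
    """Concatenate several files from one monitor in chronological order.

    Overlapping timestamp ranges are an error: they indicate duplicate
    exports of the same recording.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    if len({t.monitor_id for t in tables}) != 1:
        raise ValueError("all tables must come from the same monitor")
    ordered = sorted(tables, key=lambda t: t.wall_clock_origin)
    for prev, nxt in zip(ordered, ordered[1:]):
        prev_end = prev.wall_clock_origin + pd.Timedelta(
            milliseconds=int(prev.times[-1]) if prev.n_samples else 0
        )
        if nxt.wall_clock_origin <= prev_end:
            raise ValueError(
                f"overlapping timestamps between files for monitor "
                f"{prev.monitor_id}"
            )
    origin = ordered[0].wall_clock_origin
    times = np.concatenate(
        [
            t.times
            + int((t.wall_clock_origin - origin) / pd.Timedelta(milliseconds=1))
            for t in ordered
        ]
    )
    signals = pd.concat([t.signals for t in ordered], ignore_index=True)
    return RawSignalTable(
        monitor_id=ordered[0].monitor_id,
        times=times,
        signals=signals,
        wall_clock_origin=origin,
        sample_interval_ms=ordered[0].sample_interval_ms,
    )


def trim_by_date(table: RawSignalTable, start: date, end: date) -> RawSignalTable:
    """Keep samples whose calendar date lies in [start, end], inclusive.

    Trimming is whole-day inclusive on both ends, matching date-picker
    semantics. The retained table is re-anchored so ``times`` again
    starts at zero. An empty result is a warning, not an error.
    """
    if start > end:
        raise ValueError("start date must not be after end date")
    if table.n_samples == 0:
        return table
    stamps = table.wall_clock_times()
    dates = stamps.normalize()
    mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    mask = np.asarray(mask)
    if not mask.any():
        warnings.warn(
            f"date trim [{start}..{end}] removed every sample of monitor "
            f"{table.monitor_id}",
            stacklevel=2,
        )
        return RawSignalTable(
            monitor_id=table.monitor_id,
            times=np.empty(0, dtype=np.int64),
            signals=table.signals.iloc[:0].reset_index(drop=True),
            wall_clock_origin=table.wall_clock_origin,
            sample_interval_ms=table.sample_interval_ms,
        )
    idx = np.flatnonzero(mask)
    times = table.times[idx]
    return RawSignalTable(
        monitor_id=table.monitor_id,
        times=times - times[0],
        signals=table.signals.iloc[idx].reset_index(drop=True),
        wall_clock_origin=stamps[idx[0]],
        sample_interval_ms=table.sample_interval_ms,
    )


def assign_conditions(
    map_spec: Mapping[int | str, Mapping[str, Iterable[int]]],
    monitors: Iterable[int],
    excluded: Iterable[tuple[int, int]] = (),
) -> ConditionMap:
    """Build a :class:`ConditionMap` from a config-style nested mapping.

    ``map_spec`` maps monitor number -> {label -> well indices}. Every
    well of every loaded monitor receives a label; wells not mentioned
    get the default label ``"Condition"``. Assigning one well to two
    labels is an error, as is any well index outside 1..12.
    """
    entries: dict[tuple[int, int], str] = {}
    for mon_key, groups in map_spec.items():
        mon = int(mon_key)
        for label, wells in groups.items():
            for well in wells:
                well = int(well)
                if not 1 <= well <= N_WELLS:
                    raise ValueError(
                        f"well index {well} for monitor {mon} outside 1..{N_WELLS}"
                    )
                key = (mon, well)
                if key in entries and entries[key] != label:
                    raise ValueError(
                        f"well {key} assigned to both {entries[key]!r} and {label!r}"
                    )
                entries[key] = label
    for mon in monitors:
        for well in range(1, N_WELLS + 1):
            entries.setdefault((int(mon), well), DEFAULT_CONDITION)
    return ConditionMap(entries=entries, excluded=set(excluded))


def write_table_csv(table, path: str | Path) -> None:
    """Write any output table as RFC-4180 CSV with a header row.

    Floating values are printed at 6 significant digits, which the
    read-back path preserves to 1e-6 relative. Objects exposing
    ``to_frame()`` (e.g. binned series) are flattened first.
    """
    if table is None:
        raise ValueError("table is None")
    if hasattr(table, "to_frame") and not isinstance(table, pd.DataFrame):
        table = table.to_frame()
    if not isinstance(table, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(table)!r}")
    table.to_csv(path, index=False, float_format="%.6g")


def read_table_csv(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table_csv`."""
    return pd.read_csv(path)
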