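"""Structured experiment configuration (TOML) with dotted-key overrides.

One TOML file describes a whole analysis: input files and dialect, date
trim, condition map, light schedule, baseline/event/bin/circadian
parameters, exclusions, and the simulator block. Every key can be
overridden on the command line as ``--set section.key=value``.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from datetime import date, datetime, time
from pathlib import Path
from typing import Any

from .baseline import BaselineParams
from .circadian import PeriodogramParams
from .events import EventParams
from .flic_io import Dialect, LightSchedule
from .summary import BinSpec

__all__ = ["ExperimentConfig", "load_config", "apply_overrides"]


@dataclass
class ExperimentConfig:
    input_paths: list[str] = field(default_factory=list)
    dialect: Dialect = field(default_factory=Dialect)
    trim_start: date | None = None
    trim_end: date | None = None
    conditions: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    schedule: LightSchedule = field(
        default_factory=lambda: LightSchedule(time(9, 0), time(21, 0))
    )
    baseline: BaselineParams = field(default_factory=BaselineParams)
    events: EventParams = field(default_factory=EventParams)
    bins: BinSpec = field(default_factory=BinSpec)
    normalize: bool = False
    norm_mode: str = "sum"
    excluded: list[tuple[int, int]] = field(default_factory=list)
    circadian: PeriodogramParams = field(default_factory=PeriodogramParams)
    outdir: str = "out"
    simulate: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        c = self.circadian
        if c.dd_start is not None and self.trim_start is not None:
            if c.dd_start < self.trim_start or (
                self.trim_end is not None and c.dd_end and c.dd_end > self.trim_end
            ):
                raise ValueError(
                    "circadian: DD window must lie within the trim window"
                )
        for mon, groups in self.conditions.items():
            for label, wells in groups.items():
                for w in wells:
                    if not 1 <= int(w) <= 12:
                        raise ValueError(
                            f"conditions.{mon}.{label}: well {w} outside 1..12"
                        )


def _as_date(v) -> date | None:
    if v is None:
        return None
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def _as_time(v) -> time:
    if isinstance(v, time):
        return v
    return time.fromisoformat(str(v))


def _parse_excluded(items) -> list[tuple[int, int]]:
    out = []
    for item in items:
        if isinstance(item, str):  # "monitor:well"
            mon, well = item.split(":")
            out.append((int(mon), int(well)))
        else:
            mon, well = item
            out.append((int(mon), int(well)))
    return out


def config_from_dict(data: dict[str, Any]) -> ExperimentConfig:
    cfg = ExperimentConfig(raw=data)
    inp = data.get("input", {})
    cfg.input_paths = list(inp.get("paths", []))
    dia = inp.get("dialect", {})
    if dia:
        kwargs = {}
        for key in (
            "time_column",
            "date_column",
            "msec_column",
            "sample_column",
            "datetime_format",
            "monitor_pattern",
            "sample_interval_ms",
        ):
            if key in dia:
                kwargs[key] = dia[key]
        if "well_columns" in dia:
            kwargs["well_columns"] = tuple(dia["well_columns"])
        cfg.dialect = Dialect(**kwargs)

    trim = data.get("trim", {})
    cfg.trim_start = _as_date(trim.get("start"))
    cfg.trim_end = _as_date(trim.get("end"))

    cfg.conditions = {
        str(mon): {label: list(wells) for label, wells in groups.items()}
        for mon, groups in data.get("conditions", {}).items()
    }

    light = data.get("light", {})
    if light:
        cfg.schedule = LightSchedule(
            _as_time(light.get("lights_on", "09:00")),
            _as_time(light.get("lights_off", "21:00")),
        )

    b = data.get("baseline", {})
    als = b.get("als", {})
    cfg.baseline = BaselineParams(
        method=b.get("method", "rm"),
        rm_window_minutes=b.get("rm_window_minutes", 5.0),
        als_lambda=als.get("lambda", 1e8),
        als_p=als.get("p", 0.01),
        als_max_iter=als.get("max_iter", 20),
        als_tol=als.get("tol", 0.0),
        chunk_hours=b.get("chunk_hours", 24.0),
    )

    e = data.get("events", {})
    cfg.events = EventParams(
        feeding_minimum=e.get("feeding_minimum", 5.0),
        feeding_threshold=e.get("feeding_threshold", 15.0),
        consecutive_licks=e.get("consecutive_licks", 2),
        gap=e.get("gap", "5 samples"),
        threshold_mode=e.get("threshold_mode", "peak"),
    )

    bins = data.get("bins", {})
    cfg.bins = BinSpec(
        interval_minutes=bins.get("interval_minutes", 60),
        func=bins.get("func", "sum"),
        error_bar=bins.get("error_bar", "SEM"),
    )

    norm = data.get("normalize", {})
    cfg.normalize = bool(norm.get("enabled", False))
    cfg.norm_mode = norm.get("mode", "sum")

    cfg.excluded = _parse_excluded(data.get("exclude", {}).get("wells", []))

    c = data.get("circadian", {})
    cfg.circadian = PeriodogramParams(
        dd_start=_as_date(c.get("dd_start")),
        dd_end=_as_date(c.get("dd_end")),
        period_min_h=c.get("period_min_h", 16.0),
        period_max_h=c.get("period_max_h", 32.0),
        alpha=c.get("alpha", 0.05),
    )

    cfg.outdir = data.get("output", {}).get("dir", "out")
    cfg.simulate = dict(data.get("simulate", {}))
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def _coerce(value: str) -> Any:
    """Parse an override value as a TOML literal, falling back to str."""
    try:
        return tomllib.loads(f"v = {value}")["v"]
    except tomllib.TOMLDecodeError:
        return value


def apply_overrides(data: dict[str, Any], overrides: list[str]) -> dict[str, Any]:
    """Apply ``section.key=value`` strings onto a raw config dict.

    Unknown section paths are created; a malformed override (no ``=``)
    raises with the offending key path.
    """
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of the form key.path=value")
        keypath, value = item.split("=", 1)
        keys = keypath.strip().split(".")
        node = data
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"override {keypath!r}: {k!r} is not a section")
        node[keys[-1]] = _coerce(value.strip())
    return data
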