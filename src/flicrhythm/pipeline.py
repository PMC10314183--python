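"""End-to-end pipeline: raw CSVs -> baselined -> events -> summaries ->
periodogram, with artifacts persisted between stages.

Stages run in the fixed order baseline -> events -> summarize ->
circadian (mirroring the order the analysis requires). A stage either
runs in the same invocation as its prerequisites or finds their
artifacts in the output directory; otherwise it fails naming the stage
to run first. Given identical inputs and config the pipeline is
deterministic, so re-runs produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from . import circadian as cd
from . import events as ev
from . import flic_io as fio
from . import summary as sm
from . import synth
from .config import ExperimentConfig

__all__ = ["run_pipeline", "run_simulate", "STAGES", "PipelineError"]

STAGES = ("baseline", "events", "summarize", "circadian")


class PipelineError(RuntimeError):
    pass


def _logger(outdir: Path) -> logging.Logger:
    # one logger per output directory so parallel/sequential runs to
    # different outdirs do not cross-write each other's run.log
    logger = logging.getLogger(f"flicrhythm.run.{outdir.resolve()}")
    logger.setLevel(logging.INFO)
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == outdir / "run.log"
        for h in logger.handlers
    ):
        fh = logging.FileHandler(outdir / "run.log")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger


def _write_provenance(config: ExperimentConfig, outdir: Path) -> None:
    def default(o):
        return str(o)

    with open(outdir / "config_used.json", "w") as fh:
        json.dump(config.raw, fh, indent=2, sort_keys=True, default=default)


def run_simulate(config: ExperimentConfig, seed: int | None = None) -> None:
    """Generate FLIC-dialect CSVs (plus truth tables) at the configured
    input paths, one simulated monitor per path."""
    simcfg = dict(config.simulate)
    base_seed = seed if seed is not None else int(simcfg.pop("seed", 0))
    simcfg.pop("seed", None)
    if not config.input_paths:
        raise PipelineError("simulate: config lists no input paths to write")
    groups = simcfg.pop("groups", None)
    for i, path in enumerate(config.input_paths):
        try:
            monitor_id = fio.parse_monitor_id(path, config.dialect)
        except fio.FlicFormatError:
            monitor_id = i + 1
        params = synth.SimulationParams(
            monitor_id=monitor_id,
            seed=base_seed + i,
            sample_interval_ms=config.dialect.sample_interval_ms,
            lights_on=config.schedule.lights_on,
            lights_off=config.schedule.lights_off,
            **simcfg,
        )
        if groups:
            profiles: list = [None] * params.n_wells
            for g in groups:
                kind = g["profile"]
                kwargs = {
                    k: v for k, v in g.items() if k not in ("profile", "wells")
                }
                prof = synth.make_profile(kind, **kwargs)
                for w in g["wells"]:
                    profiles[int(w) - 1] = prof
            if any(p is None for p in profiles):
                raise PipelineError("simulate.groups must cover every well")
            params.profiles = profiles
        table, truth = synth.simulate_experiment(params)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fio.write_flic_csv(table, path, config.dialect)
        fio.write_table_csv(truth.bouts, Path(path).with_suffix("").as_posix() + "_truth.csv")


def _load_raw(config: ExperimentConfig) -> list[fio.RawSignalTable]:
    by_monitor: dict[int, list[fio.RawSignalTable]] = {}
    for path in config.input_paths:
        t = fio.read_flic_csv(path, config.dialect)
        by_monitor.setdefault(t.monitor_id, []).append(t)
    tables = [fio.concat_tables(ts) for ts in by_monitor.values()]
    if config.trim_start is not None and config.trim_end is not None:
        tables = [
            fio.trim_by_date(t, config.trim_start, config.trim_end) for t in tables
        ]
    loaded = {t.monitor_id for t in tables}
    referenced = {int(m) for m in config.conditions}
    missing = referenced - loaded
    if missing:
        raise PipelineError(
            f"condition map references monitors not among the inputs: {sorted(missing)}"
        )
    return tables


def _baselined_path(outdir: Path, monitor_id: int) -> Path:
    return outdir / f"baselined_DFM_{monitor_id}.csv"


def _require(condition: bool, stage: str, needed: str) -> None:
    if not condition:
        raise PipelineError(
            f"stage {stage!r} requires the {needed!r} stage to run first "
            f"(in this invocation or a previous one writing to the same outdir)"
        )


def run_pipeline(
    config: ExperimentConfig, stages: tuple[str, ...] = STAGES
) -> Path:
    """Run the requested pipeline stages; returns the output directory."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}; choose from {STAGES}")
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _logger(outdir)
    _write_provenance(config, outdir)

    baselined: list[fio.RawSignalTable] | None = None
    event_table: ev.EventTable | None = None
    cmap: fio.ConditionMap | None = None

    if "baseline" in stages:
        raws = _load_raw(config)
        baselined = [bl.baseline_table(t, config.baseline) for t in raws]
        for t in baselined:
            fio.write_flic_csv(t, _baselined_path(outdir, t.monitor_id), config.dialect)
        log.info(
            "baselined %d monitor(s) with method=%s", len(baselined),
            config.baseline.method,
        )

    if "events" in stages:
        if baselined is None:
            paths = sorted(outdir.glob("baselined_DFM_*.csv"))
            _require(bool(paths), "events", "baseline")
            baselined = [fio.read_flic_csv(p, config.dialect) for p in paths]
        cmap = fio.assign_conditions(
            config.conditions,
            monitors=[t.monitor_id for t in baselined],
            excluded=[
                e
                for e in config.excluded
                if any(t.monitor_id == e[0] for t in baselined)
            ],
        )
        per_monitor = [ev.call_all_events(t, config.events, log) for t in baselined]
        event_table = ev.merge_event_tables(per_monitor)
        event_table = ev.exclude_wells(event_table, cmap.excluded)
        recs = event_table.records.copy()
        recs["condition"] = [
            cmap.label_of(int(m), int(w))
            for m, w in zip(recs["monitor"], recs["well"])
        ]
        recs["onset"] = (
            event_table.origin + pd.to_timedelta(recs["onset_ms"], unit="ms")
        ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        fio.write_table_csv(recs, outdir / "events.csv")
        meta = {
            "origin": event_table.origin.isoformat(),
            "span_ms": list(event_table.span_ms),
            "wells": [list(w) for w in event_table.wells],
            "sample_interval_ms": event_table.sample_interval_ms,
        }
        with open(outdir / "events_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        log.info("called %d events on %d wells", event_table.n_events,
                 len(event_table.wells))

    def _load_events() -> ev.EventTable:
        meta_path = outdir / "events_meta.json"
        _require(meta_path.exists(), stage, "events")
        with open(meta_path) as fh:
            meta = json.load(fh)
        recs = pd.read_csv(outdir / "events.csv")
        return ev.EventTable(
            records=recs[["monitor", "well", "onset_ms", "end_ms"]],
            wells=[tuple(w) for w in meta["wells"]],
            origin=pd.Timestamp(meta["origin"]),
            span_ms=tuple(meta["span_ms"]),
            sample_interval_ms=meta["sample_interval_ms"],
        )

    for stage in ("summarize", "circadian"):
        if stage not in stages:
            continue
        if event_table is None:
            event_table = _load_events()
        if cmap is None:
            monitors = sorted({m for m, _ in event_table.wells})
            cmap = fio.assign_conditions(config.conditions, monitors=monitors)

        if stage == "summarize":
            totals = sm.individual_totals(event_table)
            fio.write_table_csv(totals, outdir / "individual_stats.csv")
            gstats = sm.group_stats(totals, cmap)
            fio.write_table_csv(gstats, outdir / "group_stats.csv")
            flagged = sm.flag_outliers(totals, cmap)
            if flagged:
                log.info("outlier wells by Tukey fences: %s", sorted(flagged))
            binned = sm.bin_events(event_table, config.bins)
            if config.normalize:
                binned = sm.normalize_wells(binned, config.norm_mode)
            fio.write_table_csv(binned, outdir / "binned.csv")
            perday = sm.events_per_day(event_table)
            fio.write_table_csv(perday, outdir / "events_per_day.csv")
            daynight = sm.split_day_night(event_table, config.schedule)
            fio.write_table_csv(daynight, outdir / "day_night.csv")
            profile = sm.daily_profile(binned, cmap)
            fio.write_table_csv(profile, outdir / "daily_profile.csv")
            log.info("summaries written for %d wells", len(event_table.wells))

        if stage == "circadian":
            spec = sm.BinSpec(interval_minutes=30, func="sum")
            binned = sm.bin_events(event_table, spec)
            if config.normalize:
                binned = sm.normalize_wells(binned, config.norm_mode)
            dd = cd.select_dd_window(binned, config.circadian)
            dead = [
                w
                for w in dd.wells
                if np.ptp(dd.values[w].to_numpy()) == 0
            ]
            if dead:
                log.info(
                    "skipping constant (no-signal) wells in circadian "
                    "analysis: %s",
                    dead,
                )
                dd = replace(dd, values=dd.values.drop(columns=dead))
            results = cd.periodogram_table(dd, config.circadian)
            table, curves, outliers = cd.periodogram_summary(results, cmap)
            fio.write_table_csv(table, outdir / "periodogram_summary.csv")
            fio.write_table_csv(curves, outdir / "periodogram_curves.csv")
            per_well = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "monitor": mon,
                            "well": well,
                            "period_h": res.periods_h,
                            "power": res.power,
                        }
                    )
                    for (mon, well), res in results.items()
                ],
                ignore_index=True,
            )
            fio.write_table_csv(per_well, outdir / "periodogram.csv")
            if outliers:
                log.info("peak-power outliers: %s", sorted(outliers))
            log.info("periodogram computed for %d wells", len(results))

    return outdir
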