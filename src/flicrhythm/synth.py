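"""Synthetic FLIC signal generator with ground truth.

Emulates what a capacitance feeding monitor records: a high, slowly
drifting baseline; short positive deflections while a fly contacts the
food (feeding bouts); and Gaussian sensor noise, quantized to integer
counts. Bout onsets are drawn from an inhomogeneous Poisson process whose
rate follows a chosen time-of-day profile, so circadian structure in the
output is known exactly. The generator returns both the raw signal table
and the list of true bouts, which downstream tests use as ground truth.

The default experiment mirrors a standard rhythmicity assay: 12 wells,
3 days of 12:12 light-dark (lights on 09:00, off 21:00) followed by
4 days of constant darkness; wells 1-6 carry a flat (arrhythmic) bout
rate and wells 7-12 a bimodal rate peaking at the light transitions,
the wild-type feeding phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import time
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .flic_io import LightSchedule, RawSignalTable

__all__ = [
    "FlatProfile",
    "BimodalProfile",
    "SinusoidalProfile",
    "make_profile",
    "rate_profile",
    "SimulationParams",
    "SimulationTruth",
    "draw_bouts",
    "simulate_experiment",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class FlatProfile:
    """Constant bout rate (events/hour) — an arrhythmic feeder."""

    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")

    def __call__(self, t_hours):
        return np.full_like(np.asarray(t_hours, dtype=float), self.rate)

    @property
    def max_rate(self) -> float:
        return self.rate


def _circular_gauss(tod, center, width):
    # shortest distance on the 24 h circle
    d = np.abs(np.mod(tod - center, HOURS_PER_DAY))
    d = np.minimum(d, HOURS_PER_DAY - d)
    return np.exp(-0.5 * (d / width) ** 2)


@dataclass(frozen=True)
class BimodalProfile:
    """Base rate plus Gaussian peaks at lights-on and lights-off.

    The peaks sit exactly at the two light transitions, reproducing the
    crepuscular feeding pattern of wild-type flies (peak rate =
    ``r_base + peak_height`` at each transition). Time is taken modulo
    24 h, so the pattern free-runs unchanged in constant darkness.
    """

    r_base: float
    peak_height: float
    peak_width_h: float
    lights_on_h: float = 9.0
    lights_off_h: float = 21.0

    def __post_init__(self):
        if min(self.r_base, self.peak_height, self.peak_width_h) < 0:
            raise ValueError("bimodal profile parameters must be nonnegative")

    def __call__(self, t_hours):
        tod = np.mod(np.asarray(t_hours, dtype=float), HOURS_PER_DAY)
        return self.r_base + self.peak_height * (
            _circular_gauss(tod, self.lights_on_h, self.peak_width_h)
            + _circular_gauss(tod, self.lights_off_h, self.peak_width_h)
        )

    @property
    def max_rate(self) -> float:
        # peaks 12 h apart with width ~1 h: cross-terms are negligible but
        # included for correctness via a dense scan
        tod = np.linspace(0, HOURS_PER_DAY, 24 * 60, endpoint=False)
        return float(np.max(self(tod)))


@dataclass(frozen=True)
class SinusoidalProfile:
    """Cosine-modulated rate: mesor + amplitude*cos(2*pi*(t - phase)/period).

    Evaluated on absolute hours since the start of the simulated
    experiment (not time-of-day) so that non-24 h periods free-run
    correctly. Negative excursions (amplitude > mesor) are clipped at 0.
    """

    mesor: float
    amplitude: float
    period_h: float = 24.0
    phase_h: float = 0.0

    def __post_init__(self):
        if self.mesor < 0 or self.amplitude < 0 or self.period_h <= 0:
            raise ValueError("mesor/amplitude must be >= 0 and period > 0")

    def __call__(self, t_hours):
        t = np.asarray(t_hours, dtype=float)
        r = self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.phase_h) / self.period_h
        )
        return np.maximum(r, 0.0)

    @property
    def max_rate(self) -> float:
        return self.mesor + self.amplitude


_PROFILE_KINDS = {
    "flat": FlatProfile,
    "bimodal": BimodalProfile,
    "sinusoidal": SinusoidalProfile,
}

Profile = Callable[[np.ndarray], np.ndarray]


def make_profile(kind: str, **params) -> Profile:
    """Construct a rate profile by name (``flat|bimodal|sinusoidal``)."""
    try:
        cls = _PROFILE_KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown profile kind {kind!r}; choose from {sorted(_PROFILE_KINDS)}"
        ) from None
    return cls(**params)


def rate_profile(kind: str, params: dict, t_hours) -> np.ndarray:
    """Evaluate a named rate profile at time(s) ``t_hours`` (events/hour)."""
    return make_profile(kind, **params)(t_hours)


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment; defaults emulate the 7-day assay."""

    n_wells: int = 12
    n_ld_days: int = 3
    n_dd_days: int = 4
    sample_interval_ms: int = 200
    lights_on: time = time(9, 0)
    lights_off: time = time(21, 0)
    baseline_level: float = 100.0
    drift_amplitude: float = 20.0  # a.u. of drift envelope per day
    noise_sd: float = 2.0
    bout_amplitude: float = 20.0
    bout_duration_s: float = 3.0  # mean; durations are 1 s + Exp(mean - 1 s)
    bout_min_duration_s: float = 1.0
    profiles: Sequence[Profile] | None = None
    monitor_id: int = 1
    start: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2021-07-01 00:00:00")
    )
    seed: int = 0

    @property
    def duration_days(self) -> float:
        return self.n_ld_days + self.n_dd_days

    @property
    def schedule(self) -> LightSchedule:
        return LightSchedule(self.lights_on, self.lights_off)

    def resolved_profiles(self) -> list[Profile]:
        """Per-well rate profiles; default = half flat, half bimodal."""
        if self.profiles is not None:
            profs = list(self.profiles)
            if len(profs) == 1:
                profs = profs * self.n_wells
            if len(profs) != self.n_wells:
                raise ValueError(
                    f"need 1 or {self.n_wells} profiles, got {len(profs)}"
                )
            return profs
        on_h = self.lights_on.hour + self.lights_on.minute / 60
        off_h = self.lights_off.hour + self.lights_off.minute / 60
        half = self.n_wells // 2
        flat = FlatProfile(3.0)
        bimodal = BimodalProfile(1.0, 6.0, 1.0, lights_on_h=on_h, lights_off_h=off_h)
        return [flat] * half + [bimodal] * (self.n_wells - half)

    def validate(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("experiment must span at least part of a day")
        if not 1 <= self.n_wells <= 12:
            raise ValueError("a FLIC monitor has 1..12 wells")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample_interval_ms must be positive")
        if self.noise_sd < 0 or self.bout_amplitude < 0:
            raise ValueError("noise_sd and bout_amplitude must be nonnegative")
        if self.bout_min_duration_s <= 0 or self.bout_duration_s < self.bout_min_duration_s:
            raise ValueError("bout_duration_s must be >= bout_min_duration_s > 0")
        if 0 < self.bout_amplitude <= self.noise_sd:
            warnings.warn(
                "bout_amplitude <= noise_sd: bouts will be buried in noise",
                stacklevel=2,
            )


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the simulated signals.

    ``bouts`` has one row per true feeding bout: well (1-based),
    onset_ms, end_ms (ms since experiment start; bouts are sorted and
    non-overlapping within each well).
    """

    bouts: pd.DataFrame
    params: SimulationParams
    seed: int

    def bouts_for(self, well: int) -> pd.DataFrame:
        return self.bouts[self.bouts["well"] == well].reset_index(drop=True)


def draw_bouts(
    rng: np.random.Generator,
    profile: Profile,
    duration_days: float,
    bout_duration_s: float = 3.0,
    bout_min_duration_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson bout onsets by thinning, with durations.

    Candidates are drawn from a homogeneous process at the profile's
    maximum rate and accepted with probability rate(t)/max_rate; this
    construction makes an independent replay of the same RNG stream
    reproduce the bout set exactly. Candidates overlapping the previous
    accepted bout are dropped to keep bouts disjoint.
    """
    total_h = duration_days * HOURS_PER_DAY
    lam = getattr(profile, "max_rate", None)
    if lam is None:
        lam = float(np.max(profile(np.linspace(0, total_h, 10000))))
    if lam <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    onsets = []
    ends = []
    t = 0.0
    prev_end_h = -np.inf
    mean_extra = bout_duration_s - bout_min_duration_s
    while True:
        t += rng.exponential(1.0 / lam)
        if t >= total_h:
            break
        u = rng.uniform()
        dur_s = bout_min_duration_s + (
            rng.exponential(mean_extra) if mean_extra > 0 else 0.0
        )
        if u * lam >= float(profile(t)):
            continue
        if t <= prev_end_h:
            continue  # would overlap the previous bout
        onsets.append(t)
        prev_end_h = t + dur_s / 3600.0
        ends.append(prev_end_h)
    onset_ms = (np.asarray(onsets) * 3_600_000.0).astype(np.int64)
    end_ms = (np.asarray(ends) * 3_600_000.0).astype(np.int64)
    return onset_ms, end_ms


def simulate_experiment(
    params: SimulationParams | None = None,
) -> tuple[RawSignalTable, SimulationTruth]:
    """Generate one monitor's raw signal table plus its ground truth.

    signal = baseline_level + drift + bout plateaus + Gaussian noise,
    rounded to integer counts. Drift is a Gaussian random walk low-pass
    filtered to a > 1 h timescale and scaled so its envelope grows by
    ``drift_amplitude`` per simulated day — slow enough that both a 5-min
    running median and the asymmetric least squares smoother remove it.
    Identical seeds give identical output.
    """
    if params is None:
        params = SimulationParams()
    params.validate()

    interval = params.sample_interval_ms
    total_ms = int(round(params.duration_days * 24 * 3_600_000))
    n = total_ms // interval
    if n == 0:
        raise ValueError("zero-length experiment")
    times = np.arange(n, dtype=np.int64) * interval

    profiles = params.resolved_profiles()
    root = np.random.default_rng(params.seed)
    children = root.spawn(params.n_wells)

    # drift is drawn as a random walk on a 1-min grid, smoothed to a 1 h
    # timescale, then interpolated to sample resolution (cheap and smooth)
    n_coarse = max(int(np.ceil(total_ms / 60_000)) + 1, 4)
    coarse_t = np.arange(n_coarse) * 60_000.0
    columns: dict[str, np.ndarray] = {}
    rows = []
    for w, (rng, profile) in enumerate(zip(children, profiles), start=1):
        onset_ms, end_ms = draw_bouts(
            rng, profile, params.duration_days,
            params.bout_duration_s, params.bout_min_duration_s,
        )
        for o, e in zip(onset_ms, end_ms):
            rows.append((w, int(o), int(e)))

        signal = np.full(n, params.baseline_level, dtype=float)
        if params.drift_amplitude > 0:
            walk = np.cumsum(rng.standard_normal(n_coarse))
            coarse = gaussian_filter1d(walk, sigma=60.0, mode="nearest")
            coarse -= coarse[0]
            peak = np.max(np.abs(coarse))
            if peak > 0:
                coarse *= params.drift_amplitude * params.duration_days / peak
            signal += np.interp(times.astype(float), coarse_t, coarse)
        if len(onset_ms):
            # sample i covers time i*interval; elevated iff onset <= t < end
            start_idx = np.ceil(onset_ms / interval).astype(np.int64)
            end_idx = np.minimum(np.ceil(end_ms / interval).astype(np.int64), n)
            delta = np.zeros(n + 1)
            np.add.at(delta, start_idx, params.bout_amplitude)
            np.add.at(delta, end_idx, -params.bout_amplitude)
            signal += np.cumsum(delta[:-1])
        if params.noise_sd > 0:
            signal += rng.normal(0.0, params.noise_sd, n)
        columns[f"W{w}"] = np.rint(signal).astype(np.int64)

    for w in range(params.n_wells + 1, 13):
        columns[f"W{w}"] = np.zeros(n, dtype=np.int64)  # unused wells idle

    table = RawSignalTable(
        monitor_id=params.monitor_id,
        times=times,
        signals=pd.DataFrame(columns),
        wall_clock_origin=params.start,
        sample_interval_ms=interval,
    )
    bouts = pd.DataFrame(rows, columns=["well", "onset_ms", "end_ms"])
    truth = SimulationTruth(bouts=bouts, params=params, seed=params.seed)
    return table, truth
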