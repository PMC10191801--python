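"""Simulation and pipeline configuration.

:class:`SimConfig` collects every tunable of the synthetic PIT-telemetry
generator: cohort structure, environmental-series dynamics, the individual
cue-threshold mechanism that creates between-year repeatability, travel and
residence distributions, tributary fidelity, and the optional social-coupling
parameter.  :class:`RunConfig` is the thin orchestration config for one-command
end-to-end runs.

Both round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SEXES = ("F", "M")
DIRECTIONS = ("up", "down")

#: Sliding-window scan grid bounds/step (hours); also constrain the
#: generator's true cue window so that truth always lies on the grid.
GRID_STEP_H = 4
GRID_MIN_H = 8
GRID_MAX_H = 240


def _sexdict(f: float, m: float) -> dict[str, float]:
    return {"F": f, "M": m}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-season spawning-migration simulation.

    Defaults emulate the study system: a spring run of ~120 tagged adults
    (67 F / 56 M), a monotonically warming river with diel cycling and
    synoptic (multi-day) weather wiggles, a stochastically declining water
    level with rain pulses, individual temperature thresholds evaluated over
    a fixed window before tributary arrival, high tributary fidelity, and
    sex-specific swimming speeds.
    """

    # cohort
    n_females: int = 67
    n_males: int = 56
    years: tuple[int, ...] = (2018, 2019)
    fork_length_mean: dict[str, float] = field(default_factory=lambda: _sexdict(772.0, 720.0))
    fork_length_sd: dict[str, float] = field(default_factory=lambda: _sexdict(92.0, 139.0))

    # season span (environmental series and all events live inside it)
    season_start_month_day: str = "04-15"
    season_days: int = 75

    # water temperature (degC): base + trend*day + diel + OU weather + white noise
    temp_base: float = 6.0
    temp_trend: float = 0.2          # degC per day
    temp_diel_amplitude: float = 1.5  # degC, peak of the sinusoidal diel cycle
    temp_noise_sd: float = 0.3       # degC, iid per 10-min sample
    temp_weather_sd: float = 1.0     # degC, stationary SD of the OU weather component
    temp_weather_tau_h: float = 12.0  # hours, OU correlation time

    # water level (m): declining baseline + Poisson rain pulses w/ exp decay + noise
    level_base: float = 1.2
    level_decline: float = 0.01      # m per day
    rain_rate: float = 0.35          # pulse events per day
    rain_pulse: float = 0.25         # m added per pulse (exponentially distributed scale)
    pulse_decay: float = 0.04        # per hour
    level_noise_sd: float = 0.01     # m

    # cue mechanism: individual i arrives at its tributary (MS2) at the first
    # 10-min grid time t where the cue averaged over
    # [t - true_lag_h, t - true_lag_h + true_duration_h) crosses tau_i
    cue_variable: str = "temperature"   # or "level"
    cue_direction: str | None = None    # "rising"/"falling"; None = by variable
    true_lag_h: int = 200
    true_duration_h: int = 40
    threshold_mean: dict[str, float] = field(default_factory=lambda: _sexdict(9.5, 8.5))
    threshold_sd: dict[str, float] = field(default_factory=lambda: _sexdict(0.15, 0.15))
    threshold_individual_sd: float = 1.0

    # travel: log(speed km/day) ~ Normal(travel_mu[sex][dir], travel_sigma[sex][dir])
    travel_mu: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "F": {"up": 0.683, "down": 1.737},   # exp() ~= 1.98 / 5.68 km/day
            "M": {"up": 1.065, "down": 0.967},   # exp() ~= 2.90 / 2.63 km/day
        }
    )
    travel_sigma: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"F": {"up": 0.5, "down": 0.5}, "M": {"up": 0.5, "down": 0.5}}
    )
    residence_mean: dict[str, float] = field(default_factory=lambda: _sexdict(12.0, 16.0))
    residence_sd: dict[str, float] = field(default_factory=lambda: _sexdict(3.0, 3.0))

    # river geometry (rkm): gate (Site L) distance from the ocean and
    # tributary distances upstream of the gate
    mouth_to_gate_km: float = 22.0
    tributary_km: tuple[float, ...] = (0.79, 1.70, 2.62, 3.53)
    capacity_weights: tuple[float, ...] = (0.35, 0.25, 0.25, 0.15)
    fidelity_prob: float = 0.85
    multi_tributary_prob: float = 0.15
    social_alpha: float = 0.0

    # diel preference: clock-time of events pulled toward a von Mises mode
    diel_nudge: bool = True
    diel_phase_h: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"F": {"up": 16.0, "down": 23.0}, "M": {"up": 15.0, "down": 13.0}}
    )
    diel_kappa: float = 2.0

    seed: int = 0

    # -- validation ---------------------------------------------------------

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.tributary_km = tuple(float(d) for d in self.tributary_km)
        self.capacity_weights = tuple(float(w) for w in self.capacity_weights)
        self.validate()

    def validate(self) -> None:
        if self.n_females <= 0 or self.n_males <= 0:
            raise ValueError("cohort counts must be positive")
        if len(self.years) < 1:
            raise ValueError("at least one season required")
        if self.season_days <= 0:
            raise ValueError("season length must be positive")
        if not (0.0 <= self.fidelity_prob <= 1.0):
            raise ValueError("fidelity_prob must lie in [0, 1]")
        if not (0.0 <= self.multi_tributary_prob <= 1.0):
            raise ValueError("multi_tributary_prob must lie in [0, 1]")
        if self.cue_variable not in ("temperature", "level"):
            raise ValueError(f"unknown cue variable {self.cue_variable!r}")
        lag, dur = self.true_lag_h, self.true_duration_h
        if not (GRID_MIN_H <= dur <= lag <= GRID_MAX_H):
            raise ValueError(
                f"true window must satisfy {GRID_MIN_H} <= duration <= lag <= {GRID_MAX_H}"
            )
        if lag % GRID_STEP_H or dur % GRID_STEP_H:
            raise ValueError(f"true window must lie on the {GRID_STEP_H}-h scan grid")
        for name in (
            "temp_noise_sd", "temp_weather_sd", "level_noise_sd",
            "threshold_individual_sd", "diel_kappa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for sex in SEXES:
            if self.threshold_sd[sex] < 0 or self.residence_sd[sex] < 0:
                raise ValueError("sigma parameters must be non-negative")
            for d in DIRECTIONS:
                if self.travel_sigma[sex][d] < 0:
                    raise ValueError("travel_sigma must be non-negative")
        if len(self.capacity_weights) != len(self.tributary_km):
            raise ValueError("capacity_weights must match tributary_km in length")
        if any(w < 0 for w in self.capacity_weights) or sum(self.capacity_weights) <= 0:
            raise ValueError("capacity_weights must be non-negative and sum > 0")
        if any(d <= 0 for d in self.tributary_km):
            raise ValueError("tributary distances must be positive")

    # -- derived ------------------------------------------------------------

    @property
    def n_tributaries(self) -> int:
        return len(self.tributary_km)

    def cue_rising(self) -> bool:
        """Whether the threshold is crossed from below (rising cue)."""
        if self.cue_direction is not None:
            return self.cue_direction == "rising"
        return self.cue_variable == "temperature"

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["tributary_km"] = list(self.tributary_km)
        d["capacity_weights"] = list(self.capacity_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> derive -> analyses)."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "migtiming_run"
    overwrite: bool = False
    alpha: float = 0.05
    window_iterations: int = 999
    social_iterations: int = 9999
    window_seed: int = 7
    social_seed: int = 11
    day_start: str = "04:20"
    day_end: str = "18:37"
    run_repeatability: bool = True
    run_timing_models: bool = True
    run_window_scan: bool = True
    run_social_test: bool = True
    run_travel_time: bool = True

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output paths and
        overwrite policy excluded, so identical analyses hash identically)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("overwrite", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
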