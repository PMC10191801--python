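"""Synthetic PIT-telemetry generator with known ground truth.

Emulates a two-season spawning run of an iteroparous salmonid past a mainstem
gate antenna (Site L) into a handful of spawning tributaries.  Every mechanism
the downstream analyses are designed to detect is injected with a known
parameter, so the whole pipeline is testable without field data:

* between-year timing repeatability, via persistent per-individual cue
  thresholds (``threshold_individual_sd``) plus transient per-year deviations
  (``threshold_sd``);
* a critical environmental cue window: individual *i* arrives at its tributary
  (stage MS2) at the first 10-min grid time ``t`` whose cue average over
  ``[t - lag, t - lag + duration)`` crosses the individual's threshold;
* tributary site fidelity and optional social coupling (``social_alpha``):
  non-homing fish inflate (deflate) the odds of following the nearest
  same-sex comigrant's tributary by ``exp(social_alpha)``;
* sex/direction-specific lognormal swimming speeds and diel clock-time
  preferences (von Mises).

Mainstem-gate arrival (MS1) and river-mouth departure are derived *backwards*
from the cue-triggered tributary arrival by subtracting lognormal travel
times; residence at the tributary and downstream travel give MS3 and MS4.
Anchoring the cue at MS2 keeps the generator's true window on the same
reference point the sliding-window scan uses.  Transit times over the short
gate<->tributary legs are behavior-dominated (holding/staging) and therefore
drawn independently of the specific tributary chosen, which makes gate
passage timing exchangeable with respect to tributary labels when the social
coupling is off.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimConfig
from .envseries import EnvSeries

STAGES = ("MS1", "MS2", "MS3", "MS4")
_STAGE_DIRECTION = {"MS1": "up", "MS2": "up", "MS3": "down", "MS4": "down"}

GATE_SITE = "L"


def tributary_sites(n: int) -> list[str]:
    return [f"T{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# environment


def _season_start(config: SimConfig, year: int) -> pd.Timestamp:
    return pd.Timestamp(f"{year}-{config.season_start_month_day}")


def _rain_pulse_times(rng: np.random.Generator, n_days: float, rate: float) -> np.ndarray:
    """Homogeneous Poisson pulse onset times (hours since series start)."""
    n = rng.poisson(rate * n_days)
    return np.sort(rng.uniform(0.0, n_days * 24.0, size=n))


def simulate_environment(
    config: SimConfig, year: int, rng: np.random.Generator | None = None
) -> tuple[EnvSeries, EnvSeries]:
    """Simulate one season of 10-min water temperature and water level.

    Temperature = linear warming trend + sinusoidal diel cycle (peak at 15:00)
    + an Ornstein-Uhlenbeck "weather" component + iid noise; its daily means
    are non-decreasing in expectation.  Level = linearly declining baseline +
    Poisson rain pulses with exponential decay + iid noise, floored at zero.
    """
    if config.season_days <= 0:
        raise ValueError("season length must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, year, 0xE0]))
    n = config.season_days * 144  # 10-min samples
    h = np.arange(n) / 6.0  # hours since season start
    start = _season_start(config, year)

    temp = config.temp_base + config.temp_trend * (h / 24.0)
    temp = temp + config.temp_diel_amplitude * np.cos(2 * np.pi * (h - 15.0) / 24.0)
    if config.temp_weather_sd > 0:
        phi = np.exp(-(1 / 6.0) / config.temp_weather_tau_h)
        innov = rng.standard_normal(n) * config.temp_weather_sd * np.sqrt(1 - phi**2)
        x0 = rng.standard_normal() * config.temp_weather_sd
        weather, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x0]))
        temp = temp + weather
    if config.temp_noise_sd > 0:
        temp = temp + rng.standard_normal(n) * config.temp_noise_sd

    level = config.level_base - config.level_decline * (h / 24.0)
    for t0 in _rain_pulse_times(rng, config.season_days, config.rain_rate):
        tail = h >= t0
        level[tail] += config.rain_pulse * np.exp(-config.pulse_decay * (h[tail] - t0))
    if config.level_noise_sd > 0:
        level = level + rng.standard_normal(n) * config.level_noise_sd
    level = np.maximum(level, 0.0)

    return (
        EnvSeries("temperature", start, temp),
        EnvSeries("level", start, level),
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortTruth:
    """Persistent per-individual latent traits."""

    threshold: dict[str, float]
    home_tributary: dict[str, str]


def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw the tagged cohort: sex, fork length, persistent cue threshold,
    and home tributary.

    Thresholds are ``sex mean + N(0, threshold_individual_sd)`` and persist
    across years; fork lengths are normal around sex-specific means.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    sexes = ["F"] * config.n_females + ["M"] * config.n_males
    n = len(sexes)
    tags = [f"A{i + 1:04d}" for i in range(n)]
    tribs = tributary_sites(config.n_tributaries)
    weights = np.asarray(config.capacity_weights) / sum(config.capacity_weights)

    fl = np.empty(n)
    tau = np.empty(n)
    for i, sex in enumerate(sexes):
        fl[i] = rng.normal(config.fork_length_mean[sex], config.fork_length_sd[sex])
        tau[i] = config.threshold_mean[sex] + rng.normal(0.0, config.threshold_individual_sd)
    home = rng.choice(len(tribs), size=n, p=weights)
    year_tagged = rng.choice([config.years[0] - 2, config.years[0] - 1, config.years[0]],
                             size=n, p=[0.2, 0.25, 0.55])

    individuals = pd.DataFrame(
        {
            "tag_id": tags,
            "sex": sexes,
            "fork_length_mm": np.round(fl, 1),
            "year_tagged": year_tagged,
        }
    )
    truth = CohortTruth(
        threshold=dict(zip(tags, tau)),
        home_tributary={t: tribs[k] for t, k in zip(tags, home)},
    )
    return individuals, truth


# ---------------------------------------------------------------------------
# detections


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses try to recover."""

    true_lag_h: int
    true_duration_h: int
    cue_variable: str
    social_alpha: float
    threshold: dict[str, float]
    home_tributary: dict[str, str]
    stage_times: pd.DataFrame  # tag_id, year, stage, timestamp, site_id
    tributaries: pd.DataFrame  # tag_id, year, first_tributary, last_tributary, n_tributaries
    speeds: pd.DataFrame       # tag_id, year, direction, speed_km_day
    non_migrants: dict[int, list[str]] = field(default_factory=dict)

    def n_non_migrants(self) -> int:
        return sum(len(v) for v in self.non_migrants.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_lag_h": self.true_lag_h,
            "true_duration_h": self.true_duration_h,
            "cue_variable": self.cue_variable,
            "social_alpha": self.social_alpha,
            "threshold": self.threshold,
            "home_tributary": self.home_tributary,
            "non_migrants": {str(y): v for y, v in self.non_migrants.items()},
            "stage_times": _frame_to_records(self.stage_times, ["timestamp"]),
            "tributaries": _frame_to_records(self.tributaries, []),
            "speeds": _frame_to_records(self.speeds, []),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        stage = pd.DataFrame(d["stage_times"])
        if len(stage):
            stage["timestamp"] = pd.to_datetime(stage["timestamp"], format="ISO8601")
            stage = stage[["tag_id", "year", "stage", "timestamp", "site_id"]]
        return cls(
            true_lag_h=d["true_lag_h"],
            true_duration_h=d["true_duration_h"],
            cue_variable=d["cue_variable"],
            social_alpha=d["social_alpha"],
            threshold=d["threshold"],
            home_tributary=d["home_tributary"],
            stage_times=stage,
            tributaries=pd.DataFrame(d["tributaries"]),
            speeds=pd.DataFrame(d["speeds"]),
            non_migrants={int(y): v for y, v in d["non_migrants"].items()},
        )


def _frame_to_records(frame: pd.DataFrame, ts_cols: Iterable[str]) -> list[dict]:
    out = frame.copy()
    for c in ts_cols:
        out[c] = out[c].map(lambda t: pd.Timestamp(t).isoformat())
    return json.loads(out.to_json(orient="records"))


def _first_crossing_index(window_means: np.ndarray, tau: float, rising: bool) -> int:
    hit = window_means >= tau if rising else window_means <= tau
    if not hit.any():
        return -1
    return int(np.argmax(hit))


def _cue_window_means(series: EnvSeries, lag_h: int, duration_h: int) -> tuple[np.ndarray, int]:
    """Mean of ``series`` over [t-lag, t-lag+duration) for every grid time t
    with full coverage; returns (means, index offset of the first valid t)."""
    per_h = int(round(60 / series.step_min))
    lag_n, dur_n = lag_h * per_h, duration_h * per_h
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    n = len(series)
    first_t = lag_n  # earliest event index with the window inside the series
    starts = np.arange(0, n - lag_n + 1)  # window start index for t = lag_n..n
    valid = starts[starts + dur_n <= n]
    means = (csum[valid + dur_n] - csum[valid]) / dur_n
    return means, first_t


def _nudge_clock(
    t_h: float,
    phase_h: float,
    kappa: float,
    floor_h: float,
    rng: np.random.Generator,
    ceil_h: float = np.inf,
) -> float:
    """Move an event to the drawn von Mises clock time on the same or an
    adjacent day, never leaving [floor_h, ceil_h]; ties resolved toward later."""
    theta = rng.vonmises(phase_h * 2 * np.pi / 24.0, kappa)
    clock = (theta % (2 * np.pi)) * 24.0 / (2 * np.pi)
    day0 = np.floor(t_h / 24.0)
    candidates = [(day0 + k) * 24.0 + clock for k in (-1, 0, 1)]
    valid = [c for c in candidates if floor_h <= c <= ceil_h]
    if not valid:
        return float(np.clip(t_h, floor_h, ceil_h))
    # closest to the original time; prefer the later one on a tie
    best = min(valid, key=lambda c: (abs(c - t_h), -c))
    return best


def simulate_detections(
    config: SimConfig,
    individuals: pd.DataFrame,
    cohort_truth: CohortTruth,
    env_by_year: Mapping[int, Mapping[str, EnvSeries]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit antenna detection events for every migrant in every season.

    Individuals whose threshold is never crossed within a season are flagged
    as non-migrants for that year and excluded (a warning reports the count).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))
    tribs = tributary_sites(config.n_tributaries)
    trib_km = dict(zip(tribs, config.tributary_km))
    weights = np.asarray(config.capacity_weights) / sum(config.capacity_weights)
    rising = config.cue_rising()

    det_rows: list[tuple] = []
    stage_rows: list[tuple] = []
    trib_rows: list[tuple] = []
    speed_rows: list[tuple] = []
    non_migrants: dict[int, list[str]] = {}

    for year in config.years:
        env = env_by_year[year]
        cue = env[config.cue_variable]
        start = cue.start
        means, first_t = _cue_window_means(cue, config.true_lag_h, config.true_duration_h)

        # -- cue-triggered tributary arrival (MS2), per individual ----------
        tags = individuals["tag_id"].to_numpy()
        sexes = individuals["sex"].to_numpy()
        ms2_h = np.full(len(tags), np.nan)
        for i, tag in enumerate(tags):
            tau_iy = cohort_truth.threshold[tag] + rng.normal(0.0, config.threshold_sd[sexes[i]])
            k = _first_crossing_index(means, tau_iy, rising)
            if k >= 0:
                ms2_h[i] = (first_t + k) * cue.step_h
        migrant = np.isfinite(ms2_h)
        non_migrants[year] = [t for t, m in zip(tags, migrant) if not m]

        # -- tributary choice in provisional MS1 order (social rule) --------
        up_speed = np.exp(
            np.array([rng.normal(config.travel_mu[s]["up"], config.travel_sigma[s]["up"])
                      for s in sexes])
        )
        down_speed = np.exp(
            np.array([rng.normal(config.travel_mu[s]["down"], config.travel_sigma[s]["down"])
                      for s in sexes])
        )
        # transit over the short gate<->tributary legs is behavior-dominated
        # (holding/staging), so travel time is drawn over the capacity-mean
        # tributary distance, independent of the specific tributary chosen;
        # this keeps gate-passage timing exchangeable w.r.t. tributary labels
        mean_trib_km = float(np.dot(weights, config.tributary_km))
        ms1_final = ms2_h - (mean_trib_km / up_speed) * 24.0
        if config.diel_nudge and config.diel_kappa > 0:
            for i in range(len(tags)):
                if migrant[i]:
                    ms1_final[i] = _nudge_clock(
                        ms1_final[i], config.diel_phase_h[sexes[i]]["up"],
                        config.diel_kappa, -np.inf, rng, ceil_h=ms2_h[i],
                    )
        order = np.argsort(ms1_final)
        chosen: dict[int, str] = {}
        assigned: list[int] = []  # indices already assigned, in passage order
        for i in order:
            if not migrant[i]:
                continue
            if rng.random() < config.fidelity_prob:
                chosen[i] = cohort_truth.home_tributary[tags[i]]
            else:
                w = weights.copy()
                nearest = None
                best_gap = np.inf
                for j in assigned:
                    if sexes[j] == sexes[i]:
                        gap = abs(ms1_final[i] - ms1_final[j])
                        if gap < best_gap:
                            best_gap, nearest = gap, j
                if nearest is not None and best_gap < 1.0 and config.social_alpha != 0.0:
                    w[tribs.index(chosen[nearest])] *= np.exp(config.social_alpha)
                chosen[i] = tribs[int(rng.choice(len(tribs), p=w / w.sum()))]
            assigned.append(i)

        # -- full stage-time trajectories and detection emission -------------
        for i, tag in enumerate(tags):
            if not migrant[i]:
                continue
            sex = sexes[i]
            first_trib = chosen[i]
            ms1 = ms1_final[i]
            residence = max(rng.normal(config.residence_mean[sex], config.residence_sd[sex]), 0.5)
            ms3 = ms2_h[i] + residence * 24.0

            multi = rng.random() < config.multi_tributary_prob
            if multi and config.n_tributaries > 1:
                others = [t for t in tribs if t != first_trib]
                last_trib = others[int(rng.choice(len(others)))]
            else:
                last_trib = first_trib
            ms4 = ms3 + (mean_trib_km / down_speed[i]) * 24.0

            ms2 = ms2_h[i]
            if config.diel_nudge and config.diel_kappa > 0:
                # MS2 is the cue-anchored event and keeps its crossing time;
                # the diel clock preference expresses in the mainstem
                # passages (MS1 nudged above) and the tributary departure
                ms3 = _nudge_clock(ms3, config.diel_phase_h[sex]["down"],
                                   config.diel_kappa, ms2, rng)
                ms4 = _nudge_clock(ms4, config.diel_phase_h[sex]["down"],
                                   config.diel_kappa, ms3, rng)

            stamps = {s: start + pd.Timedelta(hours=h)
                      for s, h in zip(STAGES, (ms1, ms2, ms3, ms4))}
            det_rows.append((tag, GATE_SITE, stamps["MS1"], "up"))
            det_rows.append((tag, first_trib, stamps["MS2"], "unknown"))
            if last_trib != first_trib:
                mid1 = ms2 + 0.4 * (ms3 - ms2)
                mid2 = ms2 + 0.5 * (ms3 - ms2)
                det_rows.append((tag, first_trib, start + pd.Timedelta(hours=mid1), "unknown"))
                det_rows.append((tag, last_trib, start + pd.Timedelta(hours=mid2), "unknown"))
            det_rows.append((tag, last_trib, stamps["MS3"], "unknown"))
            det_rows.append((tag, GATE_SITE, stamps["MS4"], "down"))

            for stage in STAGES:
                site = {"MS1": GATE_SITE, "MS2": first_trib,
                        "MS3": last_trib, "MS4": GATE_SITE}[stage]
                stage_rows.append((tag, year, stage, stamps[stage], site))
            trib_rows.append((tag, year, first_trib, last_trib, 2 if last_trib != first_trib else 1))
            # realized transit speeds over the actual detection legs; NaN if
            # diel nudging collapsed a leg to zero elapsed time
            up_el, down_el = (ms2 - ms1) / 24.0, (ms4 - ms3) / 24.0
            speed_rows.append((tag, year, "up",
                               trib_km[first_trib] / up_el if up_el > 0 else np.nan))
            speed_rows.append((tag, year, "down",
                               trib_km[last_trib] / down_el if down_el > 0 else np.nan))

    n_excluded = sum(len(v) for v in non_migrants.values())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} individual-season(s) never crossed their cue threshold; "
            "excluded as non-migrants",
            stacklevel=2,
        )

    detections = pd.DataFrame(det_rows, columns=["tag_id", "site_id", "timestamp", "direction"])
    detections = detections.sort_values(["timestamp", "tag_id"], kind="mergesort").reset_index(drop=True)
    truth = GroundTruth(
        true_lag_h=config.true_lag_h,
        true_duration_h=config.true_duration_h,
        cue_variable=config.cue_variable,
        social_alpha=config.social_alpha,
        threshold=dict(cohort_truth.threshold),
        home_tributary=dict(cohort_truth.home_tributary),
        stage_times=pd.DataFrame(
            stage_rows, columns=["tag_id", "year", "stage", "timestamp", "site_id"]
        ),
        tributaries=pd.DataFrame(
            trib_rows,
            columns=["tag_id", "year", "first_tributary", "last_tributary", "n_tributaries"],
        ),
        speeds=pd.DataFrame(speed_rows, columns=["tag_id", "year", "direction", "speed_km_day"]),
        non_migrants=non_migrants,
    )
    return detections, truth


# ---------------------------------------------------------------------------
# one-call simulation + disk output


@dataclass
class SimResult:
    config: SimConfig
    individuals: pd.DataFrame
    detections: pd.DataFrame
    env: dict[int, dict[str, EnvSeries]]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        """Write detections.csv, individuals.csv, env_<year>.csv, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        det = self.detections.copy()
        det["timestamp"] = det["timestamp"].map(pd.Timestamp.isoformat)
        det.to_csv(out / "detections.csv", index=False)
        self.individuals.to_csv(out / "individuals.csv", index=False)
        for year, series in self.env.items():
            frame = series["temperature"].to_frame().merge(
                series["level"].to_frame(), on="timestamp"
            )
            frame["timestamp"] = frame["timestamp"].map(pd.Timestamp.isoformat)
            frame.to_csv(out / f"env_{year}.csv", index=False)
        self.truth.to_json(out / "truth.json")


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator from a single RNG stream seeded by the config."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    env: dict[int, dict[str, EnvSeries]] = {}
    for year in config.years:
        temp, level = simulate_environment(config, year, rng=rng)
        env[year] = {"temperature": temp, "level": level}
    individuals, cohort_truth = simulate_cohort(config, rng=rng)
    detections, truth = simulate_detections(config, individuals, cohort_truth, env, rng=rng)
    return SimResult(config, individuals, detections, env, truth)
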