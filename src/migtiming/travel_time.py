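"""Swimming speeds from paired detections and lognormal travel-time inference.

Transit speeds are distances between the mainstem gate and tributary antennas
divided by the elapsed detection times, per individual and direction.
Upstream speeds are approximately lognormal, so the travel time over a longer
distance D (from the river mouth, where no antenna exists) is inferred two
ways, reported side by side:

* ``ratio_of_means`` — D divided by the arithmetic mean speed (a point
  estimate only);
* ``lognormal_quantile`` — T = D / V with V ~ Lognormal(mu, sigma) is itself
  lognormal with parameters (ln D - mu, sigma); the 95% interval is its
  2.5% and 97.5% quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_events import SiteRegistry

#: Default distance (rkm) from the river mouth to the average tributary site.
DEFAULT_DISTANCE_RKM = 24.2


def compute_speeds(
    events: pd.DataFrame,
    registry: SiteRegistry,
    year: int | None = None,
) -> pd.DataFrame:
    """Per-transit swimming speeds from stage events.

    Upstream: gate arrival (MS1) to tributary arrival (MS2); downstream:
    tributary departure (MS3) to gate passage (MS4).  Non-positive elapsed
    times are rejected with a warning.  Restrict to a single season (e.g.
    the no-handling year) via ``year``.
    """
    ev = events.copy()
    if year is not None:
        ev = ev[ev["year"] == year]
    wide_t = ev.pivot_table(index=["tag_id", "year"], columns="stage",
                            values="timestamp", aggfunc="first")
    wide_s = ev.pivot_table(index=["tag_id", "year"], columns="stage",
                            values="site_id", aggfunc="first")
    rows = []
    n_rejected = 0
    for key in wide_t.index:
        t = wide_t.loc[key]
        s = wide_s.loc[key]
        for direction, (s0, s1) in {"up": ("MS1", "MS2"), "down": ("MS3", "MS4")}.items():
            if pd.isna(t.get(s0)) or pd.isna(t.get(s1)):
                continue
            site_a, site_b = s.get(s0), s.get(s1)
            if pd.isna(site_a) or pd.isna(site_b):
                continue
            dist = registry.distance_km(str(site_a), str(site_b))
            elapsed = (t[s1] - t[s0]) / pd.Timedelta(days=1)
            if dist <= 0 or elapsed <= 0:
                n_rejected += 1
                continue
            rows.append(
                {
                    "tag_id": key[0],
                    "year": key[1],
                    "direction": direction,
                    "distance_km": dist,
                    "elapsed_days": elapsed,
                    "speed_km_day": dist / elapsed,
                }
            )
    if n_rejected:
        warnings.warn(f"{n_rejected} transit(s) with non-positive distance or elapsed "
                      "time rejected", stacklevel=2)
    return pd.DataFrame(rows, columns=["tag_id", "year", "direction", "distance_km",
                                       "elapsed_days", "speed_km_day"])


def per_individual_speeds(speeds: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Average transit speeds per individual (avoids pseudo-replication)."""
    sub = speeds[speeds["direction"] == direction]
    return sub.groupby("tag_id", as_index=False)["speed_km_day"].mean()


def fit_lognormal(speeds: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit: ``mu`` = mean of log speeds,
    ``sigma`` = ML (1/n) standard deviation of log speeds."""
    v = np.asarray(speeds, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 speeds")
    if np.any(v <= 0):
        raise ValueError("speeds must be positive for a lognormal fit")
    logs = np.log(v)
    return float(logs.mean()), float(logs.std(ddof=0))


@dataclass
class TravelTimeEstimate:
    distance_rkm: float
    mean_days: float
    ci_low_days: float | None
    ci_high_days: float | None
    method: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def travel_time(
    distance_rkm: float = DEFAULT_DISTANCE_RKM,
    speeds: np.ndarray | None = None,
    mu_sigma: tuple[float, float] | None = None,
    method: str = "ratio_of_means",
    ci: float = 0.95,
) -> TravelTimeEstimate:
    """Travel-time estimate over ``distance_rkm`` by either method."""
    if distance_rkm <= 0:
        raise ValueError("distance must be positive")
    if method == "ratio_of_means":
        if speeds is None:
            raise ValueError("ratio_of_means needs the raw speeds")
        v = np.asarray(speeds, dtype=float)
        return TravelTimeEstimate(distance_rkm, float(distance_rkm / v.mean()),
                                  None, None, method)
    if method == "lognormal_quantile":
        if mu_sigma is None:
            if speeds is None:
                raise ValueError("lognormal_quantile needs speeds or (mu, sigma)")
            mu_sigma = fit_lognormal(speeds)
        mu, sigma = mu_sigma
        log_t_mu = np.log(distance_rkm) - mu
        center = float(np.exp(log_t_mu))  # median travel time
        if sigma == 0:
            return TravelTimeEstimate(distance_rkm, center, center, center, method)
        alpha = (1 - ci) / 2
        qlo = float(stats.lognorm.ppf(alpha, s=sigma, scale=np.exp(log_t_mu)))
        qhi = float(stats.lognorm.ppf(1 - alpha, s=sigma, scale=np.exp(log_t_mu)))
        return TravelTimeEstimate(distance_rkm, center, qlo, qhi, method)
    raise ValueError(f"unknown method {method!r}")


def travel_time_report(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    registry: SiteRegistry,
    distance_rkm: float = DEFAULT_DISTANCE_RKM,
    year: int | None = None,
) -> dict:
    """Sex-level speed summaries plus both travel-time estimates."""
    ev = events.merge(individuals[["tag_id", "sex"]], on="tag_id", how="left") \
        if "sex" not in events.columns else events
    speeds = compute_speeds(ev, registry, year=year)
    speeds = speeds.merge(individuals[["tag_id", "sex"]], on="tag_id", how="left")
    out: dict = {"distance_rkm": distance_rkm, "year": year, "by_sex": {}}
    down_by_sex = {}
    for sex in ("F", "M"):
        sub = speeds[speeds["sex"] == sex]
        entry: dict = {}
        for direction in ("up", "down"):
            per_ind = per_individual_speeds(sub, direction)["speed_km_day"].to_numpy()
            if len(per_ind) == 0:
                continue
            entry[f"mean_speed_{direction}_km_day"] = float(per_ind.mean())
            entry[f"n_{direction}"] = int(len(per_ind))
            if direction == "down":
                down_by_sex[sex] = per_ind
            if direction == "up" and len(per_ind) >= 3:
                mu, sigma = fit_lognormal(per_ind)
                rom = travel_time(distance_rkm, speeds=per_ind, method="ratio_of_means")
                lnq = travel_time(distance_rkm, mu_sigma=(mu, sigma),
                                  method="lognormal_quantile")
                entry["travel_time"] = {
                    "ratio_of_means_days": rom.mean_days,
                    "lognormal_median_days": lnq.mean_days,
                    "ci_low_days": lnq.ci_low_days,
                    "ci_high_days": lnq.ci_high_days,
                    "mu": mu,
                    "sigma": sigma,
                }
        out["by_sex"][sex] = entry
    if all(len(down_by_sex.get(s, [])) >= 2 for s in ("F", "M")):
        from .social import downstream_speed_comparison

        t, p = downstream_speed_comparison(down_by_sex["F"], down_by_sex["M"])
        out["downstream_speed_t_test"] = {"t": t, "p": p}
    return out
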