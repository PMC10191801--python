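"""Detection-log I/O and migration-stage event derivation.

Raw antenna reads are reduced to four waypoint events per individual and
season:

* MS1 — first upstream read at the mainstem gate (arrival from the estuary),
* MS2 — first read at any tributary (arrival at the spawning grounds),
* MS3 — last read at any tributary (departure for the mainstem),
* MS4 — first downstream read at the gate after MS3 (departure seaward).

Per-season covariates ``First`` (identity of the first tributary entered) and
``Tributary`` (number of distinct tributaries entered) are derived alongside.
Seasonal timings are represented as fractional days since Jan 1 of the season
year; diel timings as clock-time mapped to an angle on the 24-h circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("MS1", "MS2", "MS3", "MS4")

#: Static daytime interval (half-open), the approximate civil-twilight span
#: at the run midpoint; day iff clock-time in [day_start, day_end).
DAY_START = "04:20"
DAY_END = "18:37"


@dataclass
class SiteRegistry:
    """Detection sites with river-kilometre positions.

    Exactly one site is the mainstem gate; the rest are tributary antennas,
    with ``river_km`` measured from the ocean along the channel.
    """

    frame: pd.DataFrame  # site_id, river_km, role

    def __post_init__(self) -> None:
        required = {"site_id", "river_km", "role"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"registry needs columns {sorted(required)}")
        if (self.frame["river_km"] <= 0).any():
            raise ValueError("river_km must be positive")
        gates = self.frame.loc[self.frame["role"] == "mainstem_gate", "site_id"]
        if len(gates) != 1:
            raise ValueError("registry must declare exactly one mainstem_gate")

    @property
    def gate(self) -> str:
        return str(self.frame.loc[self.frame["role"] == "mainstem_gate", "site_id"].iloc[0])

    @property
    def tributaries(self) -> list[str]:
        return list(self.frame.loc[self.frame["role"] == "tributary", "site_id"])

    def river_km(self, site_id: str) -> float:
        row = self.frame.loc[self.frame["site_id"] == site_id, "river_km"]
        if row.empty:
            raise KeyError(f"unknown site {site_id!r}")
        return float(row.iloc[0])

    def distance_km(self, a: str, b: str) -> float:
        return abs(self.river_km(a) - self.river_km(b))

    @classmethod
    def default(cls, gate_km: float = 22.0,
                tributary_km: tuple[float, ...] = (0.79, 1.70, 2.62, 3.53)) -> "SiteRegistry":
        rows = [("L", gate_km, "mainstem_gate")]
        rows += [(f"T{i + 1}", gate_km + d, "tributary") for i, d in enumerate(tributary_km)]
        return cls(pd.DataFrame(rows, columns=["site_id", "river_km", "role"]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SiteRegistry":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat-file I/O


def read_detections(path: str | Path) -> pd.DataFrame:
    det = pd.read_csv(path)
    det["timestamp"] = pd.to_datetime(det["timestamp"], format="ISO8601")
    return det


def write_detections(det: pd.DataFrame, path: str | Path) -> None:
    out = det.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(pd.Timestamp.isoformat)
    out.to_csv(path, index=False)


def read_stage_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    ev["timestamp"] = pd.to_datetime(ev["timestamp"], format="ISO8601")
    return ev


def write_stage_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(pd.Timestamp.isoformat)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# timing representations


def seasonal_days(ts: pd.Series | pd.Timestamp) -> pd.Series | float:
    """Fractional days since Jan 1 (00:00) of the timestamp's own year."""
    if isinstance(ts, pd.Timestamp):
        jan1 = pd.Timestamp(year=ts.year, month=1, day=1)
        return (ts - jan1) / pd.Timedelta(days=1)
    ts = pd.to_datetime(ts)
    jan1 = pd.to_datetime({"year": ts.dt.year, "month": 1, "day": 1})
    return (ts - jan1.values) / pd.Timedelta(days=1)


def diel_angle(ts: pd.Series | pd.Timestamp) -> pd.Series | float:
    """Clock time mapped to radians on [0, 2*pi): angle = 2*pi * t / 24 h."""
    if isinstance(ts, pd.Timestamp):
        frac = (ts - ts.normalize()) / pd.Timedelta(hours=24)
        return 2 * np.pi * frac
    ts = pd.to_datetime(ts)
    frac = (ts - ts.dt.normalize()) / pd.Timedelta(hours=24)
    return 2 * np.pi * frac


def _clock_minutes(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return int(h) * 60 + int(m)


def classify_day_night(
    ts: pd.Series | pd.Timestamp, day_start: str = DAY_START, day_end: str = DAY_END
):
    """Label timestamps day/night with a static half-open daytime interval."""
    lo, hi = _clock_minutes(day_start), _clock_minutes(day_end)
    if not lo < hi:
        raise ValueError("day_start must precede day_end")
    scalar = isinstance(ts, pd.Timestamp)
    s = pd.Series([ts]) if scalar else pd.to_datetime(ts)
    minutes = s.dt.hour * 60 + s.dt.minute + s.dt.second / 60.0
    lab = np.where((minutes >= lo) & (minutes < hi), "day", "night")
    return lab[0] if scalar else pd.Series(lab, index=s.index)


# ---------------------------------------------------------------------------
# stage derivation


def derive_stage_events(
    detections: pd.DataFrame,
    registry: SiteRegistry,
    day_start: str = DAY_START,
    day_end: str = DAY_END,
) -> pd.DataFrame:
    """Reduce raw detections to MS1-MS4 stage events per (tag, year).

    The season is the calendar year of each read.  Missing stages are simply
    absent (never imputed); a downstream read preceding any upstream read at
    the gate triggers a warning but the record is kept.  The result carries
    ``first_tributary`` (First) and ``n_tributaries`` (Tributary) covariates,
    plus seasonal-day, diel-angle and day/night annotations.
    """
    det = detections.copy()
    det["timestamp"] = pd.to_datetime(det["timestamp"])
    known = set(registry.frame["site_id"])
    bad = set(det["site_id"]) - known
    if bad:
        raise ValueError(f"detections reference unregistered sites: {sorted(bad)}")
    det = det.sort_values(["timestamp", "tag_id"], kind="mergesort")
    det["year"] = det["timestamp"].dt.year

    gate = registry.gate
    tribs = set(registry.tributaries)
    rows: list[dict] = []
    n_orphan_down = 0

    for (tag, year), grp in det.groupby(["tag_id", "year"], sort=True):
        at_gate = grp[grp["site_id"] == gate]
        ups = at_gate[at_gate["direction"] == "up"]
        downs = at_gate[at_gate["direction"] == "down"]
        at_trib = grp[grp["site_id"].isin(tribs)]

        ms1 = ups["timestamp"].iloc[0] if len(ups) else None
        if len(downs) and (ms1 is None or downs["timestamp"].iloc[0] < ms1):
            n_orphan_down += 1

        ms2 = ms3 = None
        first_trib = None
        n_trib = 0
        if len(at_trib):
            ms2 = at_trib["timestamp"].iloc[0]
            ms3 = at_trib["timestamp"].iloc[-1]
            first_trib = at_trib["site_id"].iloc[0]
            n_trib = at_trib["site_id"].nunique()

        ms4 = None
        if ms3 is not None:
            after = downs[downs["timestamp"] >= ms3]
            if len(after):
                ms4 = after["timestamp"].iloc[0]  # first excursion's exit kept
        elif len(downs):
            ms4 = downs["timestamp"].iloc[0]

        sites = {
            "MS1": gate,
            "MS2": first_trib,
            "MS3": at_trib["site_id"].iloc[-1] if len(at_trib) else None,
            "MS4": gate,
        }
        for stage, ts in zip(STAGES, (ms1, ms2, ms3, ms4)):
            if ts is None:
                continue
            rows.append(
                {
                    "tag_id": tag,
                    "year": int(year),
                    "stage": stage,
                    "timestamp": ts,
                    "site_id": sites[stage],
                    "first_tributary": first_trib,
                    "n_tributaries": n_trib,
                }
            )

    if n_orphan_down:
        warnings.warn(
            f"{n_orphan_down} (tag, year) group(s) show a downstream gate read "
            "before any upstream read; records kept",
            stacklevel=2,
        )

    events = pd.DataFrame(
        rows,
        columns=["tag_id", "year", "stage", "timestamp", "site_id",
                 "first_tributary", "n_tributaries"],
    )
    if len(events):
        events["seasonal_day"] = seasonal_days(events["timestamp"])
        events["diel_angle"] = diel_angle(events["timestamp"])
        events["day_night"] = classify_day_night(events["timestamp"], day_start, day_end)
    else:
        for c in ("seasonal_day", "diel_angle", "day_night"):
            events[c] = pd.Series(dtype=float if c != "day_night" else object)
    return events.reset_index(drop=True)


def standardize_seasonal(events: pd.DataFrame) -> pd.DataFrame:
    """Add ``seasonal_z``: timing standardized to mean 0, SD 1 (sample SD,
    n-1) within each (year, stage) group.

    Groups of size 1 get NaN and a warning: a z-score is undefined there.
    """
    out = events.copy()
    out["seasonal_z"] = np.nan
    singletons = 0
    for (_, _), grp in out.groupby(["year", "stage"], sort=False):
        if len(grp) < 2:
            singletons += len(grp)
            continue
        x = grp["seasonal_day"].to_numpy(dtype=float)
        out.loc[grp.index, "seasonal_z"] = (x - x.mean()) / x.std(ddof=1)
    if singletons:
        warnings.warn(
            f"{singletons} (year, stage) group(s) of size 1: seasonal_z undefined",
            stacklevel=2,
        )
    return out
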