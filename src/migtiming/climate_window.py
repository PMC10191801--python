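"""Individual-relative sliding-window scan for environmental cue windows.

For every candidate window — a (lag, duration) pair on a 4-h grid with
8 <= duration <= lag <= 240 h — the environmental variable is averaged over
``[event - lag, event - lag + duration)`` relative to each individual's
tributary-arrival time (MS2) in each of two seasons, and the two year-vectors
are correlated across individuals (Pearson).  The maximum correlation over
the grid (``r_obs``) identifies the critical time window; its significance
comes from a randomization test whose null statistic is itself a grid
maximum, so window multiplicity is accounted for by construction: each
iteration randomly re-pairs the year-2 individuals with the year-1
individuals and re-runs the full grid search.

Lag convention: ``lag`` measures from the event back to the *earlier* (i.e.
farther) edge of the window, so a window reported as "160-200 h before
arrival" is (lag=200, duration=40).  ``duration <= lag`` keeps every window
entirely before the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .envseries import EnvSeries
from .config import GRID_MAX_H, GRID_MIN_H, GRID_STEP_H

LAG_CONVENTION = "lag measured to the window's earlier (farther-from-event) edge"


def window_grid(
    min_h: int = GRID_MIN_H, max_h: int = GRID_MAX_H, step_h: int = GRID_STEP_H
) -> np.ndarray:
    """All (lag, duration) cells with min <= duration <= lag <= max on the step grid.

    Returns an integer array of shape (n_cells, 2) ordered by lag then duration.
    """
    cells = [
        (lag, dur)
        for lag in range(min_h, max_h + 1, step_h)
        for dur in range(min_h, lag + 1, step_h)
    ]
    return np.array(cells, dtype=int)


@dataclass
class Window:
    lag_h: int
    duration_h: int

    def __post_init__(self) -> None:
        if not (self.duration_h <= self.lag_h):
            raise ValueError("window must satisfy duration <= lag")


def window_mean(series: EnvSeries, event_time, w: Window | tuple[int, int]) -> float:
    """Mean of the series over the half-open window before one event.

    Raises if the series does not fully cover the window.
    """
    lag, dur = (w.lag_h, w.duration_h) if isinstance(w, Window) else w
    e_h = series.hours_since_start(pd.Timestamp(event_time))
    a = int(np.ceil((e_h - lag) / series.step_h - 1e-9))
    b = a + int(round(dur / series.step_h))
    if a < 0 or b > len(series):
        raise ValueError("series does not cover the requested window")
    return float(series.values[a:b].mean())


def _window_matrix(
    series: EnvSeries, event_times: pd.Series, grid: np.ndarray
) -> np.ndarray:
    """(n_individuals x n_cells) matrix of window means; NaN where uncovered."""
    per_h = 1.0 / series.step_h
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    n_samp = len(series)
    lags = grid[:, 0].astype(float)
    dur_n = np.round(grid[:, 1] * per_h).astype(int)
    out = np.full((len(event_times), len(grid)), np.nan)
    for i, ts in enumerate(event_times):
        e_h = series.hours_since_start(pd.Timestamp(ts))
        a = np.ceil((e_h - lags) * per_h - 1e-9).astype(int)
        b = a + dur_n
        ok = (a >= 0) & (b <= n_samp)
        if ok.any():
            out[i, ok] = (csum[b[ok]] - csum[a[ok]]) / dur_n[ok]
    return out


def _pearson_by_cell(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r between X and Y, dropping rows with missing
    coverage cell-wise; cells with n < 3 or zero variance are NaN."""
    M = np.isfinite(X) & np.isfinite(Y)
    Xz = np.where(M, X, 0.0)
    Yz = np.where(M, Y, 0.0)
    nc = M.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx, sy = Xz.sum(0), Yz.sum(0)
        sxx = (Xz * Xz).sum(0) - sx * sx / nc
        syy = (Yz * Yz).sum(0) - sy * sy / nc
        sxy = (Xz * Yz).sum(0) - sx * sy / nc
        r = sxy / np.sqrt(sxx * syy)
    bad = (nc < 3) | (sxx <= 1e-12) | (syy <= 1e-12)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r, nc


@dataclass
class WindowScanResult:
    variable: str
    grid: np.ndarray                    # (n_cells, 2) int lags/durations
    r: np.ndarray                       # per-cell Pearson r (NaN = undefined)
    n_per_cell: np.ndarray
    r_obs: float
    critical_windows: list[tuple[int, int]]  # all argmax cells (plateau-aware)
    n_individuals: int
    p: float | None = None
    n_iterations: int = 0
    r_sim: np.ndarray | None = None
    lag_convention: str = LAG_CONVENTION
    label: dict = field(default_factory=dict)

    @property
    def critical_window(self) -> tuple[int, int]:
        return self.critical_windows[0]

    def surface_frame(self) -> pd.DataFrame:
        """Long-form (lag_h, duration_h, r, n) table of the scan surface."""
        return pd.DataFrame(
            {
                "lag_h": self.grid[:, 0],
                "duration_h": self.grid[:, 1],
                "r": self.r,
                "n": self.n_per_cell.astype(int),
            }
        )

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "r_obs": self.r_obs,
            "critical_windows": [list(map(int, w)) for w in self.critical_windows],
            "p": self.p,
            "n_individuals": self.n_individuals,
            "n_iterations": self.n_iterations,
            "lag_convention": self.lag_convention,
            **self.label,
        }


def _paired_events(events: pd.DataFrame, years: tuple[int, int]) -> pd.DataFrame:
    ms2 = events[events["stage"] == "MS2"] if "stage" in events.columns else events
    wide = ms2.pivot_table(index="tag_id", columns="year", values="timestamp", aggfunc="first")
    missing = [y for y in years if y not in wide.columns]
    if missing:
        raise ValueError(f"no MS2 events for season(s) {missing}")
    return wide[list(years)].dropna()


def scan(
    series_by_year: Mapping[int, EnvSeries],
    events: pd.DataFrame,
    grid: np.ndarray | None = None,
    label: dict | None = None,
) -> WindowScanResult:
    """Run the full grid scan for one group (one sex, one variable).

    ``events`` holds the MS2 stage events (tag_id, year, timestamp) of
    individuals detected in both seasons; pre-filter by sex before calling.
    """
    years = tuple(sorted(series_by_year))
    if len(years) != 2:
        raise ValueError("scan requires exactly two seasons of environmental data")
    grid = window_grid() if grid is None else np.asarray(grid, dtype=int)
    paired = _paired_events(events, years)
    if len(paired) < 3:
        raise ValueError("need at least 3 individuals present in both seasons")
    X = _window_matrix(series_by_year[years[0]], paired[years[0]], grid)
    Y = _window_matrix(series_by_year[years[1]], paired[years[1]], grid)
    r, nc = _pearson_by_cell(X, Y)
    if np.all(np.isnan(r)):
        raise ValueError("no grid cell has enough covered individuals")
    r_obs = float(np.nanmax(r))
    crit = [tuple(map(int, grid[k])) for k in np.flatnonzero(r == r_obs)]
    return WindowScanResult(
        variable=series_by_year[years[0]].variable,
        grid=grid,
        r=r,
        n_per_cell=nc,
        r_obs=r_obs,
        critical_windows=crit,
        n_individuals=len(paired),
        label=label or {},
    )


def randomization_test(
    series_by_year: Mapping[int, EnvSeries],
    events: pd.DataFrame,
    n_iter: int = 999,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
    label: dict | None = None,
) -> WindowScanResult:
    """Grid scan plus its one-sided randomization p-value.

    Each iteration permutes which year-2 individual is paired with each
    year-1 individual (uniform permutation, identity included), re-runs the
    full grid search and records the simulated maximum ``r_sim``;
    ``p = (1 + #{r_sim >= r_obs}) / (1 + n_iter)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    years = tuple(sorted(series_by_year))
    grid = window_grid() if grid is None else np.asarray(grid, dtype=int)
    result = scan(series_by_year, events, grid=grid, label=label)
    paired = _paired_events(events, years)
    X = _window_matrix(series_by_year[years[0]], paired[years[0]], grid)
    Y = _window_matrix(series_by_year[years[1]], paired[years[1]], grid)
    n = X.shape[0]
    r_sim = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(n)
        r, _ = _pearson_by_cell(X, Y[perm])
        r_sim[it] = np.nanmax(r) if not np.all(np.isnan(r)) else -np.inf
    result.p = float((1 + np.sum(r_sim >= result.r_obs)) / (1 + n_iter))
    result.n_iterations = n_iter
    result.r_sim = r_sim
    return result


def scan_by_sex_and_variable(
    env_by_year: Mapping[int, Mapping[str, EnvSeries]],
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    variables: tuple[str, ...] = ("temperature", "level"),
    n_iter: int = 999,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
) -> list[WindowScanResult]:
    """Convenience driver: one randomization scan per (sex, variable)."""
    rng = np.random.default_rng(rng)
    ev = events.merge(individuals[["tag_id", "sex"]], on="tag_id", how="left") \
        if "sex" not in events.columns else events
    out = []
    for sex in ("F", "M"):
        sub = ev[(ev["sex"] == sex) & (ev["stage"] == "MS2")]
        for var in variables:
            series = {y: env_by_year[y][var] for y in env_by_year}
            try:
                res = randomization_test(series, sub, n_iter=n_iter, rng=rng, grid=grid,
                                         label={"sex": sex})
            except ValueError:
                continue
            out.append(res)
    return out
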