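"""Between-year repeatability of migration timing and circular diel statistics.

Repeatability is measured as Spearman's rank correlation between the two
seasons' timings of the same individuals, on the seasonal scale (date and
time, as fractional days) and on the diel scale (clock time only), separately
by sex and migration stage.  Within-season consistency is the MS1-vs-MS4
correlation in one year.  Diel timing distributions are tested for
non-uniformity with the Rayleigh test and compared between groups with the
Watson-Wheeler uniform-scores test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("MS1", "MS2", "MS3", "MS4")


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float | None
    sex: str
    stage: str
    scale: str      # "seasonal" | "diel"
    pairing: str    # "between_years" | "MS1_vs_MS4"


@dataclass
class RayleighResult:
    rbar: float
    z: float
    p: float
    n: int


@dataclass
class WatsonWheelerResult:
    w: float
    p: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# rank correlations


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float | None]:
    n = len(x)
    if n < 3:
        rho = stats.spearmanr(x, y).statistic if n == 2 else np.nan
        return float(rho), None
    res = stats.spearmanr(x, y)  # average ranks for ties; t-approximation p
    return float(res.statistic), float(res.pvalue)


def spearman_by_group(
    events: pd.DataFrame,
    pairing: str = "between_years",
    scale: str = "seasonal",
    individuals: pd.DataFrame | None = None,
    years: tuple[int, int] | None = None,
    circular_diel: bool = False,
) -> list[CorrelationResult]:
    """Spearman rank correlations per (sex, stage).

    ``pairing="between_years"`` correlates each individual's timing in the
    first season against the second; ``pairing="MS1_vs_MS4"`` correlates
    arrival against departure timing within the later season.  Only
    individuals with both members of the pair are used.  The diel scale uses
    clock time treated linearly (day boundary at midnight) by default;
    ``circular_diel=True`` switches to a circular rank correlation
    (Pearson on ranked angles mapped back to the circle).
    """
    if scale not in ("seasonal", "diel"):
        raise ValueError("scale must be 'seasonal' or 'diel'")
    ev = events.copy()
    if individuals is not None:
        ev = ev.merge(individuals[["tag_id", "sex"]], on="tag_id", how="left")
    if "sex" not in ev.columns:
        raise ValueError("events need a 'sex' column (or pass `individuals`)")
    value_col = "seasonal_day" if scale == "seasonal" else "diel_angle"
    if scale == "diel":
        ev = ev.assign(_value=ev["diel_angle"] * 24.0 / (2 * np.pi))
    else:
        ev = ev.assign(_value=ev[value_col])

    results: list[CorrelationResult] = []
    if pairing == "between_years":
        ys = years or tuple(sorted(ev["year"].unique())[:2])
        if len(ys) < 2:
            raise ValueError("between_years pairing needs two seasons")
        for sex in ("F", "M"):
            for stage in STAGES:
                sub = ev[(ev["sex"] == sex) & (ev["stage"] == stage)]
                wide = sub.pivot_table(index="tag_id", columns="year", values="_value").dropna()
                if ys[0] not in wide.columns or ys[1] not in wide.columns:
                    continue
                x, y = wide[ys[0]].to_numpy(), wide[ys[1]].to_numpy()
                rho, p = _corr(x, y, circular_diel and scale == "diel")
                results.append(CorrelationResult(rho, len(wide), p, sex, stage, scale,
                                                 "between_years"))
    elif pairing == "MS1_vs_MS4":
        year = (years or (None, int(ev["year"].max())))[1]
        sub = ev[ev["year"] == year]
        for sex in ("F", "M"):
            s = sub[sub["sex"] == sex]
            wide = s.pivot_table(index="tag_id", columns="stage", values="_value")
            if "MS1" not in wide.columns or "MS4" not in wide.columns:
                continue
            wide = wide[["MS1", "MS4"]].dropna()
            rho, p = _corr(wide["MS1"].to_numpy(), wide["MS4"].to_numpy(),
                           circular_diel and scale == "diel")
            results.append(CorrelationResult(rho, len(wide), p, sex, "MS1-MS4", scale,
                                             "MS1_vs_MS4"))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    return results


def _corr(x: np.ndarray, y: np.ndarray, circular: bool) -> tuple[float, float | None]:
    if len(x) == 0:
        return np.nan, None
    if not circular:
        return _spearman(x, y)
    # circular rank correlation: map average ranks to uniform scores and
    # correlate the resultant of the angle differences/sums
    n = len(x)
    if n < 3:
        return np.nan, None
    a = 2 * np.pi * stats.rankdata(x) / n
    b = 2 * np.pi * stats.rankdata(y) / n
    t_plus = np.abs(np.mean(np.exp(1j * (a - b))))
    t_minus = np.abs(np.mean(np.exp(1j * (a + b))))
    rho = float(t_plus**2 - t_minus**2)
    return rho, None  # no standard closed-form p; permutation left to callers


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# circular tests


def circular_sample(angles: np.ndarray) -> np.ndarray:
    a = np.asarray(angles, dtype=float) % (2 * np.pi)
    if a.ndim != 1:
        raise ValueError("angles must be 1-d")
    return a


def rayleigh_test(angles: np.ndarray) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Rbar is the mean resultant length, Z = n * Rbar**2, and the p-value uses
    the standard series approximation
    ``p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``
    clipped to [0, 1].
    """
    a = circular_sample(angles)
    n = len(a)
    if n < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    rbar = float(np.abs(np.mean(np.exp(1j * a))))
    z = n * rbar**2
    p = np.exp(-z) * (
        1 + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return RayleighResult(rbar=rbar, z=float(z), p=float(np.clip(p, 0.0, 1.0)), n=n)


def watson_wheeler_test(a: np.ndarray, b: np.ndarray) -> WatsonWheelerResult:
    """Watson-Wheeler (Mardia) two-sample uniform-scores test.

    The pooled sample is ranked (average ranks on ties), ranks are mapped to
    uniform scores ``gamma = 2*pi*rank/N``, and
    ``W = 2 * sum_g (C_g^2 + S_g^2) / n_g`` with C, S the per-group cosine and
    sine sums of the scores; p from chi-square with 2 df.
    """
    a = circular_sample(a)
    b = circular_sample(b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    gamma = 2 * np.pi * stats.rankdata(pooled) / len(pooled)
    w = 0.0
    for g in (gamma[: len(a)], gamma[len(a):]):
        w += (np.cos(g).sum() ** 2 + np.sin(g).sum() ** 2) / len(g)
    w *= 2.0
    p = float(stats.chi2.sf(w, df=2))
    return WatsonWheelerResult(w=float(w), p=p, n_a=len(a), n_b=len(b))
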