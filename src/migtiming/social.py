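"""Comigrant-pair permutation test for conspecific attraction or repulsion.

Two same-sex individuals passing the mainstem gate within one hour of each
other are *comigrants*.  The test asks whether comigrating pairs end up in
the same spawning tributary more (attraction) or less (repulsion) often than
random assignment predicts: the observed count of tributary-sharing pairs
(``n_obs``) is compared against counts from random re-assignments of the
fixed tributary-label multiset over the migrants, which preserves both the
passage timings and each tributary's total occupancy.  The p-value is
two-sided (doubled smaller tail, +1 corrected, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComigrantPair:
    tag_a: str
    tag_b: str
    gap_h: float
    sex: str


@dataclass
class SocialTestResult:
    stage: str
    sex: str
    n_pairs: int
    n_obs: int
    sim_mean: float
    sim_sd: float
    p: float
    n_iterations: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def find_comigrant_pairs(
    passages: pd.DataFrame, threshold_h: float = 1.0, chained: bool = False
) -> list[ComigrantPair]:
    """All unordered same-sex pairs whose gate passages are < threshold apart.

    ``passages`` needs columns tag_id, sex, timestamp.  The criterion is
    pairwise, not transitive: A-B and B-C within an hour does not imply A-C.
    With ``chained=True`` individuals are first linked into chains of
    successive sub-threshold gaps and every within-chain same-sex pair counts.
    """
    df = passages.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"])
    hours = (ts - ts.iloc[0]) / pd.Timedelta(hours=1) if len(ts) else pd.Series(dtype=float)
    pairs: list[ComigrantPair] = []
    n = len(df)
    if chained:
        # split at gaps >= threshold, then take all same-sex pairs per chain
        breaks = np.flatnonzero(np.diff(hours.to_numpy()) >= threshold_h) + 1
        for chunk in np.split(np.arange(n), breaks):
            for ii in range(len(chunk)):
                for jj in range(ii + 1, len(chunk)):
                    i, j = chunk[ii], chunk[jj]
                    if df["sex"].iloc[i] == df["sex"].iloc[j]:
                        pairs.append(
                            ComigrantPair(df["tag_id"].iloc[i], df["tag_id"].iloc[j],
                                          float(hours.iloc[j] - hours.iloc[i]),
                                          df["sex"].iloc[i])
                        )
        return pairs
    for i in range(n):
        for j in range(i + 1, n):
            gap = float(hours.iloc[j] - hours.iloc[i])
            if gap >= threshold_h:
                break
            if df["sex"].iloc[i] == df["sex"].iloc[j]:
                pairs.append(
                    ComigrantPair(df["tag_id"].iloc[i], df["tag_id"].iloc[j], gap,
                                  df["sex"].iloc[i])
                )
    return pairs


def count_shared(pairs: list[ComigrantPair], tributary_of: dict[str, str]) -> int:
    """Number of comigrating pairs whose two members have the same tributary."""
    n = 0
    for p in pairs:
        if p.tag_a not in tributary_of or p.tag_b not in tributary_of:
            raise KeyError(f"pair ({p.tag_a}, {p.tag_b}) has an unmapped tag")
        n += tributary_of[p.tag_a] == tributary_of[p.tag_b]
    return n


def permutation_test(
    pairs: list[ComigrantPair],
    tributary_of: dict[str, str],
    migrants: list[str],
    n_iter: int = 9999,
    rng: np.random.Generator | int | None = None,
    stage: str = "MS1",
    sex: str = "",
) -> SocialTestResult:
    """Randomize tributary assignments and compare the observed sharing count.

    ``migrants`` lists every individual of the analyzed sex/stage (paired or
    not); their tributary labels form the multiset that is uniformly permuted
    each iteration, preserving each tributary's total occupancy.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng)
    labels = np.array([tributary_of[m] for m in migrants])
    index = {m: k for k, m in enumerate(migrants)}
    ia = np.array([index[p.tag_a] for p in pairs], dtype=int)
    ib = np.array([index[p.tag_b] for p in pairs], dtype=int)
    n_obs = count_shared(pairs, tributary_of)

    if len(set(labels)) <= 1:
        warnings.warn("single tributary: sharing distribution is degenerate; p = 1",
                      stacklevel=2)
        return SocialTestResult(stage, sex, len(pairs), n_obs, float(len(pairs)), 0.0,
                                1.0, n_iter)

    n_sim = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        lab = labels[rng.permutation(len(labels))]
        n_sim[it] = int(np.sum(lab[ia] == lab[ib])) if len(ia) else 0
    lo = (1 + np.sum(n_sim <= n_obs)) / (1 + n_iter)
    hi = (1 + np.sum(n_sim >= n_obs)) / (1 + n_iter)
    p = min(1.0, 2.0 * min(lo, hi))
    return SocialTestResult(
        stage=stage,
        sex=sex,
        n_pairs=len(pairs),
        n_obs=n_obs,
        sim_mean=float(n_sim.mean()),
        sim_sd=float(n_sim.std(ddof=1)) if n_iter > 1 else 0.0,
        p=float(p),
        n_iterations=n_iter,
    )


def social_test(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    stage: str = "MS1",
    sex: str = "F",
    year: int | None = None,
    threshold_h: float = 1.0,
    n_iter: int = 9999,
    rng: np.random.Generator | int | None = None,
    chained: bool = False,
) -> SocialTestResult:
    """End-to-end test for one (stage, sex): find pairs, map tributaries, permute.

    For the ascent analysis (MS1) the tributary is the first one entered; for
    the descent analysis (MS4) it is the last one departed.  Tributary totals
    are those of the analyzed sex only.
    """
    if stage not in ("MS1", "MS4"):
        raise ValueError("social test is defined for gate passages (MS1 or MS4)")
    ev = events.merge(individuals[["tag_id", "sex"]], on="tag_id", how="left") \
        if "sex" not in events.columns else events
    if year is None:
        year = int(ev["year"].max())
    sub = ev[(ev["year"] == year) & (ev["sex"] == sex)]
    gate = sub[sub["stage"] == stage][["tag_id", "sex", "timestamp"]]

    trib_col = "first_tributary" if stage == "MS1" else "site_id"
    if stage == "MS1":
        tribs = sub[sub["stage"] == "MS2"].set_index("tag_id")["first_tributary"]
    else:
        tribs = sub[sub["stage"] == "MS3"].set_index("tag_id")["site_id"]
    tributary_of = tribs.dropna().to_dict()

    gate = gate[gate["tag_id"].isin(tributary_of)]
    pairs = find_comigrant_pairs(gate, threshold_h=threshold_h, chained=chained)
    migrants = list(gate["tag_id"])
    return permutation_test(pairs, tributary_of, migrants, n_iter=n_iter, rng=rng,
                            stage=stage, sex=sex)


def exhaustive_sharing_distribution(
    pairs: list[tuple[int, int]], labels: list[str]
) -> dict[int, float]:
    """Exact distribution of the sharing count over all distinct label
    assignments (for small instances; used as an oracle)."""
    from sympy.utilities.iterables import multiset_permutations

    counts: dict[int, int] = {}
    total = 0
    for perm in multiset_permutations(labels):
        c = sum(perm[a] == perm[b] for a, b in pairs)
        counts[c] = counts.get(c, 0) + 1
        total += 1
    return {k: v / total for k, v in sorted(counts.items())}


def downstream_speed_comparison(
    speeds_f: np.ndarray, speeds_m: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t-test on per-individual mean speeds (F vs M)."""
    a = np.asarray(speeds_f, dtype=float)
    b = np.asarray(speeds_m, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 speeds per sex")
    if (a.std(ddof=1) == 0 and len(a) == 2) or (b.std(ddof=1) == 0 and len(b) == 2):
        warnings.warn("zero-variance group with n=2; t-test at its degenerate limit",
                      stacklevel=2)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
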