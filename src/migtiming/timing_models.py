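"""Mixed-effects models of standardized seasonal migration timing.

For each migration stage the response is the season-and-stage standardized
timing (``seasonal_z``), with individual identity as a random intercept so the
two seasons of one fish share a latent timing tendency.  Candidate fixed
effects: Sex, standardized fork length (FL), day/night of the event (DN),
first tributary entered (First, a multi-level factor tested as a block), and
number of tributaries entered (Tributary), plus all Sex interactions.  Model
selection is sequential backward elimination of the least significant
removable term, never violating marginality (a main effect is removable only
once no retained interaction contains it), with maximum likelihood during
elimination and REML for the reported fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import LMMFit, fit_lmm

#: Estimated annual somatic growth rate used to standardize fork lengths
#: measured in earlier seasons to a common measurement year (mm per year).
GROWTH_RATE_MM_PER_YEAR = 24.7

MAIN_TERMS = ("Sex", "FL", "DN", "First", "Tributary")
INTERACTIONS = ("Sex:FL", "Sex:DN", "Sex:First", "Sex:Tributary")


def adjust_fork_length(fl_mm: float | np.ndarray, years_offset: float | np.ndarray):
    """Standardize a fork length to a later measurement year by adding the
    annual growth increment: ``fl + 24.7 * years_offset``."""
    years_offset = np.asarray(years_offset, dtype=float)
    if np.any(years_offset < 0):
        raise ValueError("years_offset must be non-negative")
    return fl_mm + GROWTH_RATE_MM_PER_YEAR * years_offset


def build_model_frame(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    stage: str,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Assemble one row per (individual, season) for a single stage.

    Fork lengths are growth-adjusted to ``reference_year`` (default: the last
    tagging year present) and z-scored across the cohort.
    """
    ev = events[events["stage"] == stage]
    if "seasonal_z" not in ev.columns:
        raise ValueError("events must be standardized first (run standardize_seasonal)")
    cols = ["tag_id", "fork_length_mm", "year_tagged"]
    if "sex" not in ev.columns:
        cols.insert(1, "sex")
    frame = ev.merge(individuals[cols], on="tag_id", how="inner")
    ref = reference_year if reference_year is not None else int(frame["year_tagged"].max())
    offs = (ref - frame["year_tagged"]).clip(lower=0)
    fl_adj = adjust_fork_length(frame["fork_length_mm"].to_numpy(), offs.to_numpy())
    frame = frame.assign(fl_adjusted=fl_adj)
    frame["fl_std"] = (frame["fl_adjusted"] - frame["fl_adjusted"].mean()) / frame[
        "fl_adjusted"
    ].std(ddof=1)
    keep = ["tag_id", "year", "seasonal_z", "sex", "fl_std", "day_night",
            "first_tributary", "n_tributaries"]
    return frame[keep].dropna(subset=["seasonal_z"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# design construction


def _design(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Full-model design matrix and the term -> column mapping."""
    n = len(frame)
    X = pd.DataFrame({"Intercept": np.ones(n)})
    terms: dict[str, list[str]] = {}

    sex_m = (frame["sex"] == "M").astype(float)
    X["Sex[M]"] = sex_m
    terms["Sex"] = ["Sex[M]"]

    X["FL"] = frame["fl_std"].to_numpy(dtype=float)
    terms["FL"] = ["FL"]

    X["DN[night]"] = (frame["day_night"] == "night").astype(float)
    terms["DN"] = ["DN[night]"]

    levels = sorted(frame["first_tributary"].dropna().unique())
    first_cols = []
    for lev in levels[1:]:
        col = f"First[{lev}]"
        X[col] = (frame["first_tributary"] == lev).astype(float)
        first_cols.append(col)
    terms["First"] = first_cols

    X["Tributary"] = frame["n_tributaries"].to_numpy(dtype=float)
    terms["Tributary"] = ["Tributary"]

    for main in ("FL", "DN", "First", "Tributary"):
        cols = []
        for c in terms[main]:
            col = f"Sex[M]:{c}"
            X[col] = sex_m * X[c]
            cols.append(col)
        terms[f"Sex:{main}"] = cols
    return X, terms


def _prune_degenerate(
    X: pd.DataFrame, terms: dict[str, list[str]], trace: list[dict]
) -> dict[str, list[str]]:
    """Remove candidate terms whose columns are constant or collinear."""
    active = dict(terms)
    order = list(MAIN_TERMS) + list(INTERACTIONS)
    kept_cols = ["Intercept"]
    result: dict[str, list[str]] = {}
    for term in order:
        cols = [c for c in active.get(term, []) if X[c].nunique() > 1]
        if not cols:
            trace.append({"term": term, "action": "excluded", "reason": "degenerate", "p": None})
            continue
        trial = kept_cols + cols
        if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
            trace.append({"term": term, "action": "excluded", "reason": "collinear", "p": None})
            continue
        kept_cols = trial
        result[term] = cols
    return result


# ---------------------------------------------------------------------------
# elimination


@dataclass
class TimingFitResult:
    stage: str
    table: pd.DataFrame              # retained fixed effects with inference
    retained_terms: list[str]
    elimination_trace: list[dict]
    fit: LMMFit
    alpha: float

    def summary(self) -> str:
        lines = [f"stage {self.stage}: retained {', '.join(self.retained_terms) or '(intercept only)'}"]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def _removable(active: dict[str, list[str]]) -> list[str]:
    out = []
    for term in active:
        if ":" in term:
            out.append(term)
        else:
            if not any(term in ia.split(":") for ia in active if ":" in ia):
                out.append(term)
    return out


def _term_p(fit: LMMFit, cols: list[str]) -> float:
    if len(cols) == 1:
        return float(fit.pvalues[cols[0]])
    return fit.wald_f(cols)[3]


def _fit_active(
    frame: pd.DataFrame, X: pd.DataFrame, active: dict[str, list[str]], reml: bool
) -> LMMFit:
    cols = ["Intercept"] + [c for t in active.values() for c in t]
    # keep original column order for readability
    cols = [c for c in X.columns if c in cols]
    return fit_lmm(frame["seasonal_z"], X[cols], frame["tag_id"], reml=reml)


def backward_eliminate(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    stage: str,
    alpha: float = 0.05,
    reference_year: int | None = None,
) -> TimingFitResult:
    """Select and report the timing model for one stage.

    Repeatedly refits the model (ML) and drops the removable term with the
    largest p-value until every removable term is significant at ``alpha``;
    the final model is refit with REML.  Multi-column factors are tested and
    dropped as a block via a Wald F-test.
    """
    frame = build_model_frame(events, individuals, stage, reference_year)
    return backward_eliminate_frame(frame, alpha=alpha, stage=stage)


def _assert_marginality(trace: list[dict], terms: dict[str, list[str]]) -> None:
    """A main effect may never be dropped while one of its interactions was
    still in the model at that point; checked on every elimination trace."""
    dropped: list[str] = []
    all_terms = set(terms)
    for step in trace:
        if step["action"] != "dropped":
            continue
        term = step["term"]
        if ":" not in term:
            remaining_interactions = {
                t for t in all_terms
                if ":" in t and t not in dropped and term in t.split(":")
            }
            # interactions excluded as degenerate were never in the model
            remaining_interactions -= {
                s["term"] for s in trace if s["action"] == "excluded"
            }
            if remaining_interactions:
                raise AssertionError(
                    f"marginality violated: {term} dropped before {remaining_interactions}"
                )
        dropped.append(term)


def simulate_timing_frame(
    n_per_sex: int = 120,
    n_years: int = 2,
    sex_effect: float = -0.9,
    effects: dict[str, float] | None = None,
    sd_individual: float = 0.5,
    sd_resid: float = 0.4,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Direct model-frame simulator for exercising the elimination machinery.

    Builds a balanced (individual x season) frame on the standardized-timing
    scale with a known male-minus-female shift (``sex_effect``, in SD units),
    optional additional effects keyed by design column name (e.g. ``"DN[night]"``
    or ``"Sex[M]:FL"``), an individual random intercept and iid noise; all
    unlisted candidate terms are truly null.
    """
    rng = np.random.default_rng(rng)
    n = 2 * n_per_sex
    tags = [f"S{i:04d}" for i in range(n)]
    sex = np.array(["F"] * n_per_sex + ["M"] * n_per_sex)
    fl = rng.normal(0, 1, n)
    b = rng.normal(0, sd_individual, n)
    rows = []
    for year in range(n_years):
        dn = rng.random(n) < 0.4
        first = rng.choice(["T1", "T2", "T3", "T4"], size=n)
        ntrib = 1 + (rng.random(n) < 0.15)
        rows.append(pd.DataFrame({
            "tag_id": tags, "year": 2018 + year, "sex": sex, "fl_std": fl,
            "day_night": np.where(dn, "night", "day"), "first_tributary": first,
            "n_tributaries": ntrib.astype(int),
        }))
    frame = pd.concat(rows, ignore_index=True)
    X, terms = _design(frame)
    y = sex_effect * X["Sex[M]"].to_numpy()
    for col, beta in (effects or {}).items():
        y = y + beta * X[col].to_numpy()
    codes = pd.factorize(frame["tag_id"])[0]
    y = y + b[codes] + rng.normal(0, sd_resid, len(frame))
    frame["seasonal_z"] = y
    return frame


def backward_eliminate_frame(
    frame: pd.DataFrame, alpha: float = 0.05, stage: str = "synthetic"
) -> TimingFitResult:
    """Run the elimination procedure on a ready-made model frame."""
    X, terms = _design(frame)
    trace: list[dict] = []
    active = _prune_degenerate(X, terms, trace)
    while True:
        fit = _fit_active(frame, X, active, reml=False)
        candidates = _removable(active)
        if not candidates:
            break
        pvals = {t: _term_p(fit, active[t]) for t in candidates}
        worst = max(pvals, key=lambda t: pvals[t])
        if pvals[worst] < alpha:
            break
        trace.append({"term": worst, "action": "dropped", "reason": "p>=alpha",
                      "p": float(pvals[worst])})
        del active[worst]
        if not active:
            break
    _assert_marginality(trace, terms)
    final = _fit_active(frame, X, active, reml=True)
    table = pd.DataFrame(
        {
            "term": final.params.index,
            "estimate": final.params.to_numpy(),
            "se": final.se.to_numpy(),
            "df": final.df.to_numpy(),
            "t": final.tvalues.to_numpy(),
            "p": final.pvalues.to_numpy(),
        }
    )
    return TimingFitResult(stage=stage, table=table, retained_terms=list(active),
                           elimination_trace=trace, fit=final, alpha=alpha)


def fit_all_stages(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, TimingFitResult]:
    return {
        stage: backward_eliminate(events, individuals, stage, alpha=alpha)
        for stage in ("MS1", "MS2", "MS3", "MS4")
    }
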