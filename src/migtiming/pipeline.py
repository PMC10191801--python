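"""One-command orchestration: simulate -> derive events -> every analysis.

``run_all`` chains the synthetic generator (or user-supplied input files),
stage-event derivation, repeatability and circular statistics, timing models,
the environmental window scan, the social-interaction test and travel-time
estimation into a single seeded, reproducible report bundle: JSON results per
module, CSV tables (scan surfaces, repeatability, model tables) and a
markdown report, plus a provenance block (config hash, seeds, versions).
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io_events import SiteRegistry, derive_stage_events, standardize_seasonal
from .repeatability import (rayleigh_test, results_frame, spearman_by_group,
                            watson_wheeler_test)
from .climate_window import scan_by_sex_and_variable
from .social import social_test
from .synthetic import simulate
from .timing_models import fit_all_stages
from .travel_time import travel_time_report


def _provenance(config: RunConfig) -> dict:
    import scipy

    return {
        "migtiming": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "config_hash": config.config_hash(),
        "sim_seed": config.sim.seed,
        "window_seed": config.window_seed,
        "social_seed": config.social_seed,
    }


def run_all(config: RunConfig) -> dict:
    """Run the configured pipeline end to end and write the report bundle.

    Returns the full result dictionary (also written to results.json).
    Identical configs yield byte-identical results.json.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)

    try:
        return _run_all_inner(config, out)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise


def _run_all_inner(config: RunConfig, out: Path) -> dict:
    results: dict = {"provenance": _provenance(config)}

    sim = simulate(config.sim)
    sim.write(out / "data")
    results["simulation"] = {
        "n_individuals": int(len(sim.individuals)),
        "n_detections": int(len(sim.detections)),
        "n_non_migrant_seasons": sim.truth.n_non_migrants(),
        "years": list(config.sim.years),
    }

    registry = SiteRegistry.default(config.sim.mouth_to_gate_km, config.sim.tributary_km)
    registry.to_csv(out / "data" / "sites.csv")
    events = derive_stage_events(sim.detections, registry,
                                 day_start=config.day_start, day_end=config.day_end)
    events = standardize_seasonal(events)
    ev = events.merge(sim.individuals[["tag_id", "sex"]], on="tag_id", how="left")
    ev.to_csv(out / "events.csv", index=False)

    if config.run_repeatability:
        rows = []
        for scale in ("seasonal", "diel"):
            rows += spearman_by_group(ev, "between_years", scale)
        rows += spearman_by_group(ev, "MS1_vs_MS4", "seasonal")
        rep = results_frame(rows)
        rep.to_csv(out / "repeatability.csv", index=False)
        results["repeatability"] = json.loads(rep.to_json(orient="records"))

        year = int(ev["year"].max())
        circ: dict = {}
        for sex in ("F", "M"):
            for stage in ("MS1", "MS4"):
                ang = ev[(ev["sex"] == sex) & (ev["stage"] == stage)
                         & (ev["year"] == year)]["diel_angle"].to_numpy()
                if len(ang) >= 4:
                    r = rayleigh_test(ang)
                    circ[f"rayleigh_{sex}_{stage}"] = dataclasses.asdict(r)
        for sex in ("F", "M"):
            a = ev[(ev["sex"] == sex) & (ev["stage"] == "MS1") & (ev["year"] == year)]
            b = ev[(ev["sex"] == sex) & (ev["stage"] == "MS4") & (ev["year"] == year)]
            if len(a) >= 2 and len(b) >= 2:
                r = watson_wheeler_test(a["diel_angle"].to_numpy(), b["diel_angle"].to_numpy())
                circ[f"watson_wheeler_{sex}_ascent_vs_descent"] = dataclasses.asdict(r)
        for stage in ("MS1", "MS4"):
            a = ev[(ev["sex"] == "F") & (ev["stage"] == stage) & (ev["year"] == year)]
            b = ev[(ev["sex"] == "M") & (ev["stage"] == stage) & (ev["year"] == year)]
            if len(a) >= 2 and len(b) >= 2:
                r = watson_wheeler_test(a["diel_angle"].to_numpy(), b["diel_angle"].to_numpy())
                circ[f"watson_wheeler_{stage}_F_vs_M"] = dataclasses.asdict(r)
        results["circular"] = circ

    if config.run_timing_models:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_all_stages(ev, sim.individuals, alpha=config.alpha)
        tables = []
        model_results = {}
        for stage, fit in fits.items():
            tbl = fit.table.assign(stage=stage)
            tables.append(tbl)
            model_results[stage] = {
                "retained_terms": fit.retained_terms,
                "elimination_trace": fit.elimination_trace,
                "table": json.loads(fit.table.to_json(orient="records")),
            }
        pd.concat(tables).to_csv(out / "timing_models.csv", index=False)
        results["timing_models"] = model_results

    if config.run_window_scan:
        scans = scan_by_sex_and_variable(
            sim.env, ev, sim.individuals, n_iter=config.window_iterations,
            rng=np.random.default_rng(config.window_seed),
        )
        results["window_scan"] = [s.to_dict() for s in scans]
        for s in scans:
            tag = f"{s.label.get('sex', 'all')}_{s.variable}"
            s.surface_frame().to_csv(out / f"scan_surface_{tag}.csv", index=False)

    if config.run_social_test:
        rng = np.random.default_rng(config.social_seed)
        social = []
        for stage in ("MS1", "MS4"):
            for sex in ("F", "M"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r = social_test(ev, sim.individuals, stage=stage, sex=sex,
                                        n_iter=config.social_iterations, rng=rng)
                except ValueError:
                    continue
                social.append(r.to_dict())
        results["social"] = social
        pd.DataFrame(social).to_csv(out / "social_tests.csv", index=False)

    if config.run_travel_time:
        year = int(ev["year"].max())
        results["travel_time"] = travel_time_report(
            ev, sim.individuals, registry, year=year
        )

    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    (out / "report.md").write_text(_render_report(results))
    config.to_yaml(out / "config.yaml")
    return results


def _render_report(results: dict) -> str:
    lines = ["# Migration-timing pipeline report", ""]
    prov = results["provenance"]
    lines += [f"- migtiming {prov['migtiming']} (config {prov['config_hash']})",
              f"- seeds: sim={prov['sim_seed']} window={prov['window_seed']} "
              f"social={prov['social_seed']}", ""]
    sim = results["simulation"]
    lines += ["## Simulation",
              f"{sim['n_individuals']} individuals over seasons {sim['years']}; "
              f"{sim['n_detections']} detections; "
              f"{sim['n_non_migrant_seasons']} non-migrant season(s).", ""]
    if "repeatability" in results:
        lines += ["## Between-year repeatability (Spearman rho)", ""]
        for row in results["repeatability"]:
            p = "n/a" if row["p"] is None else f"{row['p']:.3g}"
            lines.append(f"- {row['sex']} {row['stage']} [{row['scale']}, {row['pairing']}]: "
                         f"rho={row['rho']:.3f} (n={row['n']}, p={p})")
        lines.append("")
    if "window_scan" in results:
        lines += ["## Environmental cue windows", ""]
        for s in results["window_scan"]:
            w = s["critical_windows"][0]
            lines.append(
                f"- {s.get('sex', '?')} {s['variable']}: r_obs={s['r_obs']:.3f}, "
                f"critical window lag {w[0]} h / duration {w[1]} h "
                f"(i.e. {w[0] - w[1]}-{w[0]} h before arrival), p={s['p']:.3g}"
            )
        lines.append("")
    if "social" in results:
        lines += ["## Social-interaction tests", ""]
        for r in results["social"]:
            lines.append(
                f"- {r['stage']} {r['sex']}: {r['n_pairs']} comigrating pairs, "
                f"{r['n_obs']} shared a tributary (simulated "
                f"{r['sim_mean']:.1f} +/- {r['sim_sd']:.1f}), p={r['p']:.3g}"
            )
        lines.append("")
    if "travel_time" in results:
        tt = results["travel_time"]
        lines += ["## Travel time from the river mouth", ""]
        for sex, entry in tt["by_sex"].items():
            if "travel_time" in entry:
                t = entry["travel_time"]
                lines.append(
                    f"- {sex}: mean upstream speed "
                    f"{entry['mean_speed_up_km_day']:.2f} km/day -> "
                    f"{t['ratio_of_means_days']:.1f} days over {tt['distance_rkm']} rkm "
                    f"(lognormal 95% CI {t['ci_low_days']:.1f}-{t['ci_high_days']:.1f})"
                )
        lines.append("")
    return "\n".join(lines)
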