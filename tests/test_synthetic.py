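"""Generator: environmental dynamics, cohort structure, detection mechanics."""

import numpy as np
import pandas as pd
import pytest

from migtiming import SimConfig, simulate, simulate_cohort, simulate_environment
from migtiming.synthetic import _rain_pulse_times, simulate_detections


def stage_wide(truth):
    st = truth.stage_times.copy()
    return st.pivot_table(index=["tag_id", "year"], columns="stage", values="timestamp",
                          aggfunc="first")


class TestEnvironment:
    def test_noise_free_daily_means_follow_trend_exactly(self, noise_free_config):
        temp, _ = simulate_environment(noise_free_config, 2018)
        daily = temp.to_frame().set_index("timestamp")["temperature_c"].resample("D").mean()
        steps = np.diff(daily.to_numpy())
        assert np.allclose(steps, noise_free_config.temp_trend, atol=1e-12)

    def test_rainless_level_is_linear_baseline(self, noise_free_config):
        _, level = simulate_environment(noise_free_config, 2018)
        h = np.arange(len(level)) / 6.0
        expected = noise_free_config.level_base - noise_free_config.level_decline * h / 24.0
        assert np.allclose(level.values, expected, atol=1e-12)

    def test_pulse_count_matches_poisson_rate(self):
        # 10_000 replicate days against the Poisson oracle: the empirical
        # pulse rate must fall within 3 SE of the configured rate
        rate, n_days = 0.35, 10_000
        times = _rain_pulse_times(np.random.default_rng(123), n_days, rate)
        se = np.sqrt(rate / n_days)
        assert abs(len(times) / n_days - rate) < 3 * se

    def test_rejects_non_positive_season(self):
        with pytest.raises(ValueError):
            SimConfig(season_days=0)

    def test_level_floored_at_zero(self):
        cfg = SimConfig(seed=2, level_base=0.05, level_decline=0.05)
        _, level = simulate_environment(cfg, 2018)
        assert (level.values >= 0).all()


class TestCohort:
    def test_zero_individual_sd_gives_equal_thresholds_per_sex(self):
        cfg = SimConfig(seed=1, threshold_individual_sd=0.0)
        ind, truth = simulate_cohort(cfg)
        for sex in ("F", "M"):
            taus = [truth.threshold[t] for t in ind[ind.sex == sex].tag_id]
            assert np.allclose(taus, taus[0])
            assert taus[0] == cfg.threshold_mean[sex]

    def test_fixed_seed_reproduces_cohort(self):
        a, ta = simulate_cohort(SimConfig(seed=9))
        b, tb = simulate_cohort(SimConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        assert ta.threshold == tb.threshold and ta.home_tributary == tb.home_tributary

    def test_threshold_sd_recovered_at_large_n(self):
        cfg = SimConfig(seed=4, n_females=5000, n_males=5000, threshold_individual_sd=1.3)
        ind, truth = simulate_cohort(cfg)
        taus = np.array([truth.threshold[t] for t in ind[ind.sex == "F"].tag_id])
        assert abs(taus.std(ddof=1) / 1.3 - 1) < 0.02


class TestDetections:
    def test_noise_free_stage_gaps_equal_configured_means(self, noise_free_config):
        cfg = noise_free_config
        sim = simulate(cfg)
        wide = stage_wide(sim.truth)
        weights = np.asarray(cfg.capacity_weights) / sum(cfg.capacity_weights)
        mean_trib = float(np.dot(weights, cfg.tributary_km))
        for sex in ("F", "M"):
            tags = sim.individuals[sim.individuals.sex == sex].tag_id
            sub = wide.loc[[(t, 2018) for t in tags]]
            up_days = (sub["MS2"] - sub["MS1"]) / pd.Timedelta(days=1)
            res_days = (sub["MS3"] - sub["MS2"]) / pd.Timedelta(days=1)
            down_days = (sub["MS4"] - sub["MS3"]) / pd.Timedelta(days=1)
            assert np.allclose(up_days, mean_trib / np.exp(cfg.travel_mu[sex]["up"]), atol=1e-6)
            assert np.allclose(res_days, cfg.residence_mean[sex], atol=1e-6)
            assert np.allclose(down_days, mean_trib / np.exp(cfg.travel_mu[sex]["down"]),
                               atol=1e-6)

    def test_degenerate_thresholds_collapse_arrival_times(self, noise_free_config):
        # no individual variation + identical environments in both seasons:
        # every same-sex individual shares a single MS2 (hence MS1) time per year
        cfg = noise_free_config
        temp, level = simulate_environment(cfg, 2018)
        env = {y: {"temperature": temp, "level": level} for y in cfg.years}
        ind, ct = simulate_cohort(cfg)
        det, truth = simulate_detections(cfg, ind, ct, env)
        wide = stage_wide(truth).reset_index().merge(ind[["tag_id", "sex"]], on="tag_id")
        for (sex, year), grp in wide.groupby(["sex", "year"]):
            assert grp["MS2"].nunique() == 1
            assert grp["MS1"].nunique() == 1

    def test_stage_ordering_always_holds(self):
        wide = stage_wide(simulate(SimConfig(seed=21)).truth)
        assert (wide["MS1"] <= wide["MS2"]).all()
        assert (wide["MS2"] <= wide["MS3"]).all()
        assert (wide["MS3"] <= wide["MS4"]).all()

    def test_non_migrants_flagged_and_excluded(self):
        cfg = SimConfig(seed=3, n_females=5, n_males=5,
                        threshold_mean={"F": 50.0, "M": 8.5})  # F never crossed
        with pytest.warns(UserWarning, match="non-migrant"):
            sim = simulate(cfg)
        assert len(sim.truth.non_migrants[2018]) == 5
        f_tags = set(sim.individuals[sim.individuals.sex == "F"].tag_id)
        assert not (set(sim.detections.tag_id) & f_tags)

    def test_simulation_is_deterministic(self):
        a = simulate(SimConfig(seed=77))
        b = simulate(SimConfig(seed=77))
        pd.testing.assert_frame_equal(a.detections, b.detections)

    def test_truth_roundtrips_through_json(self, tmp_path, default_sim):
        from migtiming import GroundTruth

        path = tmp_path / "truth.json"
        default_sim.truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.threshold == pytest.approx(default_sim.truth.threshold)
        assert back.true_lag_h == default_sim.truth.true_lag_h
        pd.testing.assert_frame_equal(
            back.stage_times.sort_values(["tag_id", "year", "stage"]).reset_index(drop=True),
            default_sim.truth.stage_times.sort_values(
                ["tag_id", "year", "stage"]).reset_index(drop=True),
            check_dtype=False,
        )


class TestRepeatabilityStructure:
    def test_rank_correlation_tends_to_one_as_noise_vanishes(self, noise_free_config):
        # identical environments + persistent thresholds + no travel noise
        from scipy.stats import spearmanr

        cfg = noise_free_config
        cfg.threshold_individual_sd = 1.0
        temp, level = simulate_environment(cfg, 2018)
        env = {y: {"temperature": temp, "level": level} for y in cfg.years}
        ind, ct = simulate_cohort(cfg)
        det, truth = simulate_detections(cfg, ind, ct, env)
        wide = stage_wide(truth)["MS1"].unstack()
        rho = spearmanr(wide[2018], wide[2019]).statistic
        assert rho > 0.9999

    def test_repeatability_non_increasing_in_travel_noise(self):
        from scipy.stats import spearmanr

        mean_rho = []
        for sig in (0.0, 0.6, 1.2):
            rhos = []
            for seed in range(6):
                cfg = SimConfig(
                    seed=seed, n_females=40, n_males=5,
                    travel_sigma={"F": {"up": sig, "down": sig},
                                  "M": {"up": sig, "down": sig}},
                )
                truth = simulate(cfg).truth
                wide = stage_wide(truth)["MS1"].unstack().dropna()
                rhos.append(spearmanr(wide[2018], wide[2019]).statistic)
            mean_rho.append(np.mean(rhos))
        assert mean_rho[0] >= mean_rho[1] >= mean_rho[2]
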