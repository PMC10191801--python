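import warnings

import pytest

from migtiming import SimConfig, SiteRegistry, derive_stage_events, simulate, standardize_seasonal


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic dataset shared across read-only tests."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_registry():
    cfg = SimConfig()
    return SiteRegistry.default(cfg.mouth_to_gate_km, cfg.tributary_km)


@pytest.fixture(scope="session")
def default_events(default_sim, default_registry):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ev = derive_stage_events(default_sim.detections, default_registry)
        ev = standardize_seasonal(ev)
    return ev.merge(default_sim.individuals[["tag_id", "sex"]], on="tag_id")


@pytest.fixture()
def noise_free_config():
    """Config with every stochastic spread closed (deterministic limits)."""
    zero = {"F": {"up": 0.0, "down": 0.0}, "M": {"up": 0.0, "down": 0.0}}
    return SimConfig(
        seed=5,
        temp_noise_sd=0.0,
        temp_diel_amplitude=0.0,
        temp_weather_sd=0.0,
        level_noise_sd=0.0,
        rain_rate=0.0,
        threshold_sd={"F": 0.0, "M": 0.0},
        threshold_individual_sd=0.0,
        travel_sigma=zero,
        residence_sd={"F": 0.0, "M": 0.0},
        multi_tributary_prob=0.0,
        diel_nudge=False,
    )
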