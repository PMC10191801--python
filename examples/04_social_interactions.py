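"""Test whether comigrating fish choose the same spawning tributary.

Two same-sex individuals passing the gate within an hour are 'comigrants'.
If fish navigate socially, comigrating pairs should share a tributary more
often than random assignment (preserving each tributary's total occupancy)
predicts; repulsion would show fewer shared pairs.  Here we compare a
neutral cohort against one with strong injected attraction.
"""

import warnings

from migtiming import SimConfig, SiteRegistry, derive_stage_events, simulate, social_test

warnings.filterwarnings("ignore", category=UserWarning)


def run(social_alpha, fidelity, label):
    cfg = SimConfig(seed=43, social_alpha=social_alpha, fidelity_prob=fidelity)
    sim = simulate(cfg)
    events = derive_stage_events(sim.detections, SiteRegistry.default())
    events = events.merge(sim.individuals[["tag_id", "sex"]], on="tag_id")
    res = social_test(events, sim.individuals, stage="MS1", sex="F",
                      n_iter=9999, rng=11)
    print(f"{label}:")
    print(f"  {res.n_pairs} comigrating female pairs; {res.n_obs} entered the same "
          f"tributary (expected {res.sim_mean:.1f} +/- {res.sim_sd:.1f} by chance)")
    print(f"  two-sided p = {res.p:.3g}")


run(0.0, 0.85, "neutral cohort (site fidelity only)")
run(2.0, 0.0, "attraction injected (follow the nearest comigrant, odds x e^2)")
# In the neutral cohort the observed count sits inside the permutation
# distribution; with attraction it falls far in the upper tail.
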