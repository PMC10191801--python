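# migtiming

Individual-level analysis of spawning-migration timing from PIT-telemetry
detection logs — built for movement ecologists studying iteroparous fish
(salmonids in particular) that return to the same river in consecutive
seasons, but applicable to any system where tagged individuals pass fixed
waypoint antennas in more than one season.

The package answers three questions about a two-season detection dataset:

1. **Is migration timing an individual trait?**  Each fish's passage times
   are reduced to four waypoint stages per season — arrival at a mainstem
   gate (MS1), arrival at a spawning tributary (MS2), departure from the
   last tributary (MS3), and seaward passage of the gate (MS4) — and
   between-year repeatability is measured as Spearman's ρ between the two
   seasons' timings of the same individuals, on the seasonal scale (date and
   time) and the diel scale (clock time), per sex and stage.  Diel timing
   distributions get the Rayleigh uniformity test
   (Z = nR̄², with the standard series p-approximation) and between-group
   comparisons use the Watson–Wheeler uniform-scores test
   (W = 2·Σ_g (C_g² + S_g²)/n_g, p from χ²₂).

2. **Does an environmental cue explain the timing?**  An individual-relative
   sliding-window scan: for every (lag, duration) window on a 4-h grid with
   8 h ≤ duration ≤ lag ≤ 240 h (1770 cells), the environmental variable
   (water temperature or level, logged every 10 min) is averaged over
   [t − lag, t − lag + duration) before each individual's tributary arrival
   in each season, and the two year-vectors are Pearson-correlated across
   individuals.  The grid maximum r_obs identifies the critical time
   window; its one-sided p comes from a randomization test whose null
   statistic is itself a grid maximum (year-2 individuals are re-paired at
   random and the full scan re-run), so the 1770-fold multiplicity is
   handled by construction: p = (1 + #{r_sim ≥ r_obs}) / (1 + n_iter).

3. **Or do fish follow each other?**  Same-sex individuals passing the gate
   within 1 h are *comigrants*.  The observed number of comigrating pairs
   sharing a tributary (n_obs) is compared against random re-assignments of
   the fixed tributary-occupancy multiset (n_sim, 9999 iterations;
   two-sided p by doubling the smaller +1-corrected tail) — conspecific
   attraction shows as an excess, repulsion as a deficit.

Around these sit a linear mixed-model analysis of standardized seasonal
timing (individual identity as random intercept; Sex, fork length, day/night,
first tributary, tributary count and all Sex interactions as candidates;
sequential backward elimination at α = .05 with Satterthwaite degrees of
freedom) and lognormal travel-time estimation from transit speeds
(T = D/V with V ~ Lognormal(μ, σ)).

Because the field data are not bundled, a first-class **synthetic generator**
(`migtiming.synthetic`) produces detection logs, covariates and environmental
series with known ground truth: persistent individual cue thresholds create
repeatability, a configurable true cue window drives tributary arrival,
tributary fidelity and an optional social-coupling parameter drive tributary
choice, and sex-specific lognormal speeds and von Mises diel preferences
shape the event times.  Every downstream method is validated against this
known truth.

## Worked example

```sh
python examples/03_cue_window_scan.py
```

```
scanned 1770 windows over 67 females
r_obs = 0.984 at lag 200 h / duration 40 h
  i.e. the 160-200 h interval before arrival
randomization p = 0.005  (199 iterations)
truth injected by the generator: lag 200 h / duration 40 h
```

A cohort of 67 females was simulated with a true temperature cue window
160–200 h (6.7–8.3 days) before tributary arrival.  The scan recovers
exactly that window: the between-year correlation of the experienced
temperature peaks at r = 0.98 in the true cell, and no random re-pairing of
individuals produced a grid maximum as large (p = 1/200 at 199 iterations).
The other examples (`examples/01...06`) walk through simulation,
repeatability, the social test, travel times and the timing models the same
way; `migtiming run-all --out demo/` chains everything into one seeded
report bundle.

## Library or command line

The importable API is the primary interface (see `examples/`); a thin
`migtiming` CLI wraps it with subcommands `simulate`, `derive-events`,
`repeatability`, `fit-timing`, `window-scan`, `social-test`, `travel-time`
and `run-all`, each a direct call into one library function.

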