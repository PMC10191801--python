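# Methods

This note documents the models and procedures implemented in `migtiming`,
the design choices made where the design was genuinely open, and what the
synthetic generator does and does not emulate.

## Stage events and timing scales

Raw antenna reads collapse to four waypoint events per individual and
season: MS1 = first upstream read at the mainstem gate, MS2 = first read at
any tributary, MS3 = last read at any tributary, MS4 = first downstream gate
read after MS3.  A fish that re-ascends after its seaward passage keeps its
first MS4 (one spawning excursion per season).  Missing stages stay missing;
nothing is imputed.  Two covariates are derived per season: the first
tributary entered (a factor) and the number of distinct tributaries entered.

Seasonal timing is represented as fractional days since Jan 1 of the season
year; diel timing as the clock time mapped to an angle, 2π·t/24 h.  Day
versus night uses a single static half-open interval [04:20, 18:37) — a
fixed civil-twilight span at the run midpoint rather than a per-date
ephemeris, because the analyses treat day/night as a binary covariate, not
an astronomical quantity.  The half-open convention makes the boundary
unambiguous (18:37 exactly is night).

For modelling, timing is standardized to mean 0, SD 1 (sample SD, n−1)
within each (year, stage) group, so stages and seasons are comparable and
coefficients read in within-season standard deviations.

## Repeatability and circular statistics

Between-year repeatability is Spearman's ρ over individuals present in both
seasons, computed with average ranks on ties and the t-approximation for the
two-sided p (reported only for n ≥ 3).  The diel-scale correlation treats
clock time linearly with the day boundary at midnight; a circular rank
correlation (Fisher–Lee type, on uniform scores of the ranked angles) is
exposed as an option but is not the default, because events here cluster
away from midnight and the linear treatment is the simpler, more common
report.  The within-season consistency check correlates MS1 against MS4 in
the later season.

The Rayleigh test uses R̄ (mean resultant length), Z = nR̄², and the
standard series approximation
p ≈ exp(−Z)[1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)],
clipped to [0, 1]; it requires n ≥ 4.  The Watson–Wheeler two-sample test
ranks the pooled sample (average ranks on ties), maps ranks to uniform
scores γ = 2π·rank/N, computes W = 2·Σ_g (C_g² + S_g²)/n_g from each
group's cosine/sine score sums, and takes p from χ² with 2 df.  W is
exactly invariant to a common rotation of all angles (a rotation shifts the
uniform scores cyclically, which preserves each group's resultant).  Tests
verify the χ²₂ p against the exhaustive permutation distribution at n = 6+6
and the implementation against an independent uniform-scores formulation.

## Timing models

For each stage separately, standardized timing is modelled as a linear mixed
model with an individual-identity random intercept (the two seasons of one
fish share a latent tendency) and candidate fixed effects Sex, standardized
fork length, day/night, first tributary, tributary count, and all Sex
interactions.  Fork lengths measured in earlier years are first brought to
the common measurement year by adding 24.7 mm per year of offset (an
estimated annual growth rate for adults of this species), then z-scored.

Model selection is sequential backward elimination: refit, drop the
removable term with the largest p if p ≥ α = .05, repeat.  Interactions are
always removable; a main effect becomes removable only when no retained
interaction contains it (marginality, asserted on every elimination trace).
Multi-level factors are tested and dropped as a block with a Wald F-test
whose denominator df is the smallest Satterthwaite df in the block.
Maximum likelihood is used during elimination, REML for the final reported
fit — the standard practice when comparing fixed-effect structures.

The likelihood engine is written for the one-random-intercept case, where
(I + λJ)⁻¹ and log-determinants have closed per-group forms and the scale
profiles out, leaving a 1-D search in λ = σ²_b/σ²_e (grid plus bounded
refinement, with the λ = 0 boundary checked explicitly).  Per-coefficient
degrees of freedom follow Satterthwaite's approximation,
df = 2f²/(gᵀAg) with f = cᵀCov(β̂)c, g its gradient in (σ²_b, σ²_e), and A
the inverse observed REML information, both by central finite differences
(relative step 10⁻⁴).  On a frozen 40-individual test dataset the engine
reproduces lme4/lmerTest estimates, standard errors and Satterthwaite df to
three decimals, and it matches statsmodels' MixedLM likelihood on random
datasets.  A λ estimate at the zero boundary triggers an explicit OLS
fallback with residual df and a warning.

First and Tributary are offered as candidates at every stage, including
MS1, even though they describe tributary use that postdates gate arrival;
they are defined per season, and leaving the candidate set identical across
stages keeps the elimination tables comparable.

## The sliding-window cue scan

Grid: lags and durations from 8 to 240 h in 4-h steps with
duration ≤ lag — 1770 cells.  **Lag convention:** lag measures from the
event back to the window's *earlier* (farther) edge, so "160–200 h before
arrival" is the cell (lag 200, duration 40); the duration ≤ lag constraint
keeps every window strictly before the event.  The convention is recorded in
every result object.

Window means use the half-open interval [t − lag, t − lag + duration) on
the 10-min logger grid; an individual without full coverage for a cell is
dropped from that cell only, and cells with fewer than 3 individuals or a
zero-variance year-vector are undefined and excluded from the maximum.
When several cells tie for the maximum, the full argmax set is reported
(window ranges, not a single cell).

The randomization test permutes which year-2 individual is paired with each
year-1 individual — a uniform permutation, identity included, permutation
without replacement — and re-runs the entire grid search per iteration,
recording the simulated maximum.  p = (1 + #{r_sim ≥ r_obs})/(1 + n_iter),
one-sided, so the smallest attainable p at 999 iterations is 0.001.
Because the null statistic is the grid maximum, the test is calibrated
jointly over all 1770 windows; the suite verifies that p is uniform under
independence (KS over 200 replicates) and that the family-wise type-I rate
is at most nominal.

## The comigrant social test

Comigrants are same-sex pairs passing the gate within < 1 h, counted
pairwise (A–B and B–C within the hour does not imply A–C); a chained
variant is available but not default, since pair counts are the reported
unit.  For the ascent analysis each migrant's tributary is the first one
entered; for the descent analysis, the last one departed.  Each permutation
re-deals the observed tributary-label multiset uniformly over the migrants
of the analyzed sex, preserving passage times and each tributary's total
occupancy; the two-sided p doubles the smaller +1-corrected tail and is
capped at 1.  Tributary totals are sex-specific (each sex's test conditions
on its own occupancy vector); a sex-pooled mode exists for sensitivity
checks.  The sampler's n_sim distribution is verified against exhaustive
enumeration of all distinct label assignments for instances with ≤ 8
migrants.

## Travel time

Transit speeds divide gate–tributary river distances by detection-time
differences, one observation per transit, averaged within individuals
before any sex-level summary (avoiding pseudo-replication).  Upstream
speeds are treated as lognormal: μ̂ is the mean of log speeds, σ̂ the ML
(1/n) standard deviation.  The travel time over a distance D is reported
two ways, side by side and labelled: `ratio_of_means` = D / (arithmetic
mean speed), a point estimate; and `lognormal_quantile`, where
T = D/V ~ Lognormal(ln D − μ, σ), reporting the median and the 2.5%/97.5%
quantiles.  The two are kept separate because the ratio-of-means figure and
the lognormal interval answer different questions (a mean crossing time
versus the population spread of crossing times), and mixing them silently
would misstate both.  The default distance is 24.2 rkm, the river-mouth to
mean-tributary distance of the study system, overridable everywhere.

## The synthetic generator

The generator emulates the study system's structure — a 75-day spring
season from mid-April, a gate antenna 22 rkm from the ocean, four
tributaries 0.79–3.53 rkm above it, a cohort of 67 females and 56 males
with fork lengths ~N(772, 92²) and ~N(720, 139²) mm — with these
mechanisms:

* **Environment.**  Temperature = 6 °C + 0.2 °C/day trend + 1.5 °C diel
  cosine (peak 15:00) + an Ornstein–Uhlenbeck "weather" component
  (SD 1.0 °C, correlation time 12 h) + iid noise (SD 0.3 °C); daily means
  rise monotonically in expectation.  Water level = 1.2 m baseline falling
  0.01 m/day + Poisson rain pulses (0.35/day, 0.25 m, exponential decay
  0.04 h⁻¹) + noise, floored at 0.  The weather term is what makes the
  window scan identifiable: a purely deterministic series is the same in
  both seasons, so every window would be a monotone transform of every
  other and the correlation surface would be flat.  Its 12-h correlation
  time sets the sharpness of the recovered window; smoother weather widens
  the ridge.
* **Cue mechanism.**  Each individual carries a persistent threshold
  τᵢ = sex mean + N(0, 1.0 °C) plus a transient per-season deviation
  N(0, 0.15 °C).  It arrives at its tributary (MS2) at the first 10-min
  grid time whose cue average over the true window (default lag 200 h,
  duration 40 h) crosses τᵢ — evaluated on the logger grid with no
  interpolation, first grid time wins.  The persistent/transient split is
  what tunes repeatability.  A threshold never crossed within the season
  makes that individual a non-migrant for the year: excluded, counted,
  warned about.  The cue anchors **tributary arrival** (the event the scan
  is referenced to); gate arrival and river-mouth departure are derived
  backwards by subtracting lognormal travel times.  Sex-specific threshold
  means (F 9.5 °C, M 8.5 °C on a rising cue) produce protandry.
* **Travel, residence, diel preference.**  log-speeds are normal per sex
  and direction (defaults exp(μ): F 1.98/5.68, M 2.90/2.63 km/day up/down,
  σ = 0.5); residence at the tributary is normal (F 12 ± 3, M 16 ± 3 days,
  floored at 0.5).  Transit times over the short gate↔tributary legs are
  drawn over the capacity-mean tributary distance, independent of the
  specific tributary chosen: transit at this scale is holding-dominated,
  and this keeps gate-passage timing exchangeable with respect to tributary
  labels, which is exactly the null the social test assumes.  Event clock
  times for MS1, MS3 and MS4 are nudged to a von Mises draw around the
  sex/direction phase (κ = 2) on the same or an adjacent day, never
  violating stage ordering (ties resolve later); MS2 keeps its crossing
  time, since nudging the cue-anchored event would decouple it from the cue
  that generated it.
* **Tributary choice.**  Home tributary with probability 0.85 (high site
  fidelity), otherwise a capacity-weighted draw in which the nearest
  same-sex comigrant's tributary has its odds multiplied by
  exp(social_alpha); α = 0 is independence, α > 0 attraction, α < 0
  repulsion.  A second tributary is visited with probability 0.15.
* One RNG stream per simulation, seeded from the config, drives every draw:
  identical configs are bit-reproducible.

What the generator does **not** emulate: antenna inefficiency and missed
reads, duplicate detections, hydrological realism beyond the pulse-decay
sketch, within-tributary behaviour, mortality, and more than two seasons.
Passing tests therefore demonstrate that the estimators recover the
mechanisms they target under clean detection at realistic sample sizes —
not robustness to detection failure or model misspecification.

## Numerical and procedural choices

* Threshold crossing, window means and scan cells all use the half-open
  interval convention and the raw 10-min grid.
* The scan drops individuals cell-wise on missing coverage rather than
  globally, preserving n where the data allow.
* The social test's two-sided p doubles the smaller tail with the +1
  correction and caps at 1, so a degenerate single-tributary instance
  reports exactly p = 1.
* The mixed-model sex-recovery experiment simulates the model frame
  directly (240 individuals × 2 seasons, −0.9 SD male shift, individual SD
  0.5, residual SD 0.4, all other candidate effects zero) rather than
  running the full detection pipeline, because it tests the elimination
  machinery, not the generator.
* Validation problem sizes: 50-seed ensembles for window recovery and
  effect recovery, 200 replicates for calibration checks, 199 randomization
  iterations in ensemble runs (999/9999 remain the single-run defaults).
* Pipeline outputs are JSON/CSV plus a markdown report; identical run
  configurations produce byte-identical results files (the provenance block
  hashes the analysis-relevant config and records seeds and versions).

## Known limitations

* Satterthwaite df come from finite-difference derivatives; in
  near-boundary fits they can be less stable than lmerTest's analytic
  gradients (the OLS fallback handles the boundary itself).
* The diel-scale Spearman treats clock time linearly; for distributions
  straddling midnight the optional circular correlation is the right tool,
  and no analytic p is attached to it.
* The scan assumes exactly two seasons; the repeatability and social
  modules likewise target the two-season design.
* With site fidelity near 1 the social test has essentially no power to
  detect coupling, because almost no choices are free; power experiments
  set fidelity to 0 to isolate the social channel.
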