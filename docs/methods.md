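# Methods

## Model structure

The system is a discrete-state dynamic Bayesian network with monthly time
slices.  A slice holds ~16 nodes: an environment driver (`light`, binary
above/below photosynthetic saturation), three site descriptors (climate,
tidal exposure, meadow type; point-mass roots carried as metadata), process
nodes (physiological status, growth, abilities to resist and recover, loss,
recovery, net change, recruitment from seeds), and population nodes
(baseline population, seed density, realised shoot density, realised
biomass).  Cross-slice edges run through five interface nodes at most —
physiological status, seed density, baseline population and realised shoot
density in the shipped topology — so the exact interface joint has ≤ 576
states and filtering is exact by construction.  A hard cap (default 10⁵
interface states) raises an explicit error instead of silently
approximating; there is no Boyen–Koller projection and no sampling.

Non-homogeneity enters through per-node regime selectors: an ordered rule
list maps (slice index, calendar month, optional regime label) to a named
CPT, with a default.  The shipped network uses calendar-month rules to
switch growth, seed production, recruitment and baseline-population tables
between growing and senescent seasons (Austral October–March for southern
sites, boreal April–September for northern).  Months are numbered 1–12
(12 = December); slice 0 carries the simulation's start month and month
arithmetic is modulo 12.

Evidence on the light node is soft: the driver supplies a per-slice
distribution (the monthly probability of above-saturation light), not an
observation.  Each slice's posterior is renormalised; drift beyond 1e-6 is
logged.  Filtering only — no smoothing or backward pass, matching how the
model is used (cumulative monthly posteriors).

The brute-force oracle used in testing enumerates the full joint over all
nodes of a slice and propagates it with nested-loop CPT products.  It shares
no code with the filtering path and agrees with it to < 1e-10 on randomized
networks (up to 4 nodes, 3 states, 24 slices; 50 seeded draws in the test
suite).  Full enumeration of the joint over all slices jointly is
intractable even at that size, so the oracle is exact per-slice propagation
of the complete (unfactorized) state, with a cap of 10⁷ evaluated
transition entries.

## Discretisation and state values

Population metrics are percentages of a site reference value with half-open
intervals (lower, upper]: zero = 0, low (0, 20], moderate (20, 80], high
(80, 100]; loss/recovery magnitudes use (0, 10], (10, 30], (30, 100].
Printed integer thresholds are read as the integer-labelled endpoints of
these continuous intervals, so every real percentage maps to exactly one
state (property-tested over a dense grid).  Values above 100 % clamp to
high.

Each nonzero state carries a five-point quantile grid under a uniform
within-interval distribution: for integer bounds lo..hi (lo = exclusive
lower bound + 1, w = hi − lo) the grid is {lo, ⌈lo+w/4⌉, ⌈lo+w/2⌉,
⌈lo+3w/4⌉, hi} — ceiling-rounded quartiles, the unique simple rule giving
{81, 86, 91, 96, 100} for the high state.  The state value x̄_j is the grid
median (91, 51, 11, 0 for the population scheme), which equals the mean for
a uniform distribution.

## Weighted mean and resilience criteria

μ′(t) = Σ_j p_j(t)·x̄_j; μ(t) = p₀(t) when μ′(t) < α, else
(1 − p₀(t))·μ′(t).  The formula is evaluated literally.  Note the scale
mixing: when μ′ < α the trajectory reports the extinction *probability*
(≤ 1) on the percent axis.  With α = 1.0 — the lower edge of the low
interval, the default — this pins near-extinct trajectories near zero,
which is the intent; users changing α should keep it small relative to the
low-state median.

Criteria compare a stressed run to the month-matched control of the same
site, sharing initial beliefs and initialisation; baselines may be constant
(limit points) or seasonal (limit cycles), and a scalar baseline would
misjudge annual meadows.  Defaults: resistance threshold 0.20 at the first
slice after the last dredging slice; recovery threshold 0.20 with a
six-month criterion window and a 60-month permanence horizon; persistence
ratio 1.025 on the mean zero-state probability over the 60 months after
stress end (the maximum instantaneous ratio is available via
`extinction_aggregation="max"`; the mean is the default because a single
transient month should not dominate a five-year risk summary).  When the
month-matched baseline μ is zero (annual meadows out of season), relative
change is defined as 0 when the response is also below α, and a response
*above* an absent baseline is likewise not counted as a loss; both uses are
logged.

Scores: 4 = R∧C∧P, 3 = R∧C∧¬P, 2 = ¬R∧C∧P, 1 = ¬R∧C∧¬P, 0 = ¬C.
Resistance as defined implies the recovery criterion (recovery time 0), so
R∧¬C is rejected as inconsistent input.  The mapping is bijective over the
five admissible combinations and `decode_score` inverts it.

## Scenario engine

Initialisation (default 24 months), stress, response (default 60 months,
the permanence horizon).  Dredged months take min(baseline light
probability, permitted level); rest blocks and all other slices see
baseline.  Alternating designs start and end on a dredge block (6-3 spans
nine calendar months, 6-2 ten).  The scenario grid enumerates designs × 12
start months × light levels, with the light-invariant control emitted once
per month; 8 designs + control at one level is the standard 108-scenario
grid.  Initialisation convergence is checked with a month-matched
total-variation limit-cycle test (tolerance 1e-3) and logged — not
enforced, because transitory meadows cycle by design, and the shipped
enduring fixtures approach their limit points slowly (a nearly balanced
birth–death walk settles to ~1e-2 in two years).  Month-matched pairing of
baseline and response cancels residual initialisation drift in all
criteria.  Hemisphere alignment for cross-site displays is a reporting
transform only; all computation uses true calendar months.

Studies stream one JSON record per scenario (per-slice state probabilities
of the tracked nodes plus metadata) and resume by scenario id after
interruption; single-scenario failures are recorded and the study
continues.

## Synthetic archetypes

The original conditional tables were elicited from expert panels on a
nine-label linguistic scale (certainty … impossible); neither the tables
nor the label-to-number mapping are published.  The generator therefore
targets *qualitative behavioural structure*, not numerical reproduction:

* The default scale is {1.0, 0.95, 0.85, 0.70, 0.50, 0.30, 0.15, 0.05,
  0.0} — symmetric around the fixed point 50/50 = 0.5, overridable.
* Rows come from a tempered binomial kernel: Binomial(K−1, θ) raised to a
  concentration power and renormalised.  The kernel has monotone likelihood
  ratio in θ, so any target level θ monotone in a parent's ordinal level
  yields first-order stochastic dominance in that parent.  Dominance is
  verified table-by-table for every parent with the sign appropriate to the
  edge (e.g. loss decreases stochastically with light and resistance).
* Archetype trait labels (resistance, growth rate, seed production and
  recruitment, seasonal amplitude, mortality under low light) are strictly
  ordered colonising/opportunistic/persistent per axis, and the ordering is
  validated.
* Three structural choices produce the documented life-history behaviour:
  physiological status carries inertia that grows with resistance (reserves
  buffer deprivation), the ability to resist is *convex* in status (it
  holds, then collapses under sustained deprivation), and vegetative growth
  is gated by surviving shoots, so a crashed meadow recovers through its
  gradually decaying seed bank.  Together these give: persistent meadows
  resist one-month blackouts at every start month but are materially
  damaged by three months and recover slowly; colonising meadows crash fast
  and recover within months; damage accumulates with campaign duration
  rather than saturating, so recovery time and extinction ratio are
  monotone in total dredge months and anti-monotone in permitted light on
  the shipped fixtures.
* Enduring fixtures are limit-point baselines: their growing and senescent
  tables are (near-)identical, and their canonical light climate is bright
  and mildly seasonal (mean 0.85, amplitude 0.07).  Transitory fixtures
  carry the strong seasonal regimes — baseline population and realised
  population cycle annually to zero through the senescent season and return
  through seeds.  This mirrors the constant-vs-periodic baseline dichotomy
  and keeps the monotonicity properties testable where they are
  scientifically expected: under strongly seasonal recovery a longer
  campaign can genuinely recover *faster* by ending at the growing season,
  so strict duration monotonicity is asserted only on the enduring
  fixtures.
* Light climatologies are sinusoids (annual mean, amplitude, peak month)
  with optional beta-distributed monthly noise and an optional daily binary
  series consistent with the monthly probabilities.  The 28-site study
  fixture spans both hemispheres, all three life histories and both meadow
  types, with latitude-dependent amplitude.
* All randomness flows through one seeded generator; the same seed gives
  byte-identical bundles and site files.

What the fixtures do **not** emulate: elicited inter-expert variability,
burial/sediment-quality/connectivity pathways, species-level physiology
(temperature-dependent saturation thresholds are folded into the monthly
light probability), and any site's actual numbers.  Passing tests
demonstrate that the machinery is correct and that the documented
qualitative contrasts follow from the stated structural assumptions — not
that any real meadow behaves like a fixture.

## Calibration and validation machinery

Monthly light probabilities are estimated from daily series by conjugate
beta-binomial updating per calendar month, pooled across years (posterior
mean and equal-tailed 95 % interval; months without data are flagged, never
interpolated).  Observation series are converted to state probabilities by
discretising replicates and taking the Dirichlet(1,…,1)-multinomial
posterior mean.  These closed-form conjugate estimators use the same
likelihoods as sampler-based hierarchical fits but are exactly
reproducible; per-calendar-month pooling is the hierarchical level.  A
deterministic grid search over reference-value scalings replaces visual
calibration, minimising the all-states MSE.  Validation reports the MSE
between predicted and observed state probabilities over all states and over
the zero state alone.

Sensitivity analysis fits one gradient-boosted regression tree per response
(each tracked state of shoot density and biomass) on logit-transformed
posterior probabilities of every node-state at t and t−1 (clipped at 1e-6
before the logit), excluding the response's own node at t.  Influence is
the normalised tree importance; the "most influential" set is everything
within two orders of magnitude of the maximum weight.  Constant responses
are flagged and skipped.  With the reduced ~16-node network the variable
count differs from the full elicited model and no equivalence of influence
rankings is claimed.

## Problem sizes and numerical choices

The shipped interface joint has 144 states; slice propagators are compiled
once per (resolved tables, clamped light state) and cached, so a 96-slice
scenario runs in milliseconds and the 3-site × 108-scenario smoke study in
the test suite completes in seconds.  Oracle-equivalence tests use ≤ 4
nodes, ≤ 3 states, ≤ 24 slices — the scale at which full-joint enumeration
is cheap.  CPT rows must sum to 1 within 1e-9; posteriors are renormalised
each slice; monotonicity comparisons use a 1e-12 slack for floating-point
ties.  Recovery times are integers in months with "permanent" ordered above
every integer.

## Known limitations

* The reference topology is a ~16-node reduction; extension points exist in
  the schema format for burial, sediment quality and connectivity, but no
  tables ship for them.
* Exact filtering limits interface sets to ~10⁵ joint states; larger
  models need a factored approximation the package deliberately does not
  provide.
* The literal μ formula mixes probability and percent scales below α (see
  above); comparisons across α values are not meaningful.
* No parameter or structure learning: tables are inputs (elicited or
  generated), never fitted to data.
* Validation MSE machinery is exercised on synthetic data only; site-level
  empirical MSEs require the unpublished elicited tables and field data.
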