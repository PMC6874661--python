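# Methods

`fullcycle` estimates when in the annual cycle, and at which life stage,
a migratory long-lived raptor dies — and what those deaths mean for
population growth.  It implements a full chain from known-fate tracking
histories to stage-structured demography, together with a synthetic-data
generator that reproduces the statistical structure of a satellite-
tracking study, so that every stage of the chain can be validated against
known ground truth.

## The annual cycle and life cycle

The year of the study system is tiled, per age class, by four stages:
breeding (Mar 1 – Aug 31, 184 d), southward (post-breeding) migration,
African wintering, and northward (pre-breeding) migration.  Migration
durations for adults default to 20 d (southward, Sep 1–20) and 15 d
(northward, Feb 14–28), with wintering filling the remaining 146 d; these
sit inside the 8–35-day range typical of trans-Saharan raptor journeys
and are fully configurable.  One-year-old birds never attempt the
northward migration: their calendar has a slower southward journey (25 d)
and wintering that runs to the end of their year.  Feb 29 of leap years
takes the stage of Feb 28, so every year tiles the same 365-day template.

Integer age advances on a fixed reference birthday (Mar 1, the start of
breeding), so age-class transitions coincide with a stage boundary — the
convention a field study uses when ages are known in whole years.  The
life cycle is partitioned into juvenile (age 1), young adult (2–6), prime
(7–11) and senescent (12–28) classes.  Birds observed while younger than
1 (tagged as fledglings) or older than 28 are clamped to the boundary
classes for exposure labelling.

## Exposure decomposition

Each tracking history (tagging date, age at tagging, fate and fate date)
is decomposed day by day into contiguous **exposure segments** within one
(age class, stage) combination.  A bird exiting a stage alive re-enters
the next one as a *new individual*: the within-segment clock restarts at
every stage boundary and every age-class transition, and the boundary day
belongs to the earlier stage.  Exactly one segment (the last) carries the
death event of a bird that died; segments of censored birds all end
event-free.  The decomposition is validated against an independent
day-by-day labelling oracle in the test suite.

## Survival estimation

Within one combination, segments are placed on a common within-segment
day axis.  Every distinct death day closes a risk interval *t* with

    S_t = (r_t − n_t) / r_t,

where `r_t` counts segments still at risk (censored segments leave the
risk set after their last day; a segment censored on a death day is still
at risk for that day's deaths) and `n_t` the deaths on that day.
Intervals opening with ≤ 5 individuals at risk are flagged and excluded
from combination (threshold configurable).  Interval survivals are
rescaled to per-day survivals `dS_t = S_t^(1/Δt_t)`, with `Δt_t` the days
elapsed since the previous death day (or the axis start), and combined by
a geometric mean into the average daily survival `dS`.  Stage survival is
`φ = dS^l`, with `l` the stage duration for that age class.  Combinations
with no deaths are assigned `φ = 1` and flagged, preserving the
distinction from estimated values.

**Weighting of the geometric mean.**  Two conventions are implemented.
The default weights each interval by its length, which makes the combined
estimate the per-day root of the product-limit estimator,
`dS = (∏ S_t)^(1/ΣΔt)`.  Under this weighting the estimator is consistent
for the true daily survival: the acceptance suite verifies |bias| <
0.1·h and ≥ 90% CI coverage at h = 0.002/day, n = 500.  The alternative
(`weighting="intervals"`) averages the `dS_t` values with equal weight
per interval.  That reading over-weights short gaps between deaths: the
expected log daily mortality is inflated by the factor `(−ln p)/(1−p)`
with `p` the per-day probability of at least one death in the risk set,
which reaches 2–3× when risk sets are small.  It is retained for
comparability with analyses that average interval values directly, but it
is not the default precisely because it fails parameter recovery.

**Variances.**  `var(S_t)` uses the single-interval Greenwood form
`S_t² n / (r (r−n))`; all subsequent steps are first-order δ-method:
`var(dS_t) = (dS_t/(Δt S_t))² var(S_t)`, the combination propagates on
the log scale with the same weights as the mean, and
`se(φ) = l · dS^(l−1) · se(dS)`.  The δ-method SE agrees with the SD of
1,000 individual-level bootstrap resamples within a few percent on
simulated data (acceptance suite).

**Degenerate cases.**  An interval in which every remaining segment dies
gives `S_t = 0`, for which the daily rescaling is undefined; this raises
an error (it cannot occur at realistic risk-set sizes because such
intervals are also below the at-risk threshold).  A combination whose
every interval is dropped falls through to the `φ = 1` convention with
its dropped-interval count recorded.

## Significance testing by control resampling

Formal significance testing through Kaplan–Meier machinery needs far
larger samples than tracking studies provide, so stage and age effects on
*where in the cycle* death occurs are tested by resampling: every bird
that never died (a control) receives one simulated death day drawn
uniformly over its own tracking period, which automatically inherits the
exposure structure of the data.  Actual deaths (1) are contrasted with
simulated deaths (0) in a binomial GLM with logit link on stage, age
group and their interaction; each term is tested by a likelihood-ratio
χ² between nested fits.  Age enters as the pooled two-level factor
(ages 1–6 vs 7+) by default — mirroring the pooling used for the
frequency χ² when cells are sparse — or as the four life-cycle classes.
Cells observed in only one response arm are flagged as quasi-separated
rather than failing the fit.  Individuals tracked for under 7 days
(configurable) are excluded before control selection.  Because a single
simulated-death draw makes the outcome seed-dependent, an optional
Monte-Carlo mode repeats the draw R times and reports median p-values;
the default R = 1 keeps the single-draw design.

Two properties of this construction are worth knowing.  First, the
day-of-death distribution of birds that died is weighted toward the early
part of their tracks, while controls draw uniformly; the *stage main
effect* of the GLM therefore absorbs a systematic component even when
hazards are uniform, and only the interaction term is a clean null.
Second, the interaction LRT inherits the usual χ² small-cell behaviour:
the short migration stages contribute ~4% of exposure, so calibration
experiments need enough events to populate those cells.  The acceptance
suite verifies a 5% ± 2% type-I rate with 800-bird replicates (adult
calendars, so age groups share exposure structure) and ≥ 80% power
against a juvenile migration hazard 10× the wintering hazard with
900-bird replicates; at typical field sample sizes the test should be
read as mildly anticonservative for the interaction.

Death frequencies across stage × pooled age (1–6 vs 7+) are compared by
Pearson χ² (no continuity correction), with warnings when expected cell
counts fall below 5, and age-at-death and latitude-at-death are compared
across stages by one-way fixed-effects ANOVA.

## Population projection and sensitivities

Annual survival of class *j* is the product of its stage survivals,
`σ_j = ∏_k φ_{j,k}` (three stages for juveniles).  These enter a
female-based, birth-pulse, **pre-breeding-census** Leslie matrix over
integer ages 1–28 — census type and sex structure are modelling choices
of this package, standard for raptor demography.  Subdiagonal entries
carry `σ(age)`; first-row fertilities are `F(a) = σ(a) · b(class(a+1))`,
i.e. survive the year, then breed at the next birthday.  The natality
defaults (b = 0, 0.3, 0.75, 0.5 female offspring/female/year for the four
classes) are **placeholders**: they are plausible for a long-lived raptor
but are not estimates from any study, and real analyses must supply their
own values.

The dominant eigenpair gives λ, the stable age distribution and
reproductive values; a power iteration on A + I (shifted so imprimitive
toy matrices also converge) cross-checks λ to 1e-8, and the sum of entry
elasticities is verified to equal 1.  Sensitivities of λ to each stage
survival follow the eigenvector formula `∂λ/∂a_pq = v_p w_q / ⟨v,w⟩`
summed over the entries containing `φ_{j,k}` via the chain rule, and are
verified against central finite differences.  The figure-facing scale is
the derivative with respect to the stage's **daily mortality** (further
factor `l · dS^(l−1)`), reported as a magnitude; with respect to per-day
mortality the impact of a stage is essentially proportional to its
duration — the mechanism by which long, low-mortality stages matter as
much for λ as short, high-mortality ones.

Uncertainty is propagated by parametric bootstrap over 1,000 replicate
matrices: each φ is drawn from a logit-normal and each b from a
log-normal matched to its estimate and SE (δ-method on the transformed
scale), which respects the (0,1] and (0,∞) ranges; parameters with SE 0,
including the zero-death `φ = 1` convention, stay fixed.  Replicates
without a positive dominant eigenvalue are redrawn and counted in the run
log.  Bootstrap SEs are exact zeros when all inputs are fixed and stable
across seeds within a few percent at B = 1000.

## Spatial clustering of death sites

Death coordinates are projected to planar kilometres by an
equirectangular projection about the mean latitude (distortion from
meridian convergence is ~2% per 2° of latitude from the reference — fine
at the corridor scale analysed here; antimeridian-spanning sets are
refused).  The Average Nearest Neighbor statistic compares the observed
mean nearest-neighbour distance to its expectation under complete
spatial randomness, `D_exp = 0.5·√(A/n)`, `SE = 0.26136/√(n²/A)`, with a
two-tailed z-test; patterns are labelled clustered / random / dispersed
at |z| = 1.96.  The study area defaults to the points' minimum enclosing
rectangle (the convention of the common GIS tool), with convex hull and
user-supplied area as alternatives — the index is sensitive to this
choice, so the per-stage report records which was used.

The classic formulas carry a positive edge bias in bounded areas
(boundary points inflate `D_obs` by ≈ `(0.0514 + 0.041/√n)·P/n`, about
+0.85 z-units for 100 points in a unit square).  A Donnelly-corrected
mode (boundary-adjusted expectation and variance) is therefore provided
and is the calibrated choice under CSR — the acceptance suite verifies
mean z within ±0.15 of zero with the correction and documents the bias
without it.  The uncorrected mode remains the default for the
paper-facing per-stage report because it reproduces the GIS tool's
behaviour.

## The synthetic-data generator

The generator emulates a long-term tagging study: `n` birds of known
integer age (weights over tagging ages 0–27; default fledgling-heavy),
tagged at uniform dates over a 7-year trapping window and followed up to
an 11-year study end.  Each bird is walked day by day through its
calendar under constant per-(class, stage) daily death hazards, with
competing transmitter-failure censoring (default 5e-4/day — a
placeholder, as studies rarely report this rate) and administrative
censoring at study end; death wins a same-day tie.  Death locations are
drawn from per-stage isotropic normals in degrees sketching the Iberian
breeding grounds, Saharan corridor and Sahelian wintering belt.  The
default hazard table was calibrated once so that a 108-bird run yields
roughly half deaths (the scale of the motivating study system) with
migration mortality per day far above the static stages at all ages and
wintering mortality elevated only for juveniles.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: hazards are constant within a stage (no
within-stage or calendar-year variation, no individual heterogeneity or
frailty), all birds of a class share one phenology (no individual
migration timing), death sites are isotropic around a stage centroid (no
corridor geometry), and tag failure is independent of behaviour and
location.  Tests validate the *estimators* under the model's own
assumptions, not the assumptions themselves.

## Simulation sizes used in validation

The calibration experiments in the acceptance suite use 200 replicates of
500 birds for estimator recovery, 500 replicates of 800 birds for GLM
type-I error, 200 replicates of 900 birds for power, 60 seeds of 600
birds for the mortality-ordering check, and 500 CSR patterns of 100
points for the spatial test — sizes chosen so that every stage × age cell
is adequately populated while a full run of the suite stays inexpensive.

## Known limitations

- The equal-duration-weighted population impact of stages is close to an
  identity of the per-day parametrisation (`∂λ/∂m_k ∝ l_k/dS_k` within a
  class); the substantive content is in the unweighted comparison and in
  the class-to-class differences.
- No staggered-entry adjustment beyond what segment construction already
  provides; no Cox/parametric hazards; no multi-state models; no density
  dependence or stochastic projection.
- The ANN test uses planar geometry and no geodesic distances; at
  continental extents the projection distortion reaches a few percent.
- With a single simulated death day per control, GLM p-values are
  seed-dependent; report the seed or use the Monte-Carlo mode.
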