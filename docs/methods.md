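# Methods

This note documents the models, the numerical choices behind them, what
the synthetic generator does and does not emulate, and the design
decisions taken where the workflow left room for interpretation.

## Spatial conventions

Coordinates are planar map units; the package performs no great-circle or
CRS arithmetic, so real-world inputs must be pre-projected. Grid cell
(row, col) covers a half-open square with row 0 at the top; points on a
shared edge belong to the greater-index cell. This single convention
drives cell assignment, deduplication, raster extraction and the ASCII
grid I/O. The Terrain Ruggedness Index of a cell is the mean absolute
elevation difference to its up-to-8 neighbours; edge cells use the 3 or 5
neighbours that exist rather than padded values, and nodata neighbours are
skipped, so no elevation is ever fabricated. TRI is therefore invariant to
elevation shifts and scales linearly with elevation scaling, which the
property tests exercise.

## Occurrence dataset

The surface range envelope is the per-predictor box between the (1−q)/2
and 1−(1−q)/2 empirical quantiles of the presence values, with q = 0.95 by
default. "95% of presence data" is read as this symmetric two-sided
construction, which is the standard SRE; the quantiles use numpy's
linear-interpolation definition. A consequence worth stating: with linear
interpolation the box can exclude up to one extra presence per tail beyond
the nominal (1−q)·n, so exact ⌈q·n⌉ coverage is not guaranteed at every n.
A point is inside only if it is inside on every predictor.

Pseudo-absences are sampled uniformly without replacement at the cell
level from cells outside the envelope, excluding presence cells, at 10
absences per presence; if fewer eligible cells exist, all are taken with a
warning. Sampling without replacement matches the one-record-per-cell
convention established by presence deduplication.

Predictor importance is D² = 1 − (residual deviance / null deviance) of a
univariate binomial GLM with logit link — the deviance is the GLM
generalization of "residual variance / null variance". Complete separation
is caught and reported as importance 1 with a warning rather than an
exception. Screening first applies the D² ≥ 0.30 cutoff, then repeatedly
finds the remaining pair with the largest |Spearman ρ| ≥ 0.70 and drops
its lower-D² member (ties: the later-listed), a greedy rule that keeps the
highest-goodness member of every correlated cluster and is
order-independent up to documented tie-breaks.

## Ensemble SDM

Each learner is fitted on 10 stratified 80/20 calibration/evaluation
splits plus one full-data fit. TSS is maximized over candidate thresholds
(the sorted unique scores and their midpoints; smallest arg-max on ties),
with a record predicted present when its score is at or above the
threshold. Members qualify with TSS strictly above 0.80 and are averaged
with equal weight — qualifying members are treated as exchangeable rather
than weighted by their (uniformly high) skill. The no-split members have
no held-out records to score; they inherit the mean held-out TSS of their
learner's split replicates, and any resubstitution TSS printed for the
ensemble is labelled as such and never mixed with held-out values.

The native learner registry holds four techniques: unpenalized-style
logistic regression with quadratic terms, the SRE scorer (predicts 1
inside the presence envelope, 0 outside), gradient-boosted trees, and
random forest. The ensemble machinery is learner-agnostic; further
techniques plug in by registering an object with `fit`/`predict_prob`.

Permutation importance of a predictor is the mean over permutations of
1 − Pearson r between the ensemble's original predictions and its
predictions with that column permuted; constant predictions yield 0 with a
warning. Response curves evaluate the ensemble along one predictor with
the others held at their training means (the evaluation-strip convention).

Habitat accounting uses strict P(occ) > 0.5. The altitude cut keeps cells
with elevation ≥ 394 m: the lowest confirmed occurrence sits exactly at
394 m, so "higher than" is read inclusively. Masks are applied
idempotently and order-independently; removal counts are attributed to the
first failing cause in the order substrate, land cover, altitude, so the
causes partition the removals.

## Mixed-effects engine

Both seed-production families run through one engine
(`edelweiss.mixed.fit_glmm`) supporting any number of random-intercept
factors, including an observation-level random effect (one level per
record).

Poisson (log link): for candidate variance parameters, the fixed and
random effects are found at the joint mode of the penalized log-likelihood
by damped Newton iteration, and the marginal likelihood is approximated by
the Laplace correction at that mode — the scheme lme4 applies at
`nAGQ = 0`. The outer optimization runs Nelder-Mead over log standard
deviations (bounded to [e⁻⁶, e³]); after convergence each variance
component is also tested against its zero boundary and the better solution
kept, which handles singular fits cleanly. On identical data the engine
reproduces lme4's `glmer` coefficients, standard errors, variance
components and log-likelihood to two or more decimals (cross-checked in
the test suite via Rscript).

Gaussian: exact marginal maximum likelihood with the residual variance
profiled out and the outer optimization over log variance ratios. ML
rather than REML is used throughout, deliberately: stepwise selection
compares models with different fixed-effect structures, for which REML
AICs are not comparable. Profile or bootstrap intervals are out of scope;
all intervals are Wald intervals from the observed information of the
fixed effects (random effects integrated/profiled out). With few grouping
levels (7 sites in the default design) Wald intervals for the intercept
are known to undercover; the recovery battery therefore evaluates the
slope coefficients, which are well calibrated (coverage 0.90–0.96 at 200
replicates).

AIC = −2·logLik + 2·(p + number of variance parameters, + 1 for the
Gaussian residual variance).

## Seed-production models

The measurement chain follows the field protocol exactly: per-
inflorescence seed count = mean seeds per anthodium × anthodium count
(rounded half-up at this single point, because Poisson responses must be
integers); dry mass = 0.89 × fresh mass; plot totals = mean
per-inflorescence quantity × number of inflorescences on the 1 m² plot.
Braun-Blanquet ranks map to midpoint covers 0.5/5/17.5/37.5/62.5/87.5%.

Favorability is clipped to [10⁻⁶, 1−10⁻⁶] before the logit (the transform
is undefined at 0/1), then every predictor is centred and scaled; the
constants are stored in the fitted model so any later prediction
standardizes with the training constants, never with new-data moments.

Random-effect structures per response: seed number/plot — site plus a
plot-level OLRE; seed number/inflorescence — site, plot, and an OLRE;
seed mass/plot — site; seed mass/inflorescence — site and plot. Mass
responses are cube-root transformed before the Gaussian fit and
back-transformed by cubing; the naive cube is biased low as a conditional
mean (no smearing correction is applied) and is documented as such.

Backward stepwise: each round refits the model without each currently
droppable term (a main effect is droppable only when no retained
interaction contains it), removes the term whose deletion lowers AIC most
— deletions raising AIC by at most 2 units are still accepted, favouring
parsimony — and stops when the best deletion would raise AIC by more than
2 or leave the model more than 2 units above the minimum encountered. The
full AIC trace is recorded and the returned model is guaranteed within 2
units of the trace minimum.

Nakagawa R²: Rm² = var(Xβ̂)/total, Rc² adds the group-level variance
components to the numerator. For the Gaussian family the denominator adds
the residual variance; for the Poisson it adds the OLRE variance plus the
lognormal distribution-specific variance ln(1 + 1/λ) with
λ = exp(β̂₀ + σ²_total/2). The OLRE variance counts as
overdispersion (denominator only), not as explained group structure.

## Projection

Per-km² seed output of a suitable cell is the per-m² model prediction
× 10⁶, weighted by the cell's P(occ) by default. The bare 10⁶ scale-up
treats every square metre of a 1 km² cell as occupied habitat, which
overstates output in marginal cells; weighting by the occupancy
probability is the package's interpretation of per-area output and is
configurable (`weight="unit"` restores the bare scale-up). Means ± SE over
suitable cells are descriptive cell statistics, not model-based predictive
intervals. Mass converts without an explicit factor: 1 mg/m² = 1 kg/km².

## Synthetic generator

The generator exists so every stage has a testable ground truth. It
emulates: a rugged elevation surface (spectral-synthesis Gaussian random
field with a power-law spectrum, exponent 3); winter temperature declining
with elevation at 6.5 °C/km plus smooth field noise; summer precipitation
increasing with elevation; substrate/land-cover masks as random blobs; a
logistic true-occupancy surface in standardized TRI (+5), winter
temperature (−4.5) and summer precipitation (+1.5) with intercept −17 —
sharp coefficients chosen once so that suitable habitat is a rare joint
tail (a few percent of cells), as for a genuine alpine specialist, which
in turn makes presence records concentrate into few cells and gives the
envelope genuine outside area to draw absences from; valley-biased
random-walk trails; and demography tables from log-linear Poisson and
cube-root-normal processes whose fixed effects follow the directions and
magnitudes observed for edelweiss fitness (favorability +0.5, trail
distance +0.5, hemiparasites +0.45, woody cover −0.45, height +0.2 on the
standardized scale, with truly-null cushion and interaction terms for
selection tests), site/plot intercept SDs of 0.25, and a warming scenario
of +2.8 °C with a 5% precipitation increase.

Two honest limitations. First, the plot-level and inflorescence-level
responses are generated from their own processes sharing one latent
design, rather than being strictly chained through the measurement
arithmetic in noisy mode — the cube root of a product is not a sum of
cube roots, so a single strictly-chained process cannot give exact ground
truth at both levels; the chain identity holds exactly in noise-off mode
and the converter operations are unit-tested directly. Second, the
generator reproduces the qualitative structure of real alpine data, not
its messiness: no observation error in covers or heights, no spatial
autocorrelation beyond the smooth fields, no reported-coordinate error in
occurrences, and no attempt to reproduce implausible summary statistics
(e.g. a trail-distance SD far smaller than its between-massif spread).
Passing tests demonstrate the estimators and pipeline logic are correct
under the stated generative model, not that real data meet its
assumptions.

Every generator is a pure function of (truth, seed); the default problem
sizes (60×60 cells, 424 occurrence records, 7 sites × 7 plots, 3
inflorescences per plot) mirror the field study's scale, and the recovery
battery scales the plot design up to 300 plots (50 sites × 6 plots,
preserving the ~6 plots-per-site field layout) for power.

## Pipeline

One master seed deterministically spawns per-stage seeds through numpy's
`SeedSequence`, so a config plus a seed reproduces every artifact
byte-for-byte (asserted in the acceptance suite). Stage manifests record
the config hash and stage seed; a stage whose manifest matches skips
rewriting its artifacts. Configuration validation errors on out-of-domain
thresholds and warns when a value deviates from the workflow's canonical
constants (q = 0.95, ratio 10, D² 0.30, ρ 0.70, 80/20 × 10, TSS 0.80,
P 0.5, 394 m).

## Known limitations

* Wald intervals only; no profile likelihood or bootstrap.
* The Laplace scheme evaluates at the joint (β, u) mode; for severely
  small counts per group this can differ slightly from adaptive
  quadrature.
* Four of the classic ten ensemble learners are native; the others are
  pluggable but not bundled.
* No dispersal, colonization lag or population viability machinery —
  projection is a static recoupling of fitness to future favorability.
* Real-data use requires pre-projected rasters on a shared grid; the
  package performs no reprojection.
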