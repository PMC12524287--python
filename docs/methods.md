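# Methods

## The model

`occumap` is built around the Royle–Nichols (RN) abundance-induced-
heterogeneity occupancy model for station × occasion detection data. Station
*i* hosts a latent number of individuals

&nbsp;&nbsp;N_i ~ Poisson(λ_i),&nbsp;&nbsp;log λ_i = x_i′β,

and each individual is detected independently on occasion *j* with
probability r_i on a logit link, logit r_i = w_i′α, so the station-level
per-occasion detection probability is 1 − (1 − r_i)^{N_i}. The marginal
likelihood of station *i*'s history y_i over its J_i observed occasions is

&nbsp;&nbsp;L_i = Σ_{n=0}^{K} Poisson(n; λ_i) · (1 − (1−r_i)^n)^{d_i} ·
((1−r_i)^n)^{J_i − d_i},

where d_i is the station's number of detection occasions — the history
enters only through (d_i, J_i) because r_i is constant across a station's
occasions. Occupancy ψ_i = 1 − exp(−λ_i) and the species-level detection
probability p_i = 1 − E[(1−r_i)^{N_i}] (= 1 − exp(−λ_i r_i) for Poisson N,
computed by truncated sum to the tail tolerance) are derived parameters.
The MacKenzie single-season model (ψ, p on logit links, no abundance
structure) is implemented as the baseline comparator; on data whose
detection heterogeneity is abundance-driven the RN model wins the AIC
comparison in essentially every replicate, which is why the package's
selection workflow is RN-based.

Assumptions inherited from the model: population closure over the
deployment (supported by ≤ 2-month deployments), independence of occasions
given N, no unmodeled detection heterogeneity within a station, and
exchangeability of stations given covariates (no residual spatial
autocorrelation).

## Numerical choices

- **Truncation bound K.** The latent-count sum is truncated at the smallest
  K whose Poisson upper-tail mass at the largest current λ_i is below
  1e-10, with a floor of 50; K is recomputed at every likelihood
  evaluation, so the bound tracks the optimizer's current λ. A user-supplied
  K that leaves more than the tolerance of tail mass is rejected with a
  diagnostic.
- **Optimization.** L-BFGS-B on the negative log-likelihood with
  finite-difference gradients, from a zero-initialized coefficient vector
  plus 3 seeded N(0, 0.5) random restarts (the best converged solution
  wins). Convergence is declared by the optimizer at projected-gradient
  norm ≤ 1e-8 or relative function decrease ≤ 1e-12 — with numeric
  gradients of a log-likelihood of order 10², the function-decrease
  criterion is the one that can actually bind, and the convergence flag
  reports the optimizer's own verdict. Linear predictors above 30 on the
  log-λ scale are rejected (objective = +∞) to keep optimizer excursions
  from overflowing.
- **Standard errors** come from the inverse of a finite-difference Hessian
  of the negative log-likelihood (`statsmodels.tools.numdiff.approx_hess`);
  non-positive curvature yields NaN SEs rather than a silent fabrication.
- **Design matrices.** Intercept always included; the survey-site factor
  uses reference coding with the lexicographically first site as reference;
  interactions `a:b` are elementwise products and require both main effects
  (hierarchy is enforced at specification time); rank-deficient designs are
  rejected.

## Detection histories

The independence rule is *sliding*: a record is independent iff it is the
station's first or ≥ 30 min (boundary inclusive) after the immediately
preceding raw record at that station. This filter is idempotent — any
surviving pair is automatically ≥ 30 min apart. Occasions are anchored at
each station's own deployment start (occasions are exchangeable replicates,
so stations need not share calendar windows); a trailing partial window
with at least one active day is kept as an occasion (a flag drops it), and
occasion-level effort is not modeled — station-level deployment duration
is available as a standardized detection covariate instead. Dates are
calendar days with half-open day arithmetic and no time-zone handling.

## Covariates

Station covariates are buffer means: the mean of all grid cells whose
*center* lies within the radius (500 m default, the minimum female home
range) — a cell-center rule rather than area weighting, chosen for
simplicity and exact testability. Distance-to-water style covariates can be
log-transformed as ln(d + 1 m) to tame their long tail. All covariates are
z-standardized (divisor-n SD) before fitting, and the stored transform is
reapplied verbatim to prediction grids. Collinearity pruning is iterative
and greedy: while any pair of retained covariates has |Pearson r| above the
threshold (0.7), the most-correlated pair is located (lexicographic
tie-break) and its higher-univariate-AIC member dropped; the greedy order is
tested against an independent re-implementation on small cases.

## Model selection and averaging

Step 1 fixes the detection structure by AIC with abundance intercept-only;
step 2 retains abundance covariates whose univariate model has AIC strictly
below the null's, then prunes collinear survivors; step 3 fits every
hierarchical subset of the pruned global model and ranks by AIC (ties by
fewer parameters). When no model dominates, coefficients are averaged over
the smallest AIC-ordered prefix whose cumulative Akaike weight reaches 0.95,
with weights renormalized inside the subset (the renormalization is flagged
in the output). Averaging is conditional (natural): a coefficient is
averaged only over models containing it, with weights renormalized over
those models; the unconditional SE is
sqrt(Σ w_m [se_m² + (β_m − β̄)²]). AIC, not AICc, throughout.

## Goodness of fit

The MacKenzie–Bailey test groups stations into cohorts by missingness
pattern; each distinct realized history gets a Pearson cell with expected
count Σ_i P_i(h) (latent count marginalized to the tail tolerance), and one
pooled cell per cohort carries the expected mass of never-observed
histories (observed 0, contributing E to the statistic). No further pooling
is applied. The null distribution comes from simulating histories at the
fitted parameters, refitting, and recomputing; the p-value uses the add-one
convention (1 + #{boot ≥ obs}) / (n_boot + 1) so p is never exactly 0, and
ĉ = observed / mean(bootstrap). Default n_boot is 999; the test-suite and
calibration runs use 99.

## Prediction and population bounds

λ = exp(x′β̄) cell-by-cell from the averaged coefficients, with the training
standardization applied to each grid; urban/water cells are masked to
no-data. Suitability is λ / max(λ) (maximum exactly 1 on any valid
surface). Density classes use lower-inclusive half-open intervals at
thresholds 0.0001, 1.5 and 20 (absent/low/medium/high), and the population
bound multiplies each class area by a conservative density range
(0.05–0.1, 0.1–0.2, 0.15–0.3 individuals/km²). Class products are kept
unrounded; the totals sum the unrounded products and are then rounded —
this order reproduces both the per-class and the total published figures,
which a sum of pre-rounded cells does not (per-class display values are
truncated toward zero, display only). The published class areas themselves
sum to 47,935 km², 5 km² above the separately printed range figure; the
package reports the sum. Rasters are ESRI ASCII grids — a plain-text
format read and written by `occumap.raster` — with λ interpreted as
relative abundance per station-equivalent, not an absolute density.

## The synthetic survey

The generator emulates the structure the estimators assume: 8 survey grids
with (82, 62, 42, 64, 6, 9, 17, 10) stations, deployments drawn uniformly
from 24–65 days opening through a November–April season, 5-day occasions,
i.i.d. station covariates (no spatial autocorrelation — the model assumes
none), Poisson latent abundance on a log link with default coefficients
giving the field pattern (negative elevation and forest effects, a positive
elevation × forest interaction, higher abundance near water and
settlements), a logit-linked per-individual detection probability of ~0.2
per 5-day occasion with site offsets, and raw records that invert the
30-minute rule: one independent trigger per detected occasion placed
uniformly (minute precision) plus Poisson(cluster_rate = 1) clustered
repeats 1–29 min apart, kept ≥ 31 min clear of occasion ends so filtering
and binning reconstruct the simulated histories exactly. It does not
simulate animal movement, home-range structure, camera-placement bias,
spatially correlated covariates, or occasion-varying detection — so
passing recovery tests demonstrate correctness of the estimators under the
model's own assumptions, not robustness to their violation in real
surveys.

## Problem sizes used in tests and the acceptance script

Estimator properties are measured at 300 stations × 8 occasions with 200
replicates (bias, Wald coverage), 292 stations for the RN-vs-MacKenzie AIC
comparison (100 replicates), and 100 stations for GOF calibration (50
replicates × 99 bootstrap draws) — sizes chosen to match the scale of the
motivating survey while keeping a full run on one CPU in minutes. The
published-table arithmetic and likelihood-oracle checks are instantaneous.

## Known limitations

- The RN λ/r pair is weakly identified at few occasions; single fits can
  wander a few SE even though the estimators are unbiased in aggregate.
- Finite-difference Hessians can go non-positive near boundaries (ψ or p
  → 1); SEs are then NaN and the MacKenzie results flag the boundary.
- Buffer means use cell centers, so very small radii relative to the cell
  size reduce to the containing cell's value.
- The GOF statistic's absolute magnitude is large when many distinct
  histories each have tiny expected counts; only its bootstrap-referenced
  p-value and ĉ are interpretable.
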