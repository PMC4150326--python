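# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the design
decisions taken where more than one defensible option existed.

## 1. The two-stage (hurdle) model

Abundance records from compiled multi-study datasets are mostly zeros and
mix measure types (counts, densities, reporting rates), so a single count
likelihood is inappropriate. We therefore model

* **occurrence** — presence/absence of each taxon at each site of its
  study — as a Bernoulli GLMM with a logit link, and
* **abundance given presence** as a Gaussian LMM on the natural log of the
  (effort-corrected) value.

Both stages carry crossed random intercepts for study, site-within-study
(site labels are made unique within study before coding) and taxon.
Non-integer values rule out Poisson-type abundance models; spatial random
fields are out of scope (diagnosed post hoc instead, §6).

### Estimation

The marginal likelihood integrates the random effects out of the joint
density. For the Gaussian stage the integral is available in closed form;
for the Bernoulli stage we use the Laplace approximation around the joint
mode of the random effects — the standard approximation for this model
class. Implementation details that matter:

* The mode is found by Newton iteration with step halving (a single exact
  solve in the Gaussian case); the Hessian `Z'WZ + D^-1` is accumulated by
  index-bincount and Cholesky-factorised densely (random dimension is at
  most a few thousand here).
* The outer optimisation over fixed effects and log-SD variance parameters
  uses L-BFGS-B with **analytic gradients**, including the third-derivative
  terms that flow through the weights and the conditional mode; gradient
  correctness is property-tested against finite differences at 1e-5
  relative. Fits are warm-started from a plain GLM/OLS solution, or from
  the parent model during stepwise selection.
* Everything is **ML, never REML**, so log-likelihoods, LRTs and AICs are
  comparable across fixed-effect structures.
* Variance parameters are optimised as log standard deviations bounded in
  [e^-10, e^6]; a component at the lower bound is a boundary fit (reported,
  not an error). Non-convergence is flagged on the returned object.
* The fixed-effect covariance is the conventional conditional-on-theta
  Wald covariance `inv(X'WX − X'WZ H^-1 Z'WX)`.

Equivalence with lme4 (glmer Laplace / lmer ML) was verified on five small
crossed-design datasets and frozen into the test suite: fixed effects
agree within 1e-3, log-likelihoods within 0.1 (observed agreement is
roughly 1e-4 and 1e-3 respectively).

### Design matrices and selection

Continuous covariates are centred and scaled to unit SD before fitting
(human population density is log(x+1)-transformed first; both are
configurable switches on the model spec). Land use is treatment-coded
against primary forest; group against the first group of the standard
ordering present. Interaction columns that are identically zero (empty
land-use × group cells) are dropped and recorded; contrasts involving them
are reported as missing rather than invented.

Backward stepwise selection tests, at each round, only the terms contained
in no other retained term, drops the least significant with p ≥ α
(ties: the smaller χ² per df), and stops when every droppable term is
significant. Main effects are therefore never tested while an interaction
containing them survives. The reported term table carries each dropped
term's test from its final round; retained interactions get drop-one tests
from the minimum adequate model; main effects are tested in the mains-only
model (all interactions removed), matching the convention of
stepwise-ANOVA tables.

R²_GLMM follows the variance-partition formulation: marginal
= var_fixed / (var_fixed + var_random + var_resid + var_dist) with
var_dist = π²/3 for the binomial-logit stage and 0 for the Gaussian stage;
conditional adds var_random to the numerator. With small datasets,
quasi-separated cells can inflate var_fixed; we report the statistic as
defined and recommend reading it alongside the coefficient table.

## 2. iNDVI (vegetation offtake)

Composites with a non-zero quality flag are discarded and bridged by
linear interpolation on actual calendar day gaps; leading/trailing gaps
take the nearest retained value (constant extension — the least
assumption-laden choice for edges). iNDVI is the integral of
`v(t) − min v(t)` over the three calendar years up to and including 31
December of the study's last sampling year (floored at 2002 so early
studies still get a full record), computed by the trapezoidal rule on the
composite grid — exact for the piecewise-linear interpolant, and verified
against a 1-day Riemann sum to 1e-6 relative. Units are NDVI·days. iNDVI
is non-negative, zero only for constant windows, and invariant to adding a
constant to the series.

Unflagged cloud contamination appears as isolated abnormally-low
composites. The screen flags composite *i* when it lies more than k = 5
MADs below the series median while both neighbours are within 1 MAD of it
(sustained lows are never flagged). The default response re-interpolates
the flagged composites; a drop-site mode is available for analyses that
prefer to discard the whole series. Note the 1-MAD "quiet neighbour"
condition is deliberately strict: under Gaussian noise each neighbour is
quiet only about half the time, so the screen favours precision over
recall.

## 3. Preprocessing

* **Effort correction**: measures assumed proportional to effort
  (abundance, group abundance) are rescaled to the study's maximum effort;
  the study-level scale constant is absorbed by the study random intercept
  on the log scale, so the choice of within-study reference is cosmetic. A
  marker column prevents double correction.
* **Occurrence derivation**: a taxon recorded with a positive value
  anywhere in a study contributes one presence/absence row at every site
  of that study; taxa never positive in a study contribute nothing (no
  inferable absences), and single-site studies contribute no absences at
  all.
* **Range classification**: area of occupancy is the summed spherical area
  of distinct half-degree cells containing occurrence points (cells
  half-open, aligned to integer + 0/0.5 boundaries; boundary points go
  north-east). Taxa strictly above their group's median AOO are
  wide-ranged; ties go to narrow.
* **Specialists**: birds are forest specialists iff forest habitat is of
  'major' importance; mammals iff habitat breadth is 1; everything else is
  unknown and stays unsplit in trait analyses.

## 4. Phylogenetic-signal diagnostics

The taxonomy tree is built from ranked hierarchy paths (one internal node
per distinct rank/name; conflicting parentage is an error; unifurcations
are kept — they carry zero-length branches under Grafen heights and do not
affect the covariance). Grafen heights are descendant-leaf counts minus
one, scaled to root height 1 (power ρ = 1); the tree is exactly
ultrametric with depth 1.

Record-level residuals (deviance residuals for occurrence, response
residuals for abundance — both conditional on the BLUPs) are averaged per
taxon and fed to Pagel's λ: a Gaussian model with covariance
`σ²[λ(V − diag V) + diag V]`, V the Brownian covariance implied by the
tree. Mean and scale are profiled analytically; λ is maximised on [0, 1]
by bounded search (tolerance 1e-6) on the eigendecomposition of V, with
endpoint candidates checked explicitly. The LRT against the star tree
(λ = 0) uses the χ²₁ upper tail — conservative at the boundary; a 50:50
mixture reference is available but off by default. Duplicate zero-distance
leaves at λ → 1 get a 1e-10 ridge.

Because the fitted taxon random intercept already absorbs most
between-taxon structure, residual λ estimates are attenuated relative to
the λ used to simulate the taxon effects; the diagnostics' calibration is
therefore tested on traits simulated directly on trees, and the residual
pathway is tested for null calibration.

## 5. Spatial diagnostics

Per study, site-averaged residuals are tested with Moran's I under
inverse great-circle-distance weights, row-standardised, zero diagonal,
with a 1 m distance floor for coincident sites (k-nearest weights, k = 4,
are an alternative). Moments are the classical randomisation-assumption
formulas; the p-value is two-sided normal. The variance formula requires
n ≥ 4 sites; n = 3 yields the statistic and expectation only, and
constant-residual or smaller studies are skipped with the reason logged.

The meta-test counts studies with p < α and compares the count with
Binomial(n, α), one-sided. Because this test is discrete, the report
carries both the exact p and the mid-p variant; calibration checks of
uniformity use the randomised p-value P(X > k) + U·P(X = k), the only
version that is exactly Uniform(0, 1) under the null. Studies flagged at
α are dropped and the selected models refitted, with a side-by-side
coefficient comparison; contrasts whose design columns vanish with the
dropped studies are reported as undefined.

## 6. The synthetic-data generator

The generator emulates the hierarchical structure the analysis assumes,
with every parameter known:

* 20 studies of 10–50 sites (≈600 sites) by default; each study samples
  one taxonomic group (drawn with shares 0.55/0.10/0.06/0.29 for
  invertebrates/herptiles/mammals/birds) and one measure type
  (≈92% plain abundance), and a 10–30-taxon subset of its group's pool
  (400 taxa total by default — a deliberate scale-down of the
  thousands-of-taxa situation the structure mimics, keeping desk-scale
  fits tractable; all counts are configurable).
* Site land use is multinomial with probabilities proportional to the
  published per-class site tallies; forest cover, human population density
  and the latent offtake level are drawn with land-use-dependent means, so
  pressures are realistically confounded with land use.
* NDVI series are 16-day composites over three-plus years: baseline +
  seasonal sine + triangular harvest dips whose depth is offtake ×
  `offtake_depth`, plus Gaussian noise, flagged cloud drops (qa ≠ 0) and
  unflagged spikes. The site's true iNDVI is computed from the noise- and
  contamination-free latent series *by the same integrator the pipeline
  uses*, so recovery error isolates contamination handling.
* Occurrence is Bernoulli on the logit scale with group × land-use
  offsets (primary forest exactly 0), per-SD slopes on the standardised
  pressures, and study/site/taxon random intercepts; the occurrence
  intercept is calibrated by root-finding so the realised expected
  presence fraction hits the target (0.26 by default). Abundance given
  presence is log-normal; recorded value = abundance × effort for
  effort-sensitive measures. Taxon effects are drawn on the taxonomy tree
  with a Pagel transform at `lambda_true` (0.1 by default).
* Occurrence points for range classification scatter around a taxon
  centre with spread equal to the taxon's true range width; the habitat
  table encodes the specialist truth the way real trait sources would.
* All randomness flows from one root seed through four named
  `SeedSequence` children (world, studies, observations, points);
  identical configs give byte-identical output files.

What the generator does **not** emulate: biogeography (site and range
positions are arbitrary), detection processes (presence is observed
without error), species interactions, temporal turnover, and real MODIS
noise structure. Passing tests therefore demonstrate that the *estimators
and diagnostics* behave as designed under the assumed data-generating
process — not that the assumptions hold for any particular real dataset.

## 7. Simulation sizes in the test suite

The calibration and recovery tests run at reduced but pre-registered
sizes chosen once: 15 replicates at generator defaults for contrast
coverage and variance-component recovery; 10 replicates of a 20-study
design with divergent group × land-use truth for selection consistency;
600 null replicates of a 6×6×6 LMM for the LRT type-I rate; 30 replicates
on 300-tip trees for λ recovery and 200 for the boundary LRT; 200
pipeline replicates of 200 studies for meta-test calibration. The
acceptance script uses a 16-study, ~330-site configuration. These are the
package's default desk-scale study conditions; all are configurable.

## 8. Known limitations

* The Laplace approximation biases binomial variance components (and,
  mildly, contrast SEs) downward at few grouping levels; with 20 studies
  the study SD is typically underestimated by 10–25%.
* Wald coverage of land-use contrasts is near-nominal only for cells the
  data identify; separated cells produce flat likelihood directions whose
  estimates are reported but not interpretable.
* R²_GLMM inherits var(Xβ)'s sensitivity to quasi-separated coefficients
  in small datasets.
* The stepwise χ² tests are conditional on the selection path; the term
  table is a description of the path, not simultaneous inference.
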