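# Methods

## Linear diffusion of pathology on the connectome

Regional pathology is modelled as a linear dynamical system on the directed
connectome. With `A[i, j] ≥ 0` the projection strength from region `i` to
region `j` and `L = D_out − A` the out-degree Laplacian (`D_out` the diagonal
of row sums), the prediction from a seed vector `x₀` is

    x̂(t) = e^{−c t Lᵀ} x₀.

Written with a row vector this is exactly `x̂(t)ᵀ = x₀ᵀ e^{−cLt}`; we apply
the orientation in which the all-ones vector is a left null vector of the
generator, so the total seeded mass is conserved and pathology flows along
edges `i → j`. Conservation is a physical requirement for a redistribution
model and doubles as a stringent numerical check (asserted to 1e−10 relative
error on every call). Anterograde spread uses `A` as stored, retrograde
spread `Aᵀ`; because tract-tracing intensity does not by itself fix which
orientation is "anterograde", the stored-matrix convention is an explicit
configuration switch (`direction_convention`) rather than a silent
assumption. The Euclidean variant replaces `A` with a symmetric
inverse-distance kernel `1/d_ij` on region centroids (an exponential kernel
`exp(−d/λ)` is available); coincident centroids are rejected.

The matrix exponential is evaluated through a cached eigendecomposition of
the generator (O(N²) per rate value after one O(N³) factorisation), enabling
dense rate grids and large null ensembles; whenever the eigenbasis is
ill-conditioned (defective graphs such as directed chains) or the
mass-conservation check fails, the propagator falls back to scipy's
scaling-and-squaring `expm`. Negative entries smaller than 1e−12 in
magnitude — numerical dust from the exponential — are clipped to zero.

### Rate fitting

`c` (per month) is the only free parameter; the horizon is fixed at `t = 3`
months and only the product `c·t` is identified, so centroid/weight units
merely rescale the reported `c`. The fit criterion is the Pearson
correlation between `log10(x + ε)`-transformed prediction and observation,
with `ε` the smallest positive observed value. Regions with zero or missing
observation are excluded from the correlation (prediction zeros are retained
via `ε`); seed regions are excluded by default because their values are
imposed rather than predicted (configurable). The search is a 200-point
log-spaced grid over [1e−4, 1e2] followed by bounded scalar refinement around
the grid optimum — deterministic by construction. Degenerate inputs
(constant observation, fewer than three eligible regions, predictions
constant at every rate) raise typed errors instead of returning spurious
optima.

## Combined regression and tdT interaction

The combined model regresses transformed observed pathology on the three
spread predictions (optionally plus tdT⁺ density). All variables pass
through the same `log10(x + ε)` transform; predictors are z-scored. Two
coefficient scales are reported by the same fit:

* `betas` — response additionally z-scored: fully standardized weights, the
  scale on which groups are compared and beta ratios (a:r, e:r, a:e) formed;
* `coefs` — response left in transformed units: the generative scale, i.e.
  the coefficients a simulation with known weights is recovered on.

The two differ only by the factor `sd(response)`, which cancels in every
ratio and in between-group contrasts of the same statistic; reporting both
avoids conflating a normalisation convention with the estimand. Ratios with
a denominator below 1e−8 in magnitude are flagged undefined rather than
returned as ±∞.

The interaction model is fitted per genotype on (region × treatment) rows:
response is the regional mean pathology, predictors are the three spread
predictions, z-scored tdT density, treatment (Sal = 0, PTZ = 1) and
tdT × treatment. With this coding the tdT simple slope is `b_T` in the Sal
group and `b_T + b_{T×PTZ}` in the PTZ group; standard errors come from the
coefficient covariance (delta method) with two-sided t-tests. Partial
residuals for the tdT term (`residual + b_T·tdT + b_{T×PTZ}·tdT·treat`)
regress within each treatment group to exactly the corresponding simple
slope — an identity the test suite asserts.

Region-wise Pearson screens against per-mouse behavioural covariates report
(r, p, n) per region, skipping regions with fewer than three complete pairs;
multiplicity adjustment is left to the caller (the Benjamini–Hochberg helper
is `fdr_adjust`), since screens of this kind are reported both adjusted and
unadjusted in practice. The seizure-severity AUC is the sum of the 15
per-minute maximal Racine scores (1-minute rectangular rule; trapezoid
optional), giving a 0–90 range.

## Bootstrap inference and the seed-specificity null

Uncertainty in fit correlations and beta weights is mouse-level: mice are
resampled with replacement within each genotype × treatment group, regional
means recomputed, and the statistic re-evaluated (B = 1000 by default;
resamples where the statistic is unfittable are excluded and counted, never
imputed). Two bootstrap distributions are compared with a two-tailed sign
test on paired differences,

    p = 2 · min( P̂(Δ ≤ 0), P̂(Δ ≥ 0) ),  P̂ with a +1/(n+1) correction,

capped at 1, so identical distributions give p = 1 and complete separation
the minimum attainable 2/(n+1). Index-matched pairing is the default;
all-pairs pairing is available. Benjamini–Hochberg adjustment is applied per
comparison panel.

Seed specificity re-fits the model from `n_sets` random region sets of the
same cardinality as the experimental seed whose spatial clustering — mean
pairwise centroid distance by default, max pairwise optional — lies within
±20 % (configurable) of the experimental set's. Sets are rejection-sampled
uniformly (vectorised, hard-capped at 10⁶ proposals with an informative
error when the pool is exhausted), never duplicate one another or the
experimental set, and the reported percentile is the fraction of null fits
strictly below the experimental fit.

A calibration subtlety: the experimental seed defines the centre of the
matching band, while null sets spread across it, so the experimental seed is
*not* exactly exchangeable with the null ensemble — its percentile is mildly
anti-conservative when the data were in fact generated by a random matched
set. The calibration study therefore evaluates the percentile of an
arbitrary matched seed (exchangeable with the nulls by construction), maps
ranks to continuous percentiles with the randomised probability integral
transform, and verifies uniformity by Kolmogorov–Smirnov. The specificity
study — data generated from the experimental seed itself — evaluates the
experimental seed exactly as the analysis would.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every fixture a pure function of (parameters, rng_seed):

* **Geometry and connectome.** `N` centroids uniform in a 3-D box
  (default 8 mm); a directed edge `i → j` exists with probability
  `density^(1 + d_ij/(extent/2))` — distance-decaying, complete at
  density = 1 — with log-normal weights. An `asymmetry` parameter blends a
  shared symmetric edge process (0 → exactly symmetric matrix) with
  independent directed draws (1). Weights are normalised to unit maximum
  out-degree so rates of order 0.1–1 per month yield *partial* spread over a
  3-month horizon — the informative regime; without normalisation the system
  is effectively equilibrated and the rate unidentifiable. A two-level toy
  hierarchy (parents of ~5 leaves under one root) supports aggregation
  tests; the first four leaves are labelled DG, CA1, CA3, PTLp, with the
  hippocampal triplet placed close together as the injection sites are.
* **Pathology.** Per group, mean log10 pathology is the configured mixture
  `s = β_a z_a + β_r z_r + β_e z_e + β_T τ` of z-scored log spread
  predictions and a latent activity field `τ ~ N(0, 1)`; the mixture is
  mapped to density units using the log moments of the dominant spread mode,
  so a pure single-mode noiseless cohort reproduces that mode's prediction
  exactly. Per-mouse values multiply the regional mean by log-normal noise
  (σ = 0.25 by default) — pathology densities are positive and right-skewed.
* **tdT.** `10^(1.5 + τ)` with its own log-normal noise, so the partial
  association between log tdT and log pathology given the spread predictors
  equals the configured group slope. tdT is a cause-agnostic correlate: the
  generator tests association recovery, not causal direction.
* **Behaviour.** A latent severity with configurable correlation to
  target-region pathology drives the NOR % novel time (affine) and the 15
  per-minute Racine scores (scaled canonical seizure profile, integer-clipped
  to 0–6), so the Racine AUC inherits the correlation approximately.
* **Defaults.** 100 regions, 10 mice per genotype × treatment (within the
  observed 6–15 range), retrograde-dominant weights with an increased
  anterograde share in the 5X genotype and a tdT slope in every group except
  WT-PTZ — the qualitative structure the pipeline is meant to detect.

What passing tests on these data do *not* show: the generator has no
hemispheric mirroring, no regional vulnerability differences, no nonlinear
aggregation or clearance kinetics, no spatial autocorrelation of noise, and
its geometry is a uniform box rather than a brain; conclusions about real
tissue rest on the experimental design, not on these simulations.

## Study sizes and numerical choices

Validation studies run at: 50 random graphs (N ≤ 10) for the ODE oracle;
100 replicates at N = 50 for rate recovery (σ = 0.25) and direction
identifiability (asymmetry 0.6); 200 replicates at N = 100 for beta recovery
(σ = 0.1); 200 replicates at N = 150 regions for interaction power/type-I;
200 replicates with 100-set ensembles for null calibration and 50 runs for
specificity — sizes chosen so the whole battery completes in a few minutes
on one CPU while keeping Monte-Carlo error well below the margins being
asserted. The seed-null studies use the two injection *sites* (DG + PTLp)
as the matched reference: the tightly clustered four-subregion seed admits
almost no spatially matched 4-subsets in a small uniform-box atlas, whereas
the two-site pool is ample.

Known limitations: only `c·t` is identified; the bootstrap comparison treats
draws as paired by index (a design choice — the underlying draws are
independent); OLS inference on group means ignores region-level spatial
correlation; and the pairing of tract-tracing intensity to spread direction
is a convention the data cannot resolve.
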