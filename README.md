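# tauspread

Connectome-based modelling of pathological tau spread in the mouse brain:
linear network diffusion from seed regions, multivariate combination of
anterograde / retrograde / geometric spread predictions with neuronal-activity
(tdT⁺) density, mouse-level bootstrap model comparison, and spatially matched
random-seed null models — with a first-class synthetic-data generator so the
whole pipeline can be exercised end to end against known ground truth.

## The problem

After intracerebral injection of misfolded tau, pathology propagates along
neuroanatomical connections. Whole-brain imaging yields, per mouse and per
atlas region, a density of AT8⁺ tau aggregates (objects/mm²), and — in
activity-reporter (TRAP) crosses — a density of tdT⁺ neurons labelled during a
defined activity window. The modelling questions this package addresses:

* does the regional pattern of pathology follow the directed structural
  connectome (and in which direction), or mere spatial proximity?
* how much does each mode of spread contribute, and does that differ between
  genotypes (WT vs. amyloid 5X) or treatments (saline vs. PTZ seizure
  kindling)?
* is regional neuronal activity (tdT⁺ density) predictive of pathology over
  and above connectivity-based spread?
* is the model's performance specific to the experimental seed regions?

## The model

Pathology `x(t)` over `N` regions evolves linearly on the connectome
`A` (entry `A[i, j]` = projection strength from region `i` to region `j`):

```
x̂(t) = e^{−cLt} x₀ ,   L = D_out − A  (out-degree Laplacian)
```

with `x₀` placing one unit of pathology in each injection site (dentate
gyrus, CA1, CA3, posterior parietal association area — PTLp), horizon
`t = 3` months, and free rate `c` fitted by maximising the spatial Pearson
correlation between log-transformed prediction and observation. The
propagator is applied in the mass-conserving orientation (the all-ones vector
is a left null vector of the generator), so the seeded mass is redistributed
along edges, never created or destroyed. Anterograde spread uses `A` as
stored, retrograde its transpose, and a Euclidean variant replaces `A` with an
inverse-distance kernel on region centroids.

The per-mode predictions are then combined in the "Bidirectional Euclidean
(+ tdT)" regression

```
x(t) = β_a x̂_a(t) + β_r x̂_r(t) + β_e x̂_e(t) + β_T T + ε
```

with standardized beta weights and their ratios (a:r, e:r, a:e) compared
between groups via a mouse-level bootstrap and a two-tailed non-parametric
test with Benjamini–Hochberg FDR correction. A per-genotype interaction model
adds treatment and tdT × treatment terms; tdT simple slopes per treatment and
partial-residual tables visualise activity's adjusted contribution. Seed
specificity is assessed by re-fitting the model from hundreds of random seed
sets whose spatial clustering matches the experimental sites.

## Worked example

```python
import numpy as np
from tauspread import (make_ground_truth, simulate_cohort, fit_rate,
                       fit_combined, beta_ratios, regional_means,
                       random_seed_null, SeedSpec)

gt = make_ground_truth(n_regions=100, rng_seed=42)      # known ground truth
cohort = simulate_cohort(gt, n_mice=10, rng_seed=43)    # per-mouse regional data
sub = cohort[(cohort.genotype == "WT") & (cohort.treatment == "Sal")]
observed = regional_means(sub, gt.regions)

for mode in ("anterograde", "retrograde", "euclidean"):
    f = fit_rate(gt.connectomes[mode], gt.seed, observed, t=3.0)
    print(f"{mode:11s}  c_hat={f.c_hat:6.3f}  fit_r={f.fit_r:5.3f}  n={f.n_used}")

fit = fit_combined(observed, gt.predictions())
print("betas  ", {k: round(v, 3) for k, v in fit.betas.items()})
print("ratios ", {k: round(v, 3) for k, v in beta_ratios(fit).items()})

sites = gt.atlas.resolve_acronyms(("DG", "PTLp"), within=gt.regions)
ens = random_seed_null(gt.atlas, gt.connectomes["retrograde"], observed,
                       SeedSpec(sites=tuple(sites)), n_sets=200,
                       tolerance=0.2, rng_seed=7)
print(f"null: true fit_r={ens.true_fit:5.3f}  "
      f"percentile={ens.percentile_of_true:.3f}")
```

prints

```
anterograde  c_hat= 0.475  fit_r=0.540  n=96
retrograde   c_hat= 0.650  fit_r=0.878  n=96
euclidean    c_hat= 4.324  fit_r=0.395  n=96
betas   {'anterograde': 0.144, 'retrograde': 0.672, 'euclidean': 0.238}
ratios  {'a:r': 0.215, 'e:r': 0.354, 'a:e': 0.606}
null: true fit_r=0.619  percentile=1.000
```

The synthetic cohort was generated with retrograde-dominant spread
(true weights 0.2 / 0.6 / 0.2), so the retrograde model fits best
(`fit_r = 0.878`), the combined model's largest standardized weight is
retrograde, and the experimental seed outperforms all 200 spatially matched
random seed sets (percentile 1.000).

The same steps are available from the shell:

```bash
spread simulate --out data/ --rng-seed 42
spread fit --connectome data/connectome.csv --atlas data/atlas.csv \
           --cohort data/cohort.csv --mode retrograde --genotype WT --treatment Sal
spread run-all --out runs/demo --simulate --rng-seed 42
```

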