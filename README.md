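# isoniche

Isotopic-niche analysis for benthic invertebrate communities of
agricultural small water bodies (ponds and ditches), with the
ecotoxicological context needed to relate niche structure to
agricultural stressors.

The package is aimed at community ecologists working with stable
isotope data (δ¹³C, δ¹⁵N) of macroinvertebrates sampled from ponds and
drainage ditches in farmed landscapes, where two field signals overlay
the trophic structure: organic fertilizer enriches δ¹⁵N in ditches, and
maize (a C4 plant) enriches δ¹³C of consumers in ponds bordering maize
fields.

## What it computes

**δ corrections.** δX = (R_sample/R_standard − 1)·10³ converts raw
isotope ratios to per-mil values (VPDB for carbon, atmospheric air for
nitrogen). Two pure-translation corrections align pooled consumer
means: the ditch-minus-pond mean δ¹⁵N difference is subtracted from
ditch samples, and the maize-pond-minus-reference-pond mean δ¹³C
difference from maize-pond samples.

**Layman metrics.** For a community's point cloud in (δ¹³C, δ¹⁵N)
space: δ¹³C range, δ¹⁵N range, TA (convex-hull area, ‰²), CD (mean
distance to centroid), MNND (mean nearest-neighbour distance) and
SDNND (SD of nearest-neighbour distances).

**Bayesian standard ellipses.** Each group is modelled as bivariate
normal with a conjugate Normal–Inverse-Wishart prior; the posterior of
(μ, Σ) is sampled directly. The standard ellipse area
SEA(Σ) = π√det Σ covers 1 − e^(−1/2) ≈ 39.35 % of the population;
SEAc = SEA·(n−1)/(n−2) corrects the point estimate for small n, and
SEA.B (the posterior of SEA) is summarized by its KDE mode and 50/75/95 %
highest-density intervals. Community-level "Layman.B" metrics are the
Layman metrics of the member groups' posterior centroids, draw by
draw. Welch's unequal-variance t-test compares groups.

**Niche overlap.** Maximum-likelihood ellipses (mean, ML covariance,
coverage p via the χ²(2) quantile q(p) = −2 ln(1−p)) are intersected by
adaptive quadrature; overlap is reported as an area and as proportions
(over the union, and over each ellipse's own area).

**Toxic units.** TU_sum = log₁₀ Σᵢ Cᵢ/EC50ᵢ over detected pesticides,
using the most sensitive endpoint per substance and organism class
(invertebrates or algae), with sub-LOQ detections entering at half the
LOQ; plus per-type summaries of detection counts and NH₄⁺+NO₃⁻
nutrient sums.

**Ordination.** Per-site Layman metric matrices are linked to z-scaled
environmental variables by exhaustive BIOENV subset selection (Spearman
rank correlation against a Mahalanobis dissimilarity) and dbRDA (Gower
double-centering, constrained/residual eigendecomposition) with
permutation tests of the model, its terms and its axes.

**Synthetic data.** A scenario generator draws per-(site × FFG)
bivariate-normal clouds with injected fertilizer/maize offsets and
simulates water chemistry with Bernoulli pesticide detections, so every
stage is testable closed-loop against known ground truth. The
survey-shaped preset reproduces the published per-group sample counts
exactly.

## Worked example

```python
import numpy as np
from isoniche import fit_bivariate_posterior, layman_all, sea_metrics
from isoniche.layman_metrics import PointSet2D

rng = np.random.default_rng(4)
cloud = PointSet2D(
    rng.multivariate_normal([-28.0, 6.0], [[2.0, 0.5], [0.5, 1.0]], size=50),
    label="grazer_scraper@Pond 1",
)
print(layman_all(cloud))
ens = fit_bivariate_posterior(cloud, n_draws=10_000, seed=1)
print(sea_metrics(cloud, ens))
```

prints (abridged, from `examples/02_layman_and_bayesian_niches.py`):

```
Layman metrics: dC range 5.74 permil, dN range 5.05, TA 19.35 permil^2,
                CD 1.49, MNND 0.34, SDNND 0.28
SEAc = 4.30 permil^2 (n = 50)
SEA.B mode = 4.03, 95% HDI [3.03, 5.29]
true SEA = 4.16 permil^2
```

The cloud was drawn from a covariance whose true standard-ellipse area
is π√det Σ ≈ 4.16 ‰²; the SEAc point estimate (4.30) and the SEA.B
posterior mode (4.03) both track it, and the 95 % highest-density
interval quantifies the sampling uncertainty at n = 50.

The `examples/` directory holds one short script per capability
(counts and corrections, niches, overlap, toxic units, ordination, and
the full pipeline via `isoniche.pipeline.run_pipeline`).

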