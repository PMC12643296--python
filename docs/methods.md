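# Methods

This note documents the models and numerical choices behind
`isoniche`, the assumptions they rest on, and what the synthetic
scenarios do and do not establish about real field data.

## Data model and accounting

The unit throughout is the *analyzed sample*: one tin capsule, which
may pool several small individuals of one family. Samples carry a
site, a water-body type (pond or ditch), one of six functional feeding
groups (collector/filterer, collector/gatherer, grazer/scraper,
omnivore, predator, shredder) and a (δ¹³C, δ¹⁵N) pair in ‰ (VPDB /
atmospheric air). FFG labels are normalized through a fixed synonym
dictionary; unknown labels are errors rather than guesses, because a
silent misassignment would move a sample between niche groups.
Column names are matched case-insensitively against a synonym map
(`d15N`/`δ15N`/`delta15N`), since field spreadsheets vary.

Count summaries divide FFG-subset totals by the number of sites of the
type, so a "mean per site" of primary consumers is comparable across
types with different site counts. The minimum-group-size filter
(default: fewer than 3 analyzed samples, strictly below) can act at
site × FFG or type × FFG level; it is idempotent and reports what it
dropped.

## Offset corrections

Both corrections are pure translations of one stratum on one axis:

* **fertilizer (δ¹⁵N):** pooled consumer mean per water-body type,
  ditch mean minus pond mean subtracted from every ditch sample;
* **maize (δ¹³C):** pooled consumer mean over the named maize ponds
  minus the pooled mean over the remaining ponds, subtracted from the
  maize-pond samples.

Means are unweighted over analyzed samples (not over sites or FFGs),
and "consumers" includes all sampled invertebrates, omnivores too —
with no stated exclusion there is no defensible line to draw.
Translations preserve within-group variances, all pairwise distances
inside the corrected stratum, and the untouched axis, so every
covariance-based quantity downstream is unaffected except through
between-stratum geometry — which is the point of the correction.

A consequence worth knowing: the pooled-mean estimator recovers the
*injected* offset only when the two strata have the same FFG
composition. In the survey-shaped scenario the ditch FFG mix differs
from the pond mix, so the recovered δ¹⁵N offset is the injected 3.5 ‰
plus a compositional term (≈ 0.38 ‰ for the preset's centers and
counts). Recovery tests therefore use a composition-balanced scenario;
the survey-shaped preset shows the estimator doing what it would do on
real data — removing the *observed* pooled difference.

The pipeline keeps two correction states, because different analyses
consume different ones: δ¹⁵N-only for community-level Bayesian Layman
metrics and the ordination (fertilization is a general phenomenon,
while the carbon source is real resource-use signal), and
δ¹⁵N + δ¹³C for FFG-level ellipse comparison and the second overlap
column. Applying the same correction twice is mechanically allowed but
warns, since it is only a no-op when the means already coincide.

## Layman metrics

The six metrics are computed exactly as their definitions read: ranges
as max − min per axis; TA as the convex-hull area (Qhull, zero for
degenerate clouds); CD as the mean Euclidean distance to the centroid;
MNND/SDNND over each point's nearest *other* point, with SDNND using
the sample SD (n − 1), matching the conventional implementations the
literature compares against. Duplicate coordinates are allowed and can
give zero nearest-neighbour distances. A single point yields all-zero
metrics with a warning rather than an error, so degenerate groups
surface in outputs instead of crashing batch runs.

## Bayesian niche model

Each group's cloud is modelled as bivariate normal with a conjugate
Normal–Inverse-Wishart prior:

μ0 = sample centroid, κ0 = 10⁻³, ν0 = 3, Ψ0 = I (‰²).

The posterior is NIW in closed form and is sampled *directly*
(Σ ~ InvWishart(νn, Ψn), μ|Σ ~ N(μn, Σ/κn)); no MCMC, burn-in or
convergence diagnostics are needed, and in this vague-prior regime the
posterior is the one a Gibbs sampler over the same model would target.
Centering the prior mean at the data centroid with negligible weight
κ0 makes the prior mean-neutral while keeping the update proper.
Default n_draws = 10 000; the pipeline uses 2 000 where many groups are
fitted. Groups of n = 3 are fitted but warn: with ν0 = 3 the prior
contributes as much as the data and the posterior ellipse is mostly Ψ0.

SEA(Σ) = π√det Σ is the 1-SD ellipse area (population coverage
1 − e^(−1/2) ≈ 39.35 %). SEAc multiplies the n−1 sample-covariance SEA
by (n−1)/(n−2); the ML ellipse used for overlap deliberately uses the
n denominator — both conventions are implemented and documented where
they apply.

Posterior summaries: the mode is the argmax of a Gaussian KDE
(scipy's Scott-type bandwidth) on a 2048-point grid, which matches
density-plot modes without binning artifacts; credible intervals are
highest-density intervals computed as the shortest contiguous window
of the sorted draws. HDIs at 50/75/95 % are forced nested by a
monotone envelope — a no-op for the unimodal posteriors arising here,
a guard for pathological multimodal inputs. Fewer than 1 000 draws
triggers a warning rather than a failure.

Community-level "Bayesian Layman" metrics are computed over *group
posterior-centroid draws*: for draw j, the member groups' μⱼ form a
point cloud whose six metrics give one posterior draw per metric. This
is the group-centroid convention of the standard ellipse-based niche
framework; it measures spacing of group niches, not of individuals.
Welch's t-test (Welch–Satterthwaite dof, two-sided, 95 % CI) is
exposed for comparing metric samples either at the draw level or the
group level; the package asserts neither as the only valid choice.

## Ellipse overlap

Ellipses are {x : (x−c)ᵀΣ⁻¹(x−c) ≤ q(p)}, q(p) = −2 ln(1−p). For the
overlap the plane is mapped so the first ellipse becomes the unit disk
(Cholesky of Σ₁·q(p)); the second remains an ellipse, the intersection
is convex, and its area is a 1-D adaptive quadrature (scipy `quad`,
relative tolerance 10⁻⁴) of the cross-section length, scaled back by
the Jacobian. Working in the disk frame removes conditioning problems
for eccentric ellipses. The quadrature's achieved error is checked and
a failure raises rather than silently returning a poor value.

Because a single printed "overlap %" is ambiguous, three
normalizations are always reported: overlap/union (Jaccard),
overlap/area₁ and overlap/area₂.

## Toxic units and water chemistry

TU_sum = log₁₀ Σ Cᵢ/Eᵢ with Eᵢ the *minimum* (most sensitive) endpoint
per substance within the organism class. Sub-LOQ detections enter at
LOQ/2. Zero detections return a sentinel (no toxic pressure), not −∞
and not 0 — 0 would mean "as toxic as the endpoint level". A detected
substance without an endpoint is a hard error naming the substance.
Nutrient sums are NH₄⁺ + NO₃⁻ only (PO₄³⁻ and NO₂⁻ are carried in the
data model but excluded from the sum); per-type SDs use n−1 and are
missing, not zero, for single-site types. Note the published ditch
nutrient-sum SD is 0.70 while the sample SD of the printed column is
≈ 0.67; the package computes from its inputs.

## Ordination

Environmental variables are z-scaled (mean 0, sample SD 1; constant
columns are fatal). The response dissimilarity for community metrics
is Mahalanobis: Euclidean distance after whitening columns by the
inverse square root of the column covariance. With ~as many metrics as
sites that covariance is singular; the default whitens with the
Moore–Penrose pseudo-inverse (eigenvalue tolerance
`max(dim)·eps·λmax`) and warns, while `strict=True` raises instead of
hiding the rank deficiency.

BIOENV exhaustively scores every non-empty variable subset (≤ 20
variables) by the Spearman correlation (average ranks on ties) between
the subset's Euclidean inter-site distances and the response
dissimilarity. dbRDA Gower-centers −½D∘D, splits it by the hat matrix
of the centered constraints, and eigendecomposes both parts;
eigenvalues and subset selection were cross-checked against an
independent constrained-ordination implementation and against a
regress-then-PCA oracle for Euclidean inputs. Negative eigenvalues
(impossible for the metric inputs used here up to rounding) are
clipped at zero with a warning. Permutation tests use the pseudo-F
(constrained/q over residual/(n−q−1)) under free row permutation —
no blocked design is modelled — with p = (1 + #{F* ≥ F})/(1 + n_perm);
terms are tested sequentially and axes marginally. Which variables an
analyst excludes before dbRDA (e.g. conductivity and O₂ as too
volatile over a day) is configuration, not code.

## Synthetic scenarios

Each (site × FFG) group draws from its own random stream derived from
the scenario seed plus the group key (CRC32 of the names folded into a
`SeedSequence`), so adding a site never changes other sites' draws.
The survey-shaped preset uses the published per-group sample counts
(so count arithmetic is exact), FFG-typical niche centers (C3 carbon
around −28 ‰, ~1.5–3.5 ‰ δ¹⁵N steps from primary consumers to
predators), a common covariance ((1.5, 0.3; 0.3, 1.0) ‰²), a +3.5 ‰
ditch δ¹⁵N offset and a +8 ‰ maize δ¹³C offset on Pond 3 — magnitudes
a field scientist would call realistic for heavy organic fertilization
and a C3→C4 source shift. Chemistry uses Bernoulli detections with
lognormal concentrations (some forced below LOQ to exercise the
half-LOQ rule) and emits the matching endpoint table.

What the generator does *not* emulate: non-normal niche shapes,
within-site spatial structure, correlated detection of co-applied
pesticides, seasonal dynamics, and any dependence of isotope values on
chemistry. Passing tests therefore establish that the estimators
recover what they are defined to estimate under the model's own
assumptions — not that those assumptions hold in any particular field
system.

## Problem sizes and determinism

Default test and acceptance runs use deliberately modest sizes chosen
as the smallest that keep Monte-Carlo error well below the asserted
tolerances: 1 000–10 000 posterior draws, 20 replicates for recovery
checks, 99–999 permutations, 150 000–400 000 Monte-Carlo points for
area oracles, 200 replicates for the type-I-error check. Every random
stage takes an explicit seed and is bitwise reproducible under it;
the pipeline manifest records a checksum per output table so re-runs
can be compared mechanically.

## Known limitations

* The NIW sampler assumes bivariate normality per group; heavy-tailed
  or multimodal niches will mislead SEA-based widths (as they would
  any standard-ellipse analysis).
* Sample-based HDIs are noisy below ~1 000 draws; the package warns
  but does not refuse.
* Mahalanobis dissimilarity under pseudo-inverse whitening depends on
  the numerical rank decision when metrics ≈ sites; `strict` mode
  exists precisely to expose this.
* The overlap routine assumes proper ellipses (SPD covariance);
  degenerate (collinear) groups must be filtered out upstream, which
  the pipeline does via its minimum-group-size and variance checks.
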