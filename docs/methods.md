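# Methods

This note documents the models behind `assemblage`, the defaults of the
synthetic-data generator, the numerical choices, and what validation on
synthetic data does and does not establish about field data.

## Data model

The pipeline operates on three aligned tables: a samples × taxa read-count
matrix with a sample→site map, a samples × variables geochemistry table
(salts in ppm, NH₃ in ppb, gravimetric moisture as a fraction), and
per-sample coordinates (decimal-degree lat/lon or projected km). Samples
below a read-depth threshold (default 586 reads) are removed, and taxa left
with zero totals are dropped. ASV tables can be aggregated to phylum level
by summing counts within phyla (unmapped ASVs pool into an "Unassigned"
bucket); filtering and aggregation commute because aggregation conserves
row totals. Geochemical values at or below zero (below-detection) are
replaced by half the variable's smallest positive value, with a warning,
before any log transform.

## Rarefaction

Richness is standardised to a common depth n\* by the binomial
("asymptotic") expectation Σᵢ(1 − (1 − Nᵢ/N)^n\*), summed over taxa with
Nᵢ > 0. This is the with-replacement approximation to the hypergeometric
(without-replacement) expectation: the two agree closely when n\* is small
relative to N or when all counts are well above 1/(n\*/N), and the binomial
form is biased low otherwise (the test-suite pins down both regimes). n\*
may not exceed the shallowest retained sample's depth — extrapolation is
refused rather than estimated.

## Ordination and variance partitioning

Soil PCA: natural-log transform, per-variable standardisation to mean 0 and
sd 1 (ddof = 1), SVD. Axes are oriented so the largest-magnitude loading is
positive. RDA: the response (Hellinger-transformed counts) and predictors
are column-centered; coefficients come from the Moore–Penrose pseudoinverse
(rank deficiency warns rather than fails); R² = SS(fitted)/SS(total); the
constrained axes are the SVD of the fitted values. Per-axis variance is
reported both as a share of the fitted variance and of the total variance,
since both conventions circulate. The three-model partition (S, E, S+E) can
produce small negative components under suppressor structure; they are
reported as-is with a warning because clipping would hide diagnostic
information.

MEMs: pairwise distances are great-circle (haversine, R = 6371 km) for
geographic coordinates and Euclidean for projected ones. The truncation
threshold is the largest edge of the minimum spanning tree over *unique
locations* — several cores share one site's coordinates, and zero-length
edges would drive the threshold to zero — and location-level eigenvector
scores are broadcast to co-located samples. Distances beyond the threshold
and the diagonal are set to 4× the threshold; the truncated matrix is
double-centered (Gower), eigendecomposed, and axes with eigenvalue
> 1e-10 × the largest are kept, scaled by √eigenvalue, and sign-fixed
(largest-magnitude entry positive) for reproducibility across LAPACK
builds. The number of MEMs entering the RDA is a config choice (default 4,
by descending eigenvalue); all positive axes are written out for
inspection.

## Null-model stochasticity partition

Regional weights: w_f ∝ the fraction of samples each taxon occupies, w_a ∝
each taxon's share of total reads, both normalised to sum 1. Occupancy is
computed at the sample level, matching the samples × samples output
granularity. Each neutral community fixes the sample's observed richness,
draws that many taxa without replacement ∝ w_f, and draws abundances from
Dirichlet(α) with α = w_a\*/min(w_a\*) over the chosen taxa (a single
chosen taxon gets abundance 1; a chosen taxon always has w_a > 0 because
zero-read taxa have w_f = 0). The expected dissimilarity E(d) is the
elementwise mean over n_sims (default 1000) simulations.

The partition applies exactly one branch per pair (det_a when O > E, det_b
when O < E, pure stochasticity when O = E), so stoch + det_a + det_b = 1
pairwise and O = 1 is safely handled by the det_a branch. Per-sample
summaries are column means excluding the diagonal. An alternative
aggregation — the average of the det_a-branch and det_b-branch means,
0.5·(mean stoch_a + mean stoch_b) — is also emitted; when only one branch
ever applies for a sample, that branch's mean is used alone.

Weighted sampling without replacement is implemented with the Gumbel top-k
(exponential-race) construction, which is distributionally identical to
sequential renormalised draws and vectorises across simulations; this keeps
a 1000-simulation run on 86 samples under a second.

## Mechanism battery

Dispersal weights put each sample's candidate sources at all other samples,
weighted by inverse distance; co-located samples would contribute 1/0, so
distances below a floor (default: half the smallest nonzero pairwise
distance) are raised to the floor — within-site sources stay strong but
finite.

Environmental weights are per-taxon occurrence probabilities from an
RBF-kernel support-vector classifier on **all** soil principal components,
Platt-calibrated (logistic regression on the decision scores). Each
sample's probability is predicted **out-of-fold** under 5-fold stratified
cross-validation. This is a deliberate design decision: in-sample
probabilities from a flexible kernel classifier partially memorise the
training presences, which lets the environmental rule mimic *any*
occupancy pattern — including dispersal-generated ones — and destroys the
identifiability of the rule families (measured here: ~70% top-r hit rate
in-sample vs ~53% out-of-fold on dispersal-generated data, the latter equal
to the dispersal weights themselves). Degenerate taxa shortcut the
classifier: all-present → probability 1, all-absent → 1e-6 (so occurrence
draws stay defined), minority class rarer than the fold count → the
taxon's occupancy. Classifier hyperparameters are sklearn defaults
(C = 1, gamma = "scale"), recorded in the weights' provenance.

Simulation mirrors the null model: occurrence without replacement ∝ the
occurrence family's weights (if fewer taxa have positive weight than the
required richness, the remainder falls back to w_f with a logged warning),
then Dirichlet(α = w\*/min(w\*)) abundances from the abundance family's
weights. Zero abundance weights within a chosen set are floored at 1e-6 ×
the largest chosen weight before forming α, since w_e/w_d rows may contain
exact zeros. Seven processes are scored (f→a, e→a, d→a, e→e, e→d, d→e,
d→d) by per-sample mean Sørensen and Bray–Curtis dissimilarity between
simulated and observed communities; Bray–Curtis is computed on relative
abundances (simulated abundances live on the simplex, so observed counts
are row-normalised for comparability), and Sørensen depends only on the
occurrence rule, which the test-suite asserts. A log-scale correlation
between w_d and w_e is reported as a confounding diagnostic.

## Trend fits

LOWESS (span default 0.67, configurable; sensitivity over {0.3, 0.5, 0.67}
is a one-line loop for the user) or ordinary linear fits, with
(x, y)-pair bootstrap envelopes (default 1000 replicates; degenerate
resamples with zero x-range fall back to a flat line at the resample mean).
Pseudo-R² is defined package-wide as 1 − SS_residual/SS_total about the
point fit; it can be negative for nonparametric fits on adversarial data
and is reported as-is. Note the noise level bounds the attainable
pseudo-R²: for a signal s(x) with additive noise of variance σ²,
no estimator exceeds var(s)/(var(s) + σ²) in expectation.

## Synthetic-data generator

The generator emulates a polar soil transect: 12 sites spread over 120 km
along x with lateral scatter (sd 20 km), 86 samples in total (4–10 cores
per site, co-located), 30 phylum-level taxa, and read depths uniform on
[500, 20000] so the depth filter and rarefaction are exercised. A latent
environmental state h = x-position + site-level offset (sd 15 km) +
sample-level offset (sd 5 km) drives every geochemical variable:
log v = a_v + b_v·h + N(0, 0.5), with positive slopes for all salts
(they covary along the gradient; NO₃ has the steepest slope) and a negative
slope for moisture.

The regional pool gives each taxon a lognormal abundance and an
*independent* lognormal occupancy frequency (σ = 0.3 both), a niche optimum
uniform on the range of h with Gaussian niche breadth 15 km, and a 2-D home
location for dispersal. Communities are drawn by the same two-stage
procedure the battery assumes: occurrence without replacement ∝ the rule's
weights (environment ∝ abundance × Gaussian niche match; dispersal ∝
abundance / (distance-to-home + 5 km); neutral ∝ pool frequency), then
Dirichlet abundances, then multinomial reads.

Three generator choices are identifiability boundaries of the inference,
not arbitrary knobs, and are worth stating plainly:

* **Environment is not a pure function of position.** If it were, the
  environmental classifier could express any spatial pattern and dispersal
  would be indistinguishable from filtering on a 1-D transect. Site- and
  sample-level heterogeneity (real soils have plenty) breaks the
  degeneracy.
* **Dispersal acts in 2-D.** Lateral site scatter gives geographic distance
  a component the 1-D environmental gradient cannot see.
* **Pool frequency is decoupled from pool abundance.** When occupancy is a
  deterministic proxy of abundance, abundance-informed occurrence rules
  dominate the neutral rule under the battery's mean-dissimilarity score
  (which, like any mean-distance score, rewards sharp predictors); moderate
  evenness (σ = 0.3) and independent frequency keep the completely-neutral
  process recoverable. At strongly skewed abundances the neutral process
  is *not* identifiable by this battery — a caveat that applies to field
  analyses too.

What passing on synthetic data shows: the formulas are implemented
correctly, the pipeline is deterministic under a seed, and the inference
recovers generating mechanisms *under the generator's assumptions*
(Gaussian niches, single-source inverse-distance dispersal, independent
samples, no phylogenetic structure, no temporal dynamics, no compositional
artefacts beyond multinomial sampling). Field data violate several of
these; recovery rates here are an upper bound on what the method can do in
the wild.

## Numerical and reproducibility notes

* All randomness flows from one seed through spawned `SeedSequence`
  children, one per stochastic stage; result files are written with 17
  significant digits and parsed back with round-trip float precision, so a
  fixed seed reproduces outputs byte-for-byte.
* Eigenvector sign conventions (largest-magnitude entry positive) make PCA,
  RDA and MEM outputs stable across BLAS implementations.
* Dissimilarities: Sørensen requires at least one occupied set; Bray–Curtis
  requires positive vector sums; both are errors, not NaNs.
* Problem sizes in the validation suite — 20 replicate datasets per
  generating rule with 200-simulation batteries, 500-simulation null
  models, 10,000-draw resampling oracles — were chosen so the full suite
  runs in about a minute on one CPU while keeping Monte-Carlo error well
  below the margins being asserted.

## Known limitations

* The stochasticity partition inherits the zero-sum framing it is built
  on: det and stoch components must trade off by construction.
* The battery's mean-dissimilarity score is not a proper scoring rule;
  rule families whose weights are sharper than their generating process
  can be over-rewarded (see the pool-skew caveat above).
* Negative-eigenvalue spatial structure (negative autocorrelation) is
  discarded with the negative MEM axes.
* The Dirichlet abundance construction ties the concentration scale to
  min(w\*); very uneven chosen-set weights produce near-deterministic
  abundances.
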