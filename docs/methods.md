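# Methods

## The problem and the two analyses

Two populations of one species occupy spatially disjoint regions under
different climate regimes.  The question is whether their Grinnellian
(coarse climatic) niches are still the same niche.  `nichedyn` answers it
twice, with designs that fail in different ways:

1. **Reciprocal model transfer** — if the niches match, a model of
   suitability fit on one region should rank the other region's
   occurrences above that region's pseudo-absences (high transfer AUC).
2. **PCA-env overlap** — measure the two occupancy distributions directly
   in a shared environmental plane and compare them with Schoener's D,
   permutation tests, and the expansion/stability/unfilling decomposition.

The second analysis corrects for *availability*: regions offer different
climates, so raw occurrence densities differ even for identical niches.
Occupancy z = o/e (occurrence density over environment density) removes
that confound before any comparison.

## Environmental space

Layers are z-scored (sample sd, n−1) and the PCA is the
eigendecomposition of the inter-layer correlation matrix over all valid
cells of both regions pooled — the entire environmental space of the
study, so both populations are projected onto identical axes.  Axis
scores are re-standardized to unit variance; each eigenvector is oriented
so its largest-magnitude loading is positive (eigenvectors are
sign-ambiguous, and a fixed convention makes runs comparable).  The
number of retained axes is the smallest k whose cumulative variance
fraction reaches `cumvar_threshold` (default 0.97), never fewer than 2
because the overlap plane is two-dimensional.  Retained axes feed the
niche models; the overlap analysis always uses the first two.

Standardizing first is redundant under a correlation PCA (the axes are
scale-invariant; a test asserts this), but both operations are exposed
because multi-region workflows need the *pooled* standardization
(`standardize_pooled`): z-scoring each region separately would subtract
the very between-region offset the analysis is about.

## Accessible areas

Each population's accessible area is the convex hull of its records plus
a planar buffer in degrees (default 1.0, round joins).  Climate stacks
are masked to it by cell-center membership (boundary cells count as
inside).  Buffering in degree units rather than geodesically matches the
convention of defining the buffer width in degrees; at the study
latitudes the distortion is modest and identical for both populations.

## Niche models

Training sets pair each region's presences with an equal number of RSEP
pseudo-absences: uniform draws, without replacement, from accessible-area
cells *outside* the population's Bioclim envelope.  The Bioclim score of
a point is `min_j 1 − 2|F_j(x_j) − 0.5|` with F_j the per-variable
training CDF under the midrank convention
`F(x) = (#{<x} + (#{=x}+1)/2)/n`; points outside any variable's training
range score 0 and define the binary envelope.  Under this discrete CDF
the peak score at the sample median of an odd-sized training set is
1 − 1/n, approaching 1 with sample size.

Algorithms (all mapping retained-axis coordinates to [0, 1]):

* **GLM** — unpenalized binomial logistic regression on linear +
  quadratic axis terms (a unimodal niche is not linearly separable;
  quadratic terms give the logit an interior optimum).
* **RDF** — 500 classification trees; suitability = presence-vote share.
* **SVM** — RBF soft-margin classifier with sigmoid probability
  calibration (5-fold, single calibrated model).
* **GAU** — Gaussian-process classifier, RBF kernel: the smooth
  probabilistic counterpart of the other three.

Evaluation is the Mann–Whitney AUC (ties ½) of the *evaluation* region's
presences against pseudo-absences drawn in the evaluation region by RSEP
against an envelope fit on that region's presences — mirroring the
training construction, since the transfer design specifies where
presences come from but not absences.  AUC bins are lower-inclusive:
[0.5, 0.7) acceptable, [0.7, 0.9) good, ≥ 0.9 optimal, < 0.5 random.
The ensemble averages the maps whose AUC ≥ mean AUC (at least one always
qualifies); the binary map thresholds the ensemble at the cutoff
maximizing sensitivity + specificity over midpoints of adjacent unique
scores, ties resolved toward the lower cutoff (favoring sensitivity).

## Overlap analysis

Density grids are R × R (default 100) over the pooled backgrounds'
PC1–PC2 range widened by 10%.  Kernels are product Gaussians truncated at
5 bandwidths per axis; bandwidths follow Silverman's rule
(0.9·min(sd, IQR/1.349)·n^(−1/5)) per axis, estimated on the occurrences
for o and on the background for e.  Truncation bounds every density's
support, which makes the D = 0 endpoint exact for well-separated niches
and keeps gridding fast.

**Occupancy support.**  z = o/e is computed only on cells where e exceeds
10⁻⁴ of its peak; elsewhere z = 0.  In the far tail of a truncated kernel
both o and e are products of near-zero tails, and their ratio is
unbounded — without the floor a single cell with e ≈ 10⁻¹² can absorb
most of the normalized occupancy, which is numerical noise, not niche
signal.  The floor removes cells carrying a vanishing fraction of
environment density and leaves every stated identity (Σz = 1, D
endpoints, E + S = 1) intact.  All brute-force test oracles implement
this same documented definition.

**Tests.**  The equivalence test pools both occurrence sets and re-splits
them into the original sizes (backgrounds fixed), recomputing D each
replicate; p = (1 + #{D_null ≤ D_obs})/(nrep + 1), small when the
observed niches are *less* equivalent than random splits.  The similarity
test translates the observed occurrence density of one population to a
uniformly random center among its background's positive-density cells;
placements whose nonzero mass would leave the grid are redrawn (no
wrapping), and occupancy is recomputed against the unmoved background;
p = (1 + #{D_null ≥ D_obs})/(nrep + 1), small when the observed overlap
exceeds chance.  It runs in both directions (default 1,000 replicates);
the per-species reported p is the maximum of the two — the conservative
combination.  The +1 correction keeps every p within
[1/(nrep + 1), 1].

**Dynamics.**  Over the analogous environment (cells where both
backgrounds have positive density; an optional `env_quantile` tightens
this), with population 1 as reference: S = share of z₂ mass on cells
where z₁ > 0; E = 1 − S; U = share of z₁ mass on cells where z₂ = 0.
Categories: > 0.7 high, [0.5, 0.7] partial, < 0.5 low.

## Synthetic data

The generator produces what the analysis assumes and nothing more:

* **Climate** — per region, each layer mixes a shared latent field
  (weight 0.6) with its own noise, both smoothed by a moving average
  (correlation length 3 cells), then rescaled to the regime's exact mean
  and sd.  The shared latent gives the nonzero inter-layer correlations a
  correlation-PCA needs; moving-average smoothing supplies spatial
  autocorrelation without a geostatistics dependency.
* **Regions** — two disjoint extents (25°×20° and 13°×22° at 0.5°
  cells; 2,000 and 1,144 cells) separated by a gap.  The second regime is
  cooler, drier and 30% more variable, offset 0.2 regime-sd per variable
  from the first — different regimes that still overlap enough for one
  species to occupy both, which is the regime an unshifted virtual
  species requires.
* **Species** — Gaussian product niche: suitability
  Π_j exp(−(x_j − μ_j)²/2σ_j²), centroid midway between the regimes,
  breadth 0.4 regime-sd.  The `shift` displaces the second population's
  centroid (the divergence dial, expressed in breadths).
* **Sampling** — cells drawn without replacement with probability
  proportional to suitability, one record at each drawn cell center
  (which makes cell deduplication exactly testable).  Defaults of
  200/100 records per region sit inside the 10–2,000 range typical of
  presence-only compilations.  Sampling is suitability-proportional
  only; real observation biases (roads, museums, effort) are not
  emulated, so passing tests validate the *method*, not robustness to
  biased sampling.

Region sizes, layer count (5 rather than a full bioclimatic suite) and
record counts are deliberate desk-scale choices: large enough that the
KDEs, PCA and classifiers behave asymptotically, small enough that the
full validation suite runs in minutes.

## Pipeline

Occurrences are deduplicated to one record per cell per species per
region (first record wins; out-of-extent records are dropped and
counted) and species need ≥ `min_records` (default 10) unique records in
*both* regions.  Every stochastic stage gets a seed derived by hashing
the master seed with the stage and species names, so results are
independent of processing order and each table entry is reproducible
from the logged seed.  A failing stage turns that species' row into NA
markers and a log entry; the study continues.  The summary block
recomputes the study-level aggregates (mean/sd of D, dynamics means,
fraction of similarity-significant species, AUC-category shares) from
the emitted per-species tables.

## Known limitations

* Planar-degree geometry throughout; no geodesic buffering or
  equal-area projection.
* Occupancy spikes are floored, not modeled; very sparse backgrounds
  (< ~100 points) still make z noisy.
* The similarity test translates the whole density by whole cells;
  sub-cell shifts are not explored.
* The GAU classifier is a Gaussian-process classifier; with hundreds of
  training points it is the slowest algorithm and its O(n³) cost makes
  it unsuitable for very large presence sets.
* Virtual species have independent per-variable tolerances (axis-aligned
  niches); correlated niche axes are not simulated.
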