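# nichedyn

Quantifying Grinnellian-niche divergence between disjunct populations of
the same species — for example bird populations split between two
rainforest blocks by an intervening dry corridor.  When two populations
have been isolated long enough, their realized climatic niches may drift
apart; `nichedyn` measures that drift two complementary ways and ships a
virtual-species simulator so the whole analysis can be validated end to
end without any external data.

## What it computes

**Reciprocal niche-model transfer.**  Ecological niche models (logistic
GLM with quadratic terms, random forest, RBF-SVM with calibrated
probabilities, Gaussian-process classifier) are fit on one region's
presences plus Bioclim-profile pseudo-absences (RSEP, restricted to the
accessible area: minimum convex polygon of the records + 1° buffer), then
scored on the *other* region's presences.  Transfer accuracy is the
Mann–Whitney AUC; per species the better-than-mean-AUC models are
averaged into an ensemble and binarized at the max(sensitivity +
specificity) threshold.

**PCA-env niche overlap.**  Climate layers are z-scored and reduced by a
correlation-matrix PCA fitted on the pooled environment of both regions.
On the first two axes, each population gets kernel densities of its
occurrences (o) and its available environment (e); occupancy is
z = o/e normalized to sum 1.  Overlap is Schoener's

    D = 1 − ½ Σ |z₁ − z₂| ∈ [0, 1],

tested by niche-equivalence (pool & re-split occurrences) and
niche-similarity (recenter one observed density at random within its own
background) permutations, and decomposed over the analogous environment
into expansion E, stability S = 1 − E, and unfilling U.

## Worked example

A two-species synthetic study — one species with a conserved niche, one
whose second population's niche centroid is shifted by six niche
breadths:

```python
from nichedyn.pipeline import StudyConfig, SpeciesSim, run_study
from nichedyn.synthetic_data import default_species

cfg = StudyConfig(
    seed=7, grid_R=60, nrep_similarity=99, nrep_equivalence=49,
    species=[SpeciesSim(default_species("conserved"), 120, 80),
             SpeciesSim(default_species("diverged", shift_breadths=6.0), 120, 80)])
result = run_study(cfg, out_dir="out")
print(result.overlap_table.round(3).to_string(index=False))
```

```
  species     D  equivalence  similarity  expansion  stability  unfilling expansion_cat stability_cat unfilling_cat
conserved 0.713         0.94        0.01      0.019      0.981      0.001           low          high           low
 diverged 0.000         0.02        1.00      1.000      0.000      0.932          high           low          high
```

The conserved species overlaps substantially (D = 0.713) and more than
chance (similarity p = 0.01), with high stability; the diverged species
shows no overlap (D = 0), complete expansion and near-complete unfilling.
The AUC table tells the same story from the modeling side — transferred
ensemble AUCs of 0.989/0.991 for the conserved species versus 0.338/0.485
for the diverged one:

```
  species  ENS_AM  ENS_MA  GLM_AM  GLM_MA  RDF_AM  RDF_MA  SVM_AM  SVM_MA  GAU_AM  GAU_MA
conserved   0.989   0.991   0.991   0.946   0.966   0.984   0.984   0.975   0.964   0.986
 diverged   0.338   0.485   0.338   0.485   0.092   0.229   0.076   0.245   0.166   0.160
```

The same study runs from the shell:

```sh
nichedyn simulate --seed 3 --out demo/           # climates + occurrences
nichedyn overlap --occurrences demo/occurrences.csv --rasters demo/rasters --seed 3
nichedyn run --seed 7 --out out/                 # full study with reports
```

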