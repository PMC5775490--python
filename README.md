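# landgen

Landscape-genomics analysis for SNP data on environmental gradients: from a
genotype matrix and climate rasters to population-structure summaries,
nonlinear genotype–environment association models, and mapped **genetic
offset** under a future-climate scenario.

The package is written for the kind of study done on Hawaiian koa (*Acacia
koa*)-like systems: a few hundred georeferenced trees genotyped by
reduced-representation sequencing (GBS/RAD) on an island with steep
windward/leeward rainfall gradients, where the questions are (i) how genetic
variation is structured in space, (ii) which environmental variables are
associated with allelic turnover, and (iii) where populations may become
genetically mismatched to their environment as climate changes.

## What it computes

Genotypes are carried as **dosages** — the within-individual alternate-allele
frequency at each SNP (0, 0.5, 1 for diploid calls; missing allowed).

* **QC** (`genotype_qc`): locus filters (missingness > 0.30, then minor
  allele frequency < 0.05, computed on non-missing calls); a
  replicate-concordance score for choosing SNP-calling parameter sets
  (mean within-replicate / between-individual distance in a classical-MDS
  embedding of dosage Hamming distances, with a more-SNPs tie-break); and a
  read-fraction ploidy diagnostic — in an autotetraploid, heterozygous calls
  show alternate-read fractions near 0.25/0.5/0.75 rather than only 0.5, so
  the fraction of heterozygous-call mass in the outer windows,
  `(m25 + m75) / (m25 + m50 + m75)`, indexes tetrasomic behavior.
* **Structure** (`popgen_structure`): unbiased expected heterozygosity H and
  per-base nucleotide diversity π per group; pairwise Weir–Cockerham F_ST
  (ratio of summed variance components, as PLINK reports); genotype PCA;
  and the admixture model — alt-allele count at locus j of individual i is
  Binomial(2, Σ_k q_ik f_kj) — fitted by EM with restarts, with K chosen by
  masked-genotype cross-validation.
* **Spatial predictors** (`spatial_pcnm`): PCNM / Moran's eigenvector maps
  from sample coordinates (MST-edge truncation, 4t replacement, Gower
  double-centering, eigendecomposition), retaining half of the
  positive-eigenvalue vectors.
* **Gradient forest** (`gradient_forest`): per-locus random-forest
  regressions of dosage on predictors; split impurity reductions are binned
  along each predictor gradient, normalized per locus, weighted by
  out-of-bag R², and averaged into non-decreasing cumulative-importance
  functions F_p whose total height W_p is the predictor's importance.
* **GDM** (`gdm_model`): generalized dissimilarity modeling — pairwise
  genetic dissimilarity regressed on monotone I-spline transforms of
  predictor differences through μ = 1 − exp(−η), fitted by non-negative
  deviance minimization, with geographic distance as one splined predictor.
* **Offset maps** (`offset_mapping`): per-cell genetic offset between
  current and future environments (GF: Euclidean distance between
  transformed predictor vectors; GDM: predicted dissimilarity between a
  cell's current and future environment at zero geographic distance), plus
  RGB maps of the first three principal components of the transformed grid.
* **Synthetic landscape** (`synthetic_landscape`): a fully seeded generator
  for an island with a sigmoidal west–east rainfall field, K admixed
  clusters with geographic structure, adaptive loci following a logistic
  cline in rainfall centered near 3,500 mm/yr, negative-binomial read
  depths, replicate call sets, and a reduced-rainfall future scenario —
  with the ground truth returned for estimator validation.

File formats: minimal VCF (GT only) or 0/1/2 dosage TSV for genotypes, CSV
sample metadata, ESRI ASCII grids for rasters, JSON model reports, YAML
pipeline configs.

## Worked example

```python
import numpy as np
import landgen

cfg = landgen.SimConfig(seed=3)          # 200 trees, 450 neutral + 50 adaptive SNPs
rasters, mask = landgen.make_env_rasters(cfg)
gm, truth, samples = landgen.simulate_genotypes(cfg, rasters=rasters, mask=mask)

basis = landgen.pcnm(samples.coords(gm.sample_ids), sample_ids=gm.sample_ids)
predictors = truth.env_at_samples.join(landgen.retain_half(basis))

model = landgen.fit_gf(gm, predictors, landgen.ForestConfig(n_trees=50, seed=3))
print({k: round(v, 4) for k, v in sorted(
    model.importance.items(), key=lambda kv: -kv[1])[:3]})
f = model.curve_value("rainfall", np.array([3000.0, 4000.0]))
print(round((f[1] - f[0]) / model.importance["rainfall"], 3))
```

prints

```
{'rainfall': 0.8083, 'temp_seasonality': 0.0004, 'temp_min': 0.0}
0.928
```

i.e. rainfall carries essentially all of the R²-weighted importance
(W_rainfall ≈ 0.81 versus ≤ 0.0005 for every other predictor), and 92.8% of
its cumulative-importance rise happens between 3,000 and 4,000 mm/yr — the
model has localized the planted allelic turnover zone. Continuing,

```python
current = {n: p[0] for n, p in rasters.items()}
future = {n: p[1] for n, p in rasters.items()}
offset = landgen.gf_offset(model, current, future, mask)
print(round(np.nanmax(offset.values), 3))   # 0.675
```

the offset map peaks (0.675 in transformed-composition units) along the
windward transition zone where the future scenario pushes rainfall down
through the turnover zone.

The same analysis runs end-to-end from a YAML config via the CLI:

```bash
landgen run --config config.yaml --out results/ --seed 7
```

with stages `simulate | qc | structure | pcnm | gf | gdm | offset` also
available individually; every run writes a `manifest.json` recording the
config, seed and input checksums.

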