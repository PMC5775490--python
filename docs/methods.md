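# Methods

This note documents the models and procedures implemented in `landgen`, the
choices made where several reasonable conventions exist, and what the
synthetic-data tests do and do not establish about behavior on real data.

## Data model

Genotypes are dosages: the within-individual alternate-allele frequency at
a biallelic SNP. Diploid calls 0/1/2 map to 0/0.5/1; missing is `nan`. The
dosage scale (rather than allele counts) was chosen because the same
container then holds tetraploid dosages {0, 0.25, 0.5, 0.75, 1} produced by
the read simulator, and because distance-based analyses (site pairs,
replicate Hamming scores) read naturally off it. VCF parsing is minimal —
GT field only, `/` and `|` treated identically, multi-allelic records
skipped with a logged count. Rasters follow the ESRI ASCII convention
(row 0 = north, values at cell centers); no CRS math is done, so PCNM and
GDM geographic distances are Euclidean in whatever units the coordinates
arrive in (decimal degrees by default in the simulator). Both raw-degree
and projected inputs work; mixing them in one analysis does not.

## Synthetic landscape

The generator emulates the statistical situation the analysis assumes, not
any particular data set:

* **Rainfall** is logistic in easting between `rain_west` = 800 and
  `rain_east` = 6,200 mm/yr, passing through 3,500 mm at the island
  midline with steepness 12/degree — a steep windward/leeward gradient
  whose transition zone spans roughly a third of the island.
* **Auxiliary variables** (minimum temperature, isothermality, temperature
  seasonality, rainfall seasonality) mix the standardized rainfall field
  with independent smoothed-noise fields at target correlations of
  |r| = 0.35–0.55, then rescale into plausible units. The generator
  verifies empirically that |r| < 0.8 over mask cells and errors otherwise
  — mirroring the usual predictor-screening rule.
* **Neutral structure**: each locus draws an ancestral frequency in
  [0.2, 0.8]; each of the K clusters is pushed half the configured
  divergence up or down (opposite signs when K = 2, so the realized mean
  |F₁ − F₂| equals the `cluster_divergence` parameter exactly, 0.3 by
  default). Admixture proportions decay with distance to K random cluster
  centers (exp(−d/τ) weights times Gamma(2) noise, normalized), giving
  admixed-with-geography structure without a coalescent simulation.
* **Adaptive loci** follow a logistic cline in rainfall,
  p = 1/(1 + exp(−s (rain − c))) with c = 3,500 mm and s = 0.004/mm: allele
  frequency swings from ~0 to ~1 across the 3,000–4,000 mm band. Genotypes
  are Binomial(2, p)/2 throughout.
* **Read depths** are negative binomial (mean 20, overdispersion 3 by
  default — a long-tailed coverage distribution); alternate reads are
  binomial at the true dosage. Autotetraploid dosages are Hardy–Weinberg
  draws on four chromosome copies.
* **Future scenario**: rainfall declines in proportion to its wet-side
  excess (up to 1,500 mm at the wettest cells); other variables are held
  constant. This plants a wet-to-dry transition whose cells must cross the
  allelic turnover zone.
* Missingness is off by default and opt-in: missing-completely-at-random,
  or per-sample rates proportional to cluster-1 membership for testing the
  membership-vs-missingness check.

Defaults (n = 200 individuals, 450 neutral + 50 adaptive loci, K = 3)
define the conditions of the recovery tests. What passing tests show: the
estimators recover planted structure at realistic sample sizes and effect
sizes. What they do not show: robustness to linkage, genotyping error
correlated with environment, uneven spatial sampling, or model
misspecification (e.g. non-logistic clines) — none of which the generator
produces.

## QC

Filters run missingness-first (fraction > 0.30 removed), then MAF < 0.05
computed on non-missing calls of the surviving loci; a locus exactly at a
threshold is kept. The order makes attrition counts reproducible; the
filter is idempotent. Upstream caller-side filters (one SNP per tag,
likelihood and haplotype pruning) are out of scope and recorded as assumed
in the report.

Replicate scoring embeds dosage-aware Hamming distances (hom/het mismatch
= 0.5) by classical MDS and scores each call set as mean within-replicate
distance over mean between-individual distance; 0 iff replicates coincide.
Among call sets within 10% of the minimum score, the one with more SNPs
ranks first — the tolerance is a package default; the underlying preference
(more loci at indistinguishable error) does not pin down a number.

The ploidy diagnostic uses loci with ≥ 60× coverage for individuals with
≥ 1,000 such loci; heterozygous calls are alt fractions in (0.05, 0.95),
and window half-width 0.05 around 0.25/0.5/0.75 defines the masses m25,
m50, m75. The tetraploid index (m25+m75)/(m25+m50+m75) is ~0 for diploids
at 60× (binomial spread keeps het fractions near 0.5) and ~0.5–0.7 for
tetrasomic simulations; the classification threshold 0.3 sits in that gap.
Both a het-only and an all-fractions histogram mode exist (default
het-only). At depths well below 60× the windows overlap and the index
loses meaning — hence the eligibility rule.

## Population structure

* Gene diversity per locus is h = (2n/(2n−1))·2p̂(1−p̂) on non-missing
  calls; H is its mean over loci and π spreads Σh over 87 assayed bases per
  locus (one variant site per sequenced tag). The per-base denominator is a
  documented approximation — callers that include invariant sites within
  tags will report slightly different π; `locus_length` is configurable.
* Pairwise F_ST is Weir–Cockerham (1984) for two populations with the full
  genotype-based components a (among populations), b (among individuals
  within), c (within individuals, from observed heterozygosity), aggregated
  as Σa / Σ(a+b+c) over loci — the ratio-of-sums convention. Loci with zero
  total component are skipped and counted. Slightly negative estimates are
  expected under no differentiation and are not truncated.
* PCA mean-imputes missing calls per locus, centers at 2p̂ and (by default)
  scales by √(p̂(1−p̂)); monomorphic loci are dropped; signs are fixed by
  making the largest-magnitude score positive.
* The admixture likelihood is the standard binomial mixture; EM updates are
  the exact responsibility-weighted ones, vectorized so no n×L×K array is
  formed. Frequencies are clamped to [1e-6, 1−1e-6]; the log-likelihood is
  non-decreasing by construction and asserted in tests. Three random
  restarts by default; EM was chosen over quasi-Newton block relaxation for
  transparency — it is slower but every iterate is interpretable.
* K is selected by masking 10% of non-missing genotypes per fold, refitting,
  and scoring mean squared prediction error (g − ĝ)²/4 on the masked
  entries; the argmin is the smallest K attaining the minimum. This differs
  from ADMIXTURE's deviance-residual CV in the error functional but ranks K
  the same way in the regimes the tests probe (checked by property, not
  assumed).

## PCNM

Classical construction: Euclidean distances, truncation at the longest
minimum-spanning-tree edge t, distances beyond t replaced by 4t, Gower
double-centering of −½D∘D, eigendecomposition. Eigenvectors with
eigenvalue > 1e-10 × the largest are kept, scaled by √λ, signs fixed by
largest-magnitude loading. The truncation and 4t constants are the
conventional ones; nothing in the method pins them down, and the basis is
insensitive to the replacement constant for the uses here. "Retain half of
the positive-eigenvalue vectors" uses the ceiling on odd counts (floor
available); with 52 positive vectors both give 26.

## Gradient forest

Per locus, a random forest (default 500 trees, mtry = ⌈P/3⌉, min leaf 5)
regresses dosage on all predictors; samples with missing dosage are
dropped per locus. A locus enters the aggregation only if its out-of-bag
R² is positive. Each split's impurity decrease is credited to the bin
(default 200 left-closed bins per predictor range) containing its
threshold; per locus the binned importances are divided by a Silverman-
bandwidth kernel density of the predictor's sampled values (so densely
sampled gradient stretches are not over-credited; this single-ratio
standardization is a simplification of the reference tooling's options and
can be switched off), normalized to sum one, scaled by R², and cumulated.
F_p is the mean of these per-locus cumulative step functions over included
loci; W_p = F_p(max) is the predictor importance, and by construction
W_p equals the mean R²-weighted per-locus importance. A permutation-
importance mode exists (per-predictor totals from permutation, curve
shapes from split bins) but split importance is the default. The
spatial/environment importance split is Σ W over PCNM-named predictors
versus the rest, normalized — it depends on how many predictors of each
type enter the model and is reported as data-specific, not a stable
quantity.

Grid transforms evaluate each cell through the F_p step functions, with
out-of-range values clamped to the training range. PCNM predictors have no
raster; when a map of the full composition is wanted they are interpolated
to the grid by inverse-distance weighting (power 2, k = 8) of the sample
scores, but the default for offsets and RGB maps is to drop spatial
dimensions entirely — space does not change between scenarios.

## GDM

Sites are individuals (no deduplication of nearby trees). Genetic
dissimilarity is the Euclidean distance between dosage vectors over
pairwise-complete loci, divided by √(shared loci), then scaled into [0, 1]
by the observed maximum (a fixed-denominator mode exists; the mapping into
the response domain is a convention, and importances are insensitive to it
up to overall scale). All unordered pairs are used (20,100 at n = 201); a
subsampling flag exists for larger n. Each predictor gets three order-2
I-splines (integrated linear M-splines) with knots at its min/median/max;
geographic distance is splined on the distance value itself with the lower
knot pinned at 0. The fit minimizes the binomial-form deviance of
μ = 1 − exp(−η) under non-negativity (L-BFGS-B with analytic gradients and
box bounds; observed d clamped to [1e-6, 1−1e-6]); the deviance at each
accepted iterate is recorded and non-increasing. Percent deviance explained
is 100(1 − D/D₀) against an intercept-only fit. Predictor importance is the
spline-coefficient sum (spline height); a predictor driven to all-zero
coefficients has importance exactly 0. Environment/space shares derived
from coefficient sums are labelled as such — they are not a deviance
partition.

## Genetic offset

GF offset is the per-cell Euclidean distance between transformed predictor
vectors under current and future environments. The F_p curves already
integrate to W_p, so no additional importance weighting is applied by
default; a flag enables per-dimension W_p weighting for sensitivity
analysis, making the offset quadratic rather than linear in importance.
GDM offset is the predicted dissimilarity between a cell's current and
future environment with geographic distance 0; under identical rasters it
equals the intercept floor 1 − exp(−α) (exactly 0 when α = 0). Spatial
terms are frozen in both methods, and predictors that cannot change
between scenarios (e.g. substrate age) are named in a drop list
(default `["substrate_age"]`). RGB maps min–max scale the first three
principal components of the transformed mask cells to [0, 255]; fewer than
three informative dimensions are zero-padded with a note.

## Problem sizes and numerics

Recovery tests and the acceptance script run at the generator defaults
(n = 200, L = 500, 50 adaptive loci) with 50-tree forests — the floor of
the configured range, chosen because importance rankings on these fixtures
are already stable there and ten replicate fits stay cheap on one CPU;
production fits should use the 500-tree default. Admixture recovery uses
n = 100, L = 1,000, divergence 0.3, with 3-fold CV and single restarts
inside CV. Ties in split-threshold binning use left-closed bins; KDE
densities are floored at 1e-3 of their maximum to avoid dividing by ~0 in
empty gradient stretches; eigen-solver sign ambiguity is fixed by
largest-loading conventions everywhere, and replicate ordination scores
below 1e-12 of the between-individual scale are snapped to exactly 0.

## Known limitations

Loci are modeled independently (no linkage); the forest response is the
0/0.5/1 dosage, not haplotypes; GDM significance testing (matrix
permutation) and predictor elimination are not implemented; PCNM
generalizations with custom weight matrices are out of scope; VCF support
is deliberately minimal (no BCF, no indexing, no streaming of very large
files); and offsets inherit every assumption of the fitted models — in
particular that today's genotype–environment relationship is adaptive and
transferable to future climates, which no amount of synthetic validation
can establish.
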