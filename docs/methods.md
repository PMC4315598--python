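# Methods

This note documents the models, estimators, and design choices behind
`urbanbarrier`, in the order the pipeline runs.

## Data model

A dataset is a list of loci (name, repeat unit in bp, grid anchor) and a
list of samples (id, planar x/y in meters, city-block label, collection
year, and one unordered diploid allele-size pair per locus, or a missing
marker). Genotypes are unphased; allele pairs are sorted on ingest. A
single in-memory missing sentinel is translated to format-specific codes
(`000000` in GenePop, `-9` in STRUCTURE input, empty CSV cells) only at
I/O boundaries. Coordinates are planar projected meters — the intended
spatial scale is a transect of a few kilometers, so no geodesy.
Privacy-redacted deposits often omit coordinates entirely; the reader
tolerates metadata-free tables, and operations that need coordinates,
blocks, or years raise a specific error instead of guessing.

Raw fragment sizes are binned to the repeat grid as
`offset + round((size − offset)/unit) · unit` with round-half-up on the
unit scale: a fragment exactly half-way between grid points bins to the
larger allele. The rule is deliberately simple and deterministic rather
than a reproduction of any particular binning program's dialect.

## Pairwise dissimilarity

Bray-Curtis dissimilarity is computed on pooled allele counts: each
diploid locus contributes two counts per individual, and only loci typed
in *both* members of a pair enter that pair's numerator and denominator
(pairwise deletion, preserving sample size). The statistic is symmetric,
lies in [0, 1], is 0 exactly for identical allele multisets on shared
loci, and is *not* a metric — no triangle inequality is claimed or used.
A pair sharing no typed locus is an error at the pair level and is
excluded (with a logged count) at the table level, never silently
scored 0.

Indicator coding: `cross_block = 1` and `cross_year = 1` for pairs on
*different* blocks/years, so positive regression coefficients mean
streets (or time) add dissimilarity.

## Permutation regression

The observed fit is OLS of genetic distance on Euclidean distance,
cross-year, and cross-block with intercept (statsmodels). Constant
predictors (e.g. cross-year in a one-year dataset) are dropped and
reported as NaN; a rank-deficient design raises an error naming the
degenerate predictor.

Inference comes exclusively from a stratified permutation null: whole
multilocus genotypes are shuffled among individuals collected in the
same year, keeping all spatial metadata fixed, and the regression is
refit per permutation. Because permuting whole genotypes is a
row/column relabeling of the precomputed dissimilarity matrix, each
permutation costs one gather plus one projector multiply; the null
coefficients are numerically identical to refitting from scratch.
P-values are two-sided with the add-one rule,
`p = (1 + #{|β*| ≥ |β_obs|}) / (n_perm + 1)`, so `p ∈ [1/(n_perm+1), 1]`
and is never 0. Sidedness is a package choice (two-sided is
conservative); the default 10,000 permutations matches the intended
study design, and all replicate studies in the tests use 199.

Calibration facts, measured by the test suite: on label-exchangeable
data (i.i.d. genotypes, or a one-time within-year shuffle of simulated
data) the block-coefficient p-value is uniform and the rejection rate at
α = 0.05 is 0.05. Two caveats are inherent to the method, not defects:
(i) datasets with few distinct genotypes produce ties between null and
observed statistics, making the p-values slightly conservative; (ii) a
population with frequent *local* dispersal but no long-range mixing is
not exchangeable — same-block pairs are enriched for close kin, and the
test correctly reports that spatial-genetic signal (rejection ≈ 0.22 in
the streets-transparent, local-dispersal-only regime). The "barrier-free"
reference condition for type-I studies therefore opens both dispersal
channels (`p_street = p_jump = 0.5`), where the measured rate is ≈ 0.10.

## Matched equal-distance pairs

Same-block pairs, visited in order of increasing distance, each claim
the unused cross-block pair minimizing the distance difference, accepted
only within the tolerance (default 1 m). Matching is one-to-one, greedy,
and deterministic for a given table. The differences
(cross-block minus same-block genetic distance) go into a standard
paired t-test (two-sided, df = couples − 1); zero-variance differences
are handled explicitly (t = 0, p = 1 when all differences are 0; a
warning and a 0-limit p otherwise).

## Neighborhood diversity

Every sample (focal individual included — the neighborhood is a census
of samples in the ball) centers a radius-r neighborhood. Per locus with
n typed individuals: Ho is the heterozygote fraction; He is Nei's
unbiased estimator `(2n/(2n−1))(1 − Σ p²)`; allelic richness is the
hypergeometric expectation of distinct alleles in `g′ = 2g` gene copies.
Sample-level values average the loci typed in at least `g` individuals
(default g = 10, matching the minimum neighborhood size, so every valid
neighborhood is rarefied to the same standard). F_IS is
`1 − mean(Ho_l)/mean(He_l)` — the ratio of multilocus means, stable when
individual loci are near-monomorphic; when every retained locus is
monomorphic (He = 0) F_IS is undefined and reported absent with a
warning. Neighborhoods with fewer than `min_n` samples (default 10) are
flagged invalid and carry no indices.

The radius is selected where the number of valid neighborhoods levels
off across the candidate list (default 100–250 m by 25): the smallest
radius whose relative gain over its predecessor is below 5%. The 5%
threshold operationalizes "levels off" and is exposed as a parameter; if
the counts never level off the largest radius is used with a warning.
Neighborhoods can be computed pooled across years (default) or within a
single collection year via the `year` argument / CLI flag.

Each index is regressed (OLS) on the transect x coordinate over valid
samples; slope, R², F, and p are reported.

## Cluster post-processing

The Bayesian clustering itself is out of scope; the package consumes its
outputs. Evanno's ΔK at interior K is `|L′(K+1) − L′(K)| / sd(lnP(K))`
with L′ the first difference of mean lnP across runs; it needs ≥ 3
contiguous K values and ≥ 2 runs per K, is undefined at the boundary K
and wherever the across-run sd is 0 (warned), and the selected K
maximizes ΔK. Modal assignment takes the argmax of each Q-matrix row
(rows must sum to 1 within 1e−6), ties breaking to the lowest cluster
index. The co-assignment test compares the observed fraction of
same-block pairs sharing a label with the chance expectation
`Σ_k q_k²` under the observed label frequencies, via a 1-df
goodness-of-fit χ² on the co-assigned/not split. Same-block pairs are
not independent, so the χ² is an index of excess rather than an exact
test; expected counts below 1 trigger a warning.

## The synthetic city

The generator is a forward-time individual-based model on an
`n_cols × n_rows` grid of square blocks separated by streets, with
non-overlapping generations, run per generation as: migration →
Wright-Fisher reproduction within blocks (each of `n_per_block`
offspring draws two parents uniformly with replacement, one allele per
parent per locus) → stepwise mutation (±1 repeat unit with probability
`mutation_rate`, direction fair, floored at one repeat) → colonization.
Migration is per individual: probability `p_street` of moving to one of
the four orthogonal neighbor blocks (staying put if that direction is
off-grid or not yet built), `p_jump` of relocating to a uniformly random
active block — an agnostic stand-in for flight and human-mediated
transport, which field data cannot distinguish. Migrants compete in the
destination block.

Columns of blocks activate west to east every `founding_interval`
generations. Each new block is seeded by `n_founders` propagules copied
from the same-row block of the nearest occupied column (falling back to
the whole column if that block is empty): rows thus form parallel
colonization chains whose serial bottlenecks both erode heterozygosity
eastward and let sibling chains drift apart, which is what gives eastern
neighborhoods their Wahlund-type heterozygote deficit (rising F_IS). The
westernmost column is an open boundary: each resident is replaced by an
immigrant from a diverse external source pool (equifrequent alleles per
locus) with probability `source_rate` per generation, sustaining
diversity in the old city core. A fully closed grid (`source_rate = 0`)
instead drifts its oldest blocks to fixation and inverts the gradient.

Defaults emulate the intended study shape: 12 × 3 blocks of 80 m side
with 10 m streets (a ≈ 1.1 km transect), 40 individuals per block, 13
loci, mutation 1e−3, `p_street` 0.002 and `p_jump` 0.0005, columns every
8 generations, 5 founders, sampling 90 individuals (stratified by
transect thirds) at generations 98 and 104 — roughly a 3-year gap at two
generations per year. No field estimates exist for these quantities;
they are calibration targets chosen so the generator reproduces the
qualitative structure the analyses assume, not parameter estimates.
Replicate studies (type-I error, power) use a scaled-down condition —
6 × 2 blocks, 30 per block, 5 loci, 60 samples — chosen to keep 200-
replicate studies fast while preserving the block/street geometry.

What the generator does *not* emulate: household-level substructure
within blocks, stage-structured insect demography, insecticide
interventions, temporal heterogeneity in dispersal, and genotyping
artifacts (allele dropout, scoring error). Passing calibration tests on
these simulations therefore shows the inference machinery is correct
under the model's assumptions, not that real data meet them.

Determinism: one seed in the config drives a single generator for the
whole simulation; identical configs give identical datasets. The
pipeline derives stage seeds from the master seed by fixed offsets.

## Numerical and degenerate-input choices

* Binning ties round up (documented above); binning is idempotent.
* Allele sizes above 999 bp cannot be GenePop-encoded and raise an
  explicit overflow error.
* The permutation p-value estimator counts ties as exceedances
  (conservative).
* Rarefaction uses exact integer binomial coefficients; when `g′`
  exceeds the available gene copies the observed distinct-allele count
  is returned (no extrapolation).
* Matching ties (equal distance gaps above and below) resolve to the
  smaller-distance candidate.
* ΔK with zero across-run sd, F_IS with He = 0, and χ² with expected
  counts at the boundary are all reported as undefined/degenerate with
  warnings rather than fabricated numbers.

## Known limitations

* The OLS point estimates on pair data are consistent descriptive
  summaries, but all uncertainty statements come from the permutation
  null; the reported R²/F of pair regressions inherit the pairs'
  non-independence.
* The co-assignment χ² ignores pair dependence (by design, to match the
  classical presentation); treat its p-value as an index.
* The greedy matcher does not globally minimize the total distance
  mismatch; it is deterministic and auditable instead.
* sGD-style software varies in its exact estimator set; the estimators
  here (Nei unbiased He, ratio-of-means F_IS, hypergeometric AR) are
  documented substitutes, exact as specified above.
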