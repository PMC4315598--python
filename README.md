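# urbanbarrier

Landscape genetics for urban insect invasions: do city streets act as
barriers to dispersal?

When an insect population (the motivating case is *Triatoma infestans*,
the Chagas disease vector, colonizing a growing city) spreads through an
urban grid, city blocks form habitat patches separated by inhospitable
streets. `urbanbarrier` provides the statistical toolkit to detect that
barrier effect from diploid microsatellite genotypes with spatial
metadata, plus a forward-time simulator that generates datasets with the
same assumed structure for calibration and power studies.

## What it computes

**Pairwise dissimilarity.** Genetic distance between two individuals is
the Bray-Curtis dissimilarity of their pooled allele counts (two counts
per diploid locus, loci missing in either member dropped for that pair):

    BC(i, j) = 1 − 2 Σ_a min(c_ia, c_ja) / (Σ_a c_ia + Σ_a c_ja)

**Permutation regression.** Genetic distance over all n(n−1)/2 pairs is
regressed by OLS on Euclidean distance (m), a cross-year indicator, and a
cross-block indicator (1 = different city block, so a positive
coefficient means streets add dissimilarity). Inference never uses OLS
standard errors — pairs are not independent — but a stratified
permutation null: whole multilocus genotypes are shuffled among
individuals of the same collection year (default 10,000 permutations),
genetic distances rebuilt, and each coefficient's two-sided add-one
p-value read off its null distribution.

**Matched equal-distance pairs.** Same-block pairs are greedily matched
to unused cross-block pairs of equal Euclidean distance (1 m tolerance)
and the genetic-distance differences tested with a paired t-test — a
design that controls for distance exactly.

**Spatial genetic neighborhoods.** Every sample centers a circular
neighborhood (candidate radii 100–250 m; the radius is chosen where the
count of valid neighborhoods — those with ≥ 10 samples — levels off).
Within each neighborhood the package computes observed heterozygosity
Ho, Nei's unbiased expected heterozygosity He, F_IS = 1 − Ho/He, and
rarefied allelic richness (hypergeometric expectation at a standard
number of gene copies), and regresses each index on the transect
coordinate to detect colonization-history gradients.

**Cluster post-processing.** From externally produced clustering runs:
Evanno's ΔK (|second difference of mean lnP| / sd across runs) to choose
the number of clusters, modal assignments from a Q-matrix, and a χ² test
of whether same-block samples are co-assigned more often than the
random-label expectation Σ_k q_k².

**Synthetic city.** An individual-based Wright-Fisher simulator on an
expanding block grid: west-to-east column activation with founder
propagules from the nearest occupied column, rare street-crossing and
long-jump dispersal, stepwise microsatellite mutation, and two-year
stratified sampling — reproducing block-dominant genotypes, barrier
signal, and the west-to-east diversity gradient of a colonization wave.

## Worked example

```python
import urbanbarrier as ub

ds = ub.simulate(ub.default_study_config(seed=1))   # 180 samples, 13 loci
res = ub.permutation_test(ds, n_perm=999, seed=2)
obs = res.observed
print(f"beta_dist (per m): {obs.beta_dist:.3e}  p = {res.p_values['beta_dist']:.3f}")
print(f"beta_block:        {obs.beta_block:.3e}  p = {res.p_values['beta_block']:.3f}")

pairs = ub.build_pair_table(ds)
m = ub.match_equidistant_pairs(pairs, tolerance=1.0)
t = ub.paired_t_test(m)
print(f"matched couples: {t.n_couples}  t = {t.t_stat:.3f}  p = {t.p_two_sided:.2e}")

scan = ub.select_radius(ds)
idx = ub.neighborhood_indices(ds, radius=scan.selected)
print(f"Ho slope:   {ub.longitudinal_trend(idx, ds, 'ho').slope:.3e} per m")
print(f"F_IS slope: {ub.longitudinal_trend(idx, ds, 'f_is').slope:.3e} per m")
```

prints

```
beta_dist (per m): 1.263e-04  p = 0.001
beta_block:        4.270e-01  p = 0.001
matched couples: 270  t = 22.672  p = 2.32e-64
Ho slope:   -2.117e-04 per m
F_IS slope: 1.313e-04 per m
```

Read: after controlling for distance and year, being on different blocks
adds 0.43 to the expected Bray-Curtis dissimilarity (permutation
p = 0.001, the smallest value a 999-permutation null can produce) — the
street-barrier signature. The matched-pair design confirms it at equal
distances. Along the transect, heterozygosity falls and inbreeding rises
toward the recently colonized east, the footprint of the founder wave.

The same stages are available from the shell:

```bash
urbanbarrier simulate --seed 1 --out data.csv
urbanbarrier pairs --in data.csv --out pairs.csv
urbanbarrier permtest --in data.csv --n-perm 10000 --seed 17 --out result.json
urbanbarrier matched --in pairs.csv --tol 1.0 --out matched.csv
urbanbarrier radius-scan --in data.csv
urbanbarrier neighborhoods --in data.csv --radius 225 --out indices.csv
urbanbarrier deltak --runs runs.csv
urbanbarrier coassign --q q.csv --in data.csv
urbanbarrier run --config pipeline.yaml   # all six stages + manifest
```

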