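# Methods

`seepcomm` implements the statistical chain commonly applied to amplicon
surveys of cold-seep (and other) sediments: rarefaction and α-diversity,
Bray–Curtis ordination and PERMANOVA, phylogenetic and taxonomic null
models for community assembly (NTI, βNTI, Raup–Crick Bray–Curtis and the
five-process classification), environmental-driver statistics (Mantel,
random-forest importance), and co-occurrence network topology. A synthetic
community generator with planted assembly regimes provides ground truth for
every stage. This note records the models, the conventions chosen where the
field's usage varies, and what the synthetic benchmark does and does not
establish.

## Null models for community assembly

**MNTD / NTI.** For one sample, the mean nearest-taxon distance is

    MNTD = Σ_i w_i · min_{j ≠ i, j present} d(i, j)

over present taxa, where `d` is patristic distance and `w_i` is either
uniform over present taxa (default) or the relative abundance. NTI is the
negated z-score of MNTD against `n_null` randomizations that shuffle taxa
labels across the patristic distance matrix: positive NTI means the sample
is phylogenetically clustered.

**βMNTD / βNTI.** Between samples j and k,

    βMNTD(j,k) = ½ [ Σ_i w_ij · min_{m ∈ k} d(i,m) + Σ_m w_mk · min_{i ∈ j} d(m,i) ]

with the same weighting options. Conspecifics count: a taxon present in
both samples contributes distance 0, so identical samples score exactly 0.
βNTI is the (signed) z-score of βMNTD under the taxa-shuffle null, with one
permutation applied identically to both samples per replicate. These
conventions reproduce picante's `comdistnt`/`ses.mntd` behaviour; the
abundance-weighted mode matches `comdistnt(..., abundance.weighted=TRUE)`
to machine precision (cross-checked in the test suite via `Rscript`). In
presence mode picante averages the pooled nearest-distance lists, whereas
this package averages the two per-sample means, as in the formula above;
the two coincide at equal richness.

The default is presence-based weighting — the default of the R functions
this chain mirrors. Two degenerate cases are flagged rather than forced: a
perfect star tree (all nulls identical) yields NaN NTI, and two samples
with identical membership yield NaN βNTI, because observed *and* every
null βMNTD are exactly 0 (the null permutes labels but preserves the zero
diagonal), leaving no variance to standardize against. Such pairs are
excluded from process fractions and counted in an `n_unclassified`
diagnostic.

**Raup–Crick (Bray–Curtis).** For each sample pair, `n_null` pairs of null
communities are assembled: species enter without replacement with
probability proportional to their occupancy across all samples until the
observed richness is reached; remaining individuals are then distributed
over the chosen species with probability proportional to metacommunity
relative abundance until the observed sample total is reached. With
`BC_obs` ranked among the null Bray–Curtis values,

    RC = 2 · ( (#{BC_null < BC_obs} + ½·#{BC_null = BC_obs}) / n_null − ½ ) ∈ [−1, 1].

RC-bray expects integer counts at comparable totals; rarefy first. Note
the null is sharp: it attributes *only* richness, regional relative
abundance and multinomial noise to chance. Any further reproducible
abundance heterogeneity between samples (e.g. environmental tracking the
model does not know about) is read as excess turnover.

**Classification.** Each within-site sample pair is labelled by, in order:
βNTI > 2 → heterogeneous selection; βNTI < −2 → homogeneous selection;
otherwise RC > 0.95 → dispersal limitation; RC < −0.95 → homogenizing
dispersal; otherwise undominated. All inequalities are strict, so values
exactly at a boundary fall through to the next rule. Per-site process
fractions are computed over the C(n_depths, 2) within-site pairs by
default (`within_groups=False` classifies all pairs).

`n_null` defaults to 999 for NTI, βNTI and RC-bray; every null draw flows
through one seeded generator.

## Diversity

Shannon uses natural log (configurable base). ACE uses the standard
rare/abundant cutoff of 10 with the rare-species coefficient of variation
floored at 0; when every rare individual is a singleton the estimator is
undefined and bias-corrected Chao1 is substituted with a warning. Good's
coverage is 1 − F1/N and requires integer counts. Faith's PD is rooted
(the minimal spanning subtree includes the root), computed by scikit-bio.
Group comparison uses the least-significant-difference procedure: one-way
ANOVA pooled error, pairwise t tests at level α, and a compact letter
display built by insert-and-absorb; groups are lettered in
decreasing-mean order, with exact ties broken lexicographically so the
display is reproducible.

## Ordination and permutation tests

Bray–Curtis distances feed classical PCoA (Gower double-centering;
negative eigenvalues zeroed and excluded from the variance denominator; no
Lingoes/Cailliez correction). PERMANOVA and Mantel (Spearman by default,
Euclidean distance on each scalar geochemical variable) use seeded
permutations with the +1 correction, so the smallest attainable p-value is
1/(nperm+1); nperm defaults to 999. Note that in small balanced designs a
random permutation can recreate the observed partition and tie the
observed statistic, so the floor is attained only when the permutation
space is large relative to nperm.

## Random-forest driver importance

Samples are classified into sites from the geochemical variables by a
bagged forest of `sqrt`-feature decision trees (the bagging form of a
random forest, chosen because it exposes per-tree bootstrap indices).
Importance is out-of-bag mean decrease in accuracy: for each tree, the
accuracy on its out-of-bag samples minus the accuracy after permuting one
variable among those samples, averaged over trees and reported in percent.
Small negative values are normal for uninformative variables.
Significance comes from `nperm` whole-forest refits on permuted site
labels: p = (1 + #{perm importance ≥ observed}) / (1 + nperm). Defaults:
500 trees, nperm = 99 (refits dominate the cost). Constant variables get
importance 0 and p 1 with a warning.

## Co-occurrence networks

ASVs are first filtered to mean relative abundance strictly greater than
0.005 (a fraction, i.e. 0.5%) across the group's samples. All pairwise
Spearman correlations are computed on the table as given (rank-based, so
per-sample monotone rescaling is immaterial), with two-sided p-values from
the t approximation; Benjamini–Hochberg adjustment runs jointly over the
upper triangle; edges require |ρ| ≥ 0.6 and adjusted p < 0.05 (both
explicit parameters — the thresholds are a convention, not a default to
hide). Constant ASVs keep their node but contribute no edges. Topology:
average degree 2E/N; average clustering coefficient (triangles over
possible triangles per node, 0 for degree < 2); average path length over
*connected* pairs only, pair-weighted across components; modularity of the
greedy Clauset–Newman–Moore partition (deterministic). Per-site networks
built from 7 samples have little power after BH correction and come out
sparse; that is the correct inference at that sample size, and the
whole-survey network is the informative object in the worked analyses.

## The synthetic generator

The generator emulates the *design* of a cold-seep survey — `n_sites` = 4
sites × `n_depths_per_site` = 7 five-centimetre depth layers, one
community of `sequencing_depth` = 2000 reads per layer, a 200-taxon
regional pool, and a porewater geochemistry table in which exactly one
variable (CH4) tracks the between-site gradient while eleven others are
nuisance noise.

**Pool phylogeny.** A ladderized radiation: a backbone of exponential
segments totalling height 1, one short pendant tip per rung (pendant scale
`tip_shrink`·height/n ≈ 0.001). Two properties motivate this shape. First,
nearest-relative distance shrinks smoothly the more densely a neighbourhood
of the pool is sampled, as in real ASV tables where lineages contain many
nearly identical sequences. Second, the patristic distribution has no
extreme outliers; on pools with long deep stems, the rare null event
"community misses a whole clade" is orders of magnitude larger than the
typical nearest-taxon distance, and its variance contribution swamps the
βNTI denominator, capping |z| near zero at a 200-taxon scale regardless of
how strongly selection acted. The ladder keeps the null distribution
well-behaved, so the z-score reflects the planted ecology rather than
tree-shape artefacts. (A generic pure-birth simulator with exponential
branch lengths, `simulate_tree`, is kept for random-tree oracles and
calibration tests.)

**Niche trait.** A Brownian walk along the tree with a directional trend
(`trend` = 3, σ = 1): tips inherit their neighbourhood's niche, giving the
phylogenetic niche conservatism the nearest-taxon framework assumes, and
the trend keeps the niche band of any optimum a contiguous stretch of the
radiation instead of the fragmented level-sets of a driftless walk.

**Sampling model.** Expected abundance of taxon i in a sample is

    E_i ∝ base_i · w_i(q) · lottery_i · drift_i

where `base` is log-normal(0, σ = 1) (the regional rank–abundance curve),
and, under the *selection* regime, `w_i(q) = exp(−s (F_i − q)²)` with
`F_i` the empirical CDF of the trait, `q` the site's optimum quantile
(evenly spaced interior quantiles by default), `s` = 200, truncated to 0
below a 5% floor (a fundamental-niche boundary). Standardizing through the
CDF makes the filtered pool a stable fraction (~a quarter) of the taxa
wherever the optimum sits. `lottery` is a Bernoulli(φ = 0.55) colonization
draw per taxon and sample, and `drift` log-normal(0, 1) — local
demographic stochasticity, which is what creates membership turnover
between depth layers of one site. Reads are a single multinomial draw.
Depth layers jitter the optimum slightly (`depth_jitter` = 0.02 quantile
units), keeping "site" the dominant grouping. The *neutral* regime is the
mass-effects end member — expected abundance is `base` alone, no lottery,
no drift — because under the sharp RC null any reproducible extra
abundance noise is (correctly) scored as dispersal limitation. The
*dispersal-limited* regime multiplies in an independent log-normal local
pool perturbation of width 2(1 − `dispersal_m`) per sample, plus the
lottery and drift. Setting `selection_strength = 0`, `colonization_phi = 1`
and `drift_sigma = 0` makes all regimes identical and site-exchangeable.

The lottery probability sits near one half because membership turnover is
the information the nearest-taxon z-score runs on: with T taxa differing
between two samples, |βNTI| scales like √T, and presence probability ~0.5
maximizes T for a given pool. This is a designed property of the
benchmark, set against the generator's own contract (strong selection must
produce within-site βNTI < −2 for most pairs) — not fitted to any
empirical dataset.

**What the generator does not emulate.** Sequencing error, chimeras, PCR
and copy-number bias, compositional coupling beyond the multinomial,
taxonomy, true geochemical covariance structure (real porewater profiles
covary strongly; here one gradient is planted and the rest are
independent), temporal dynamics, and pool sizes beyond a few hundred taxa.
Passing the recovery tests therefore shows the *inference chain* is
internally consistent and statistically calibrated on data that match its
assumptions — not that real seep sediments assemble this way.

## Problem sizes and runtime choices

The test suite and acceptance script run the survey-scale configuration
(4 × 7 samples, 200 taxa, 2000 reads, n_null = 999) for process recovery;
null-model calibration uses 21 uniform-random communities (210 pairs,
n_null = 199) on a 40-taxon tree; PERMANOVA type-I error uses 200
exchangeable replicates at nperm = 99; the bit-reproducibility check runs
the full pipeline twice at a reduced size (80 taxa, 16 samples,
n_null = 99). Oracle equivalence for βMNTD uses 50 random instances of at
most 10 taxa and 6 samples against an explicit double-loop evaluation at
1e-12.

## Known limitations

- βNTI magnitude depends on pool size; with a few hundred taxa the
  framework needs substantial membership turnover to reach |z| > 2, and
  abundance-weighted βNTI is additionally dominated by shared abundant
  taxa. Real datasets with 10³–10⁴ ASVs are more favourable.
- The RC-bray null conditions on occupancy and pooled abundance computed
  from the analysed table itself; with few samples these estimates are
  noisy, and with strong between-site structure the pooled metacommunity
  mixes guilds.
- LSD makes no multiplicity correction beyond the pooled-error t tests
  (that is what "least significant difference" means); treat letters as
  descriptive.
- The greedy modularity partition is deterministic but not optimal;
  modularity values are comparable across networks analysed the same way,
  not global optima.
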