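# Methods

`accdiv` re-implements, as a tested library, the accession-level SNP analysis
workflow used for genebank germplasm panels: genotype QC, diversity
statistics, distance-based AMOVA and pairwise FST, haplotype merging as an
ascertainment-bias diagnostic, geographic correlation tests, individual- and
accession-level PCA with the PC-dispersion statistic, and in-silico pooling.
This note records the models, defaults and numerical choices, and what the
synthetic-data validation does and does not establish.

## Data model

A panel is a diploid biallelic genotype matrix (individuals × markers, calls
hom_ref / het / hom_alt / missing) in which each individual belongs to
exactly one accession — a genebank seed lot treated as a population sample,
typically 5–6 plants.  Passport metadata assigns each accession a taxon, a
biological type (wild / feral / cultivated), an optional agro-climatic zone,
coordinates and an exclusion flag; a genetic map assigns markers a
chromosome and a cM position.

## QC cascade

Filters run in a fixed order: (1) markers with no calls; (2) markers missing
in more than a fraction of individuals (default 0.50); (3) monomorphic
markers; (4) individuals with zero calls on the retained markers; (5)
individuals above a missingness cap (default 0.50 — the cap is a
configurable choice because "too many missing data points" has no canonical
value); (6) accessions left with fewer than 4 individuals; (7) manual
exclusions.  Marker rules precede individual rules because failed assays are
removed before samples are judged.  Monomorphism is evaluated once, on the
individuals present at step 3; a re-check after individual filtering exists
behind `recheck_monomorphic` but is off by default, so QC is idempotent.
The report records counts and ids per rule and satisfies
removed + retained = input for both axes.

## Diversity statistics

Per locus: reference-allele frequency p = (2·hom_ref + het)/(2·n_calls);
observed heterozygosity Ho = het/n_calls; expected heterozygosity
He = 1 − p² − q² (the unadjusted gene diversity, matching GenAlEx's He — the
small-sample-unbiased 2n/(2n−1) variant is available behind a flag);
fixation index F = (He − Ho)/He, undefined where He = 0 and excluded from
means.  Group summaries come as the unweighted mean of accession-level means
(each accession one vote regardless of its n) and as group totals recomputed
from frequencies pooled over all the group's individuals; loci monomorphic
within a group contribute He = 0.

The folded minor-allele-frequency spectrum is compared with the neutral
expectation for haploid sample size m (median of 2 × non-missing
individuals across loci, rounded down to even): class weights
(1/i + 1/(m−i)) / (1 + [i = m−i]) for minor counts i = 1..⌊m/2⌋, binned on
the same frequency grid and scaled to the observed number of polymorphic
markers.  An array panel whose SNPs were discovered in a narrow panel shows
a deficit in the lowest bins against this expectation.

## Haplotype merging and the ascertainment diagnostic

Mapped SNPs are sorted per chromosome by cM (ties by marker id) and cut into
consecutive disjoint windows of exactly k SNPs (k = 1..5); the remainder is
dropped and unmapped markers are never used.  Sliding windows were rejected
to avoid pseudo-replication.  Haplotype frequencies within a block are
estimated from unphased genotypes by an Excoffier–Slatkin-style EM over the
2^k-haplotype simplex (tolerance 1e−8 on the log-likelihood, max 500
iterations, 5 restarts: uniform plus 4 seeded Dirichlet starts; the
log-likelihood is non-decreasing within a run, and data without double
heterozygotes short-circuit to exact counting).  Individuals missing any
member SNP are excluded from that block rather than imputed.  An alternative
estimator that treats each distinct multilocus genotype string as an allele
is available (`mode="genotype_string"`).

The diagnostic reports, per group and k, the mean block gene diversity
He_hap = 1 − Σ f_h² and its ratio to a reference group.  Under
discovery-panel ascertainment the non-discovery groups' ratio rises with k:
merging SNPs into multi-allelic loci restores variation that per-SNP
discovery filtering suppressed.

## Distances, AMOVA and FST

The genetic distance between diploid genotypes is the squared codominant
(Smouse–Peakall) distance — 0 for identical genotypes, 1 when one allele is
shared, 4 for opposite homozygotes, i.e. the squared difference of the
0/1/2 dosage coding — summed over loci where both individuals have calls
(no rescaling by the number of shared loci; a per-locus-normalized variant
sits behind a flag).

AMOVA decomposes these squared distances into among-group, among-accession-
within-group and within-accession sums of squares, with method-of-moments
variance components for unequal sample sizes and Φ-statistics.  Negative
components are retained in the raw output and floored at zero for
percentages and reported Φ (the convention of the standard software).
Permutation tests (default 999, seeded) shuffle whole accessions among
groups for the among-group Φ, individuals among accessions within their
group for the among-accession Φ, and individuals anywhere for Φ_ST; the
observed value is included in the count (p = (#≥obs + 1)/(n_perm + 1)).
Permutations compare the *unfloored* statistic — truncating at zero would
stack the null distribution at a point mass and destroy calibration.

Two unit levels are exposed.  With `unit="genotype"` the individuals are the
units (PhiPT style); under Hardy–Weinberg structure with allele-level
differentiation F this Φ has expectation 2F/(1+F), because the
within-individual half of the variance is suppressed.  With `unit="allele"`
each individual contributes its two gene copies and the among-group Φ
estimates F directly.  Both are validated: the allele-level Φ against the
simulated F_CT, the genotype-level Φ against its 2F/(1+F) mapping, and
Weir & Cockerham's θ is provided as an independent cross-check estimator.
Pairwise FST between groups is the among-group Φ of a two-population AMOVA,
tested by shuffling individuals between the two groups; small negative
estimates are preserved.

Nei's standard distance uses D = −ln I with I = Jxy/√(Jx·Jy), the J's summed
over loci where both frequency vectors are defined; disjoint fixed alleles
give D = +∞ with a warning rather than an error.

Geographic distances are great-circle (haversine, Earth radius 6371.0 km).
The Mantel test correlates off-diagonal upper triangles and permutes rows
and columns of the second matrix jointly (one-sided positive by default).
Diversity-vs-geography regressions correlate accession He with latitude,
longitude and distance to an assumed origin — default (39.0 N, 35.0 E),
central Anatolia, configurable because only the region is conventionally
agreed.  These use two-tailed permutation p-values by default.  ANOVA and
t-tests on accession-level statistics are thin wrappers over
scipy/statsmodels.

## PCA, PC dispersion and near-identical individuals

Accession-level PCA decomposes the column-centered (unscaled) accession ×
locus allele-frequency matrix by SVD; individual-level PCA codes genotypes
0/1/2, imputes missing calls with the locus mean, and centers.  A
deterministic sign convention (largest-|loading| element positive) makes
coordinates reproducible.  PC dispersion is the mean and variance
(population formula, divided by the number of pairs) of all pairwise
Euclidean distances among an accession's individuals in the *full* PC
space.  Because full-rank PCA is an orthogonal rotation, these distances
equal distances in the centered imputed input space — the scaling choice is
therefore the only free parameter, and it is logged in the PCA result
(`coding`).  Near-identical individuals are flagged by identity-by-state
(fraction of matching calls over ≥100 shared loci, default threshold 0.99 —
no canonical value exists, so it is surfaced prominently); re-analysis drops
the lexicographically later member of each flagged pair.

## In-silico pooling

Each accession collapses to one pseudo-genotype per marker: with equal
weight per non-missing individual, the call is heterozygous when the major
allele's frequency is below the cutoff (default 0.75) and homozygous for the
major allele otherwise.  Exactly 0.75 is *not* below the cutoff
(homozygous); an exact 0.5 tie is (heterozygous).  Pooled pseudo-genotypes
are treated as one diploid individual per accession for diversity.  The
capture fraction per group is pooled group-total He over un-pooled
group-total He; it can exceed 1 when pooling symmetrises frequencies, so it
is reported, not bounded.  Pooling retains most gene diversity but
sacrifices structure resolution: the within-accession level collapses to a
single unit, and on simulated panels the pooled among-cluster Φ deviates
more from the simulated truth than the un-pooled estimate.

## Synthetic data

The generator uses the Balding–Nichols beta hierarchy: ancestral frequency
p0 per locus (uniform or neutral-SFS law); cluster frequencies from
Beta(p0·(1−F_CT)/F_CT, q0·(1−F_CT)/F_CT), so Var = p0·q0·F_CT; accession
frequencies likewise below clusters with F_SC; HWE genotypes with optional
inbreeding F_IS.  This was chosen over coalescent simulation because the
analyses consume frequency-level structure only, and the targets (F_CT,
F_SC) map directly onto what AMOVA estimates.  Ascertainment is rejection
sampling: a locus is kept only if a small discovery sample (default 8
individuals from the discovery accessions) carries ≥ 2 minor-allele copies;
configs whose acceptance rate falls below 1e−4 are rejected with a
diagnostic.  Optional extras: per-cluster MCAR missingness, clone
individuals (duplicates with a per-locus error rate, labelled in the truth
record so duplicate detection has known positives), a uniform cM map, and
coordinates jittered around cluster centroids.

Registered fixtures define the validation conditions:

* `tiny` — 2 accessions × 3 individuals × 10 markers, for hand-checkable
  end-to-end runs;
* `rye-like-default` — 3 clusters × 8 accessions × 6 individuals, 600
  markers, F_CT = 0.03, F_SC = 0.10, ascertainment from cluster 1,
  per-cluster missingness 3/5/8 % (the missingness range typical of array
  genotyping of wild-to-cultivated panels);
* `biased-panel` — 2 clusters × 6 accessions × 6 individuals, 400 markers,
  F_CT = 0.30, F_SC = 0.05, strong ascertainment from cluster 1, for the
  bias diagnostic.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent — haplotype-block tests exercise frequency structure, not LD),
selection, demography through time, genotype-calling error structure, or
non-random missingness.  Passing tests therefore establish that the
estimators recover frequency-level hierarchical structure and that the
diagnostics move in the right direction under ascertainment, not that the
pipeline is robust to LD or call-quality artefacts in real data.

## Validation problem sizes

Parameter recovery uses 20 replicates per F_CT ∈ {0.05, 0.15, 0.30} of the
3 × 8 × 6, 600-locus panel; the mean among-cluster Φ lands within ±0.03 of
target.  Permutation calibration uses 200 null replicates with 999
permutations each (split-half panmictic panels of 24 individuals × 100 loci
for FST; 10-accession random matrices for Mantel), rejecting at α = 0.05
between 2 % and 9 % of the time.  Oracle-equivalence checks run on random
panels of ≤ 30 individuals against definitional (coordinate-route)
computations.  These sizes were chosen so the full validation completes in
minutes on one CPU while keeping Monte-Carlo error far below the asserted
tolerances.

## Known limitations

* The wide-TSV genotype dialect carries ref/alt implicitly (token order);
  the VCF reader takes REF as the reference allele and rejects
  multi-allelic sites rather than splitting them.
* EM haplotype frequencies are maximum-likelihood under random mating
  within the member set; estimating them per accession with 5–6 individuals
  is noisy, which is why the bias diagnostic pools individuals per group.
* The genotype-level Φ (PhiPT-style) is kept as the default because it is
  what the comparison software reports, but it is *not* an unbiased FST
  estimator; use `unit="allele"` or Weir–Cockerham θ when the allele-level
  quantity is wanted.
* Bayesian model-based clustering (STRUCTURE-type) is intentionally out of
  scope; the package only exports STRUCTURE input files.
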