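# Methods

This note records the models implemented in `cohortnb`, their
assumptions, the defaults that matter, and the design choices made where
the method left room.

## Ageing and cohort assignment

Lengths are converted FL→TL by ordinary least squares on paired
measurements (`fit_length_conversion`); residual diagnostics are reported
but not enforced. Ages come from inverting the von Bertalanffy growth
function, age = t₀ − ln(1 − TL/L∞)/k, defined for 0 < TL < L∞; lengths at
or beyond the asymptote are rejected rather than clamped. Ages are
rounded to the **nearest** whole year by default (a `floor` option
exists): birth-year binning needs integers, and nearest-rounding is
unbiased for mid-year births. When a sample carries a measured TL it is
used directly and the conversion bypassed (the conversion exists because
TL is often unmeasurable at capture). Cohorts are retained when they
contain strictly more than `min_n` = 25 samples, because single-sample
estimators are badly biased at small cohort sizes.

VBGF parameters are required configuration for real data — there are no
silent defaults. The fixture curve used in tests and examples
(L∞ = 600 cm, k = 0.056 /yr, t₀ = −4.3 yr) is an arbitrary synthetic
constant chosen to give ~20 cm/yr juvenile growth; it is **not** an
estimate for any real population.

## QC cascade

Thresholds (all logged at run time): locus reproducibility ≥ 0.98,
minor-allele count strictly > 3, mean read depth in [5, 25]
("coverage" is interpreted as mean read depth per locus), one SNP per
clone/fragment tag (first in file order kept), monomorphic removal,
individual missingness strictly > 20% dropped, Hardy–Weinberg exact
mid-p < 0.01 removed, |F_IS| ≥ 0.5 removed (inclusive). The filter order
is fixed and logged because removal counts depend on it; the cascade is
idempotent. HWE/F_IS filtering is applied globally, not per cohort
(logged choice). F_IS = 1 − H_o/H_e uses Nei's unbiased expected
heterozygosity, so a locus where every individual is heterozygous has
F_IS slightly above −1 at finite n.

The exact HWE test enumerates the conditional (Levene) distribution of
the heterozygote count given the allele counts, in log space; mid-p sums
strictly-less-probable tables plus half the probability of
equally-probable tables (ties resolved at 1e−12 relative tolerance).
Multi-allelic loci use a Monte-Carlo permutation version (default 10,000
permutations) with the conditional table probability as statistic and the
(count+½(ties+1))/(reps+1) mid-p convention.

The outlier-locus scan regresses standardized, mean-imputed dosages on
the first k = 3 principal components (orthonormal scores, so z = β/σ̂),
combines the k z-scores into a Mahalanobis distance, rescales by the
genomic inflation factor (median distance over the χ²(k) median), and
flags loci at Benjamini–Hochberg q < 0.05. BH is a deliberate,
documented replacement for the smoothed q-value machinery some outlier
scanners use.

The divergent-individual (migrant) screen flags individuals whose
distance from the group's median centroid exceeds the median distance by
more than 6 median absolute deviations. The distance is taken in full
standardized-genotype space by default (equivalently, all PC axes
weighted by their singular values) rather than on 2–3 unit-scaled leading
axes: equal-scaled leading axes let a near-noise axis — for instance one
created by a duplicated sample — dominate, producing false flags, whereas
data-space distances make genuinely diverged individuals stand out by
orders of magnitude while duplicates sit at typical distances. A
leading-axes variant remains available via `n_axes`. This centroid
screen is a declared simplification of a discriminant-analysis
(DAPC-style) migrant test.

Duplicate genotypes are pairs whose mismatch rate over co-called loci is
≤ 1%; the second member is the removal candidate.

## LD method

For two diallelic loci the composite association is Burrows' Δ̂ computed
over individuals called at both loci, with the n/(n−1) small-sample
factor and Weir's homozygosity correction in the denominator:

    Δ̂ = [n/(n−1)] (Σ X_i Y_i / 2n − 2 p_A p_B)
    r  = Δ̂ / sqrt((p_A q_A + D_A)(p_B q_B + D_B))

with X, Y allele dosages and D_A the departure of the homozygote
frequency from p_A². Algebraically r equals n/(n−1) times the
maximum-likelihood Pearson correlation of the dosage vectors, which is
how the all-pairs computation is vectorised (per-pair sufficient
statistics as matrix products, float32, complete-cases per pair). The
equivalence is also kept as an independent test oracle. Because of the
n/(n−1) factor, a locus paired with its own copy gives r² = (n/(n−1))²,
not exactly 1.

Alleles with minor-allele frequency below Pcrit = 0.05 are excluded
(rare alleles bias r² upward); pairs with fewer than 5 complete
individuals are skipped; pairs are weighted by their complete-case count
and S is the harmonic mean of per-pair counts.

The sampling expectation subtracted from r̂² is E[r̂²|S] = 1/S + 3.19/S²
for S ≥ 30 and 0.0018 + 0.907/S + 4.44/S² below (random mating), and the
drift relationship is inverted through the standard quadratic
N̂ = (1/3 + √(1/9 − 2.76 r̂²′))/(2 r̂²′) (0.308/2.08 coefficients for
S < 30). These regression constants come from the LD-method literature,
not from this package. Two boundary conventions: a non-positive drift
signal maps to **+∞** (the sample cannot distinguish the pool from an
infinite one), and a drift signal beyond the quadratic's domain
(negative discriminant) collapses to the small-N boundary solution —
a huge r̂² means a tiny pool, never an infinite one.

Confidence intervals are a delete-one-**individual** jackknife (not
locus pairs), which accounts for the pseudo-replication of overlapping
pairs: leave-one-out estimates are transformed to the 1/N̂ scale (∞ → 0),
the jackknife variance is formed there, and the normal-theory interval is
back-transformed with non-positive bounds mapping to +∞. The Pcrit locus
screen is fixed from the full sample. A complete-data fast path downdates
only the L×L cross-product matrix per deletion; with missing data all
four per-pair sufficient-statistic matrices are downdated.

## Sibship method

Pair likelihoods use per-locus genotype-pair probabilities under IBD
coefficients k = {1,0,0} (unrelated), {½,½,0} (half-sib), {¼,½,¼}
(full-sib), with allele frequencies fixed from the cohort sample (no
update) and a symmetric genotyping-error mixture: an allele is replaced
by a uniform draw from the allele set at rate 0.001 (effective flip
probability e/2 for diallelic loci), entering as a 3×3 confusion matrix
on each side of the true-pair probability table. Dyads need ≥ 100
informative co-called loci; monomorphic loci are skipped. A dyad's
`support` is the log-likelihood margin of the best hypothesis over the
second best; a sib call whose margin over *unrelated* is below 3 natural-
log units is conservatively demoted to unrelated.

Reconstruction is pairwise-ML + graph clustering, a declared
simplification of a full-pedigree simulated-annealing search: full-sib
edges are closed transitively into maternal families, with open triangles
(two edges whose closing dyad was not called full-sib) resolved by
dropping the lower-support edge; half-sib edges join families into
paternal groups. Under the default female-monogamy/male-polygamy system
Q₂ = 0 within a cohort (a monogamous female has one litter and one sire
per cycle), N₂ = number of families, N₁ = number of paternal groups, and
Q₁/Q₃ are the dyad fractions **implied by the reconstruction** over all
C(n,2) dyads. Under both-polygamous mating half-sib links cannot be
sexed; the implied half-sib fraction is split evenly between Q₁ and Q₂
(documented heuristic). α defaults to 0 (random mating); the cohort's
multilocus F_IS can be supplied instead. A sibship-size prior is not
replicated; with thousands of SNPs the pairwise likelihoods are
decisive, and the estimator is insensitive to such priors at this marker
density.

Bootstrap CIs resample individuals with replacement, hold the
reconstructed family/group memberships fixed, and recompute the implied
dyad fractions under the resample multiplicities; dyads formed by two
copies of the same individual are excluded from numerator and
denominator. Percentile intervals use order-statistic (nearest)
quantiles so infinite resamples never interpolate; more than 50%
infinite resamples force an infinite upper bound. The bootstrap median
is reported alongside the point estimate as a replicate-averaged
summary.

## Combining estimates and ratios

Variances are recovered from 95% CIs by treating ln(N̂) as normal:
sd_ln = (ln hi − ln lo)/(2·1.96), var(N̂) = N̂²·sd_ln² (an alternative
1/N-scale recovery is exposed via `variance_scale="inverse"`). Weights
are ∝ 1/var and the combination is the weighted harmonic mean
1/(w_LD/N̂_LD + w_SA/N̂_SA), with the SD propagated by the delta method on
the 1/N scale. Any infinite point or bound refuses combination rather
than truncating — an infinite bound means the cohort's data cannot
support a finite combined value. Nb/Na divides the combined value by a
census adult estimate; the interval endpoints divide by the Na range
endpoints. The stability check is an explicitly-labelled heuristic: a
cohort series is "stable" iff all pairwise 95% CIs overlap.

## Demographic expectations

The deterministic calculator assumes a stationary population recruiting
N₁ age-1 individuals per cycle, survivorship l_a from the life table, and
within-age offspring numbers with mean b_a (rescaled so Σ l_a b_a = 2 per
sex) and variance φ·b_a (φ = 1, Poisson, by default), independent across
ages. Lifetime Vk follows by accumulating these moments over the
age-at-death distribution; Ne = 4N₁T/(V̄k + 2) with T the age-weighted
mean parental age and V̄k pooled across sexes. Per-cycle Nb applies the
Crow–Denniston form Ne = (k̄N−2)/(k̄−1+Vk/k̄) to each sex's mature pool
(season fecundities rescaled to a season total of N₁) and combines the
sexes as 4·N_f·N_m/(N_f+N_m).

The forward simulator recruits exactly N₁ age-1 individuals per cycle
from parents drawn ∝ age-specific fecundity among alive, mature,
non-skipping adults (population seeded at the stable age distribution;
family sizes multinomial, hence Poisson-like at large pools; optional
negative-binomial overdispersion). A female that breeds skips the next
`skip` ∈ {0,1,2} cycles; the fraction of breeders subject to the rule is
configurable and defaults to 1.0. Per-cycle Nb comes from the realized
offspring counts of that cycle's eligible pools; generational Ne is the
Crow–Denniston size of the lifetime offspring-number distribution of
completed cohorts multiplied by the realized generation length. Reported
values are harmonic means of Ne and Nb and arithmetic means of k̄ and Vk
across replicates (10 by default, 50 tracked cycles after a 50-cycle
burn-in). With skip = 0 the simulator and the deterministic calculator
describe the same process; the validation suite requires them to agree
within 5% relative on both Ne and Nb, and observed agreement is ~0.1%.

The shipped life table (`white_shark_life_table`) is **synthetic**:
max age 40, annual survival 0.9, female maturity 15, male maturity 10,
flat adult fecundity, N₁ = 1,000. It is demographically plausible for a
long-lived shark but fitted to nothing; analyses of real populations
must supply their own vital rates.

## Synthetic-data engine: what it does and does not emulate

`simulate_study` emulates the study design this pipeline targets: four
consecutive birth cohorts, ~50 juveniles sampled per cohort, thousands of
diallelic loci, parent pools of order 10²–10³ per cycle, female
skip-breeding (default skip = 1, matching a multi-season gestation),
VBGF lengths with 4 cm Gaussian measurement noise (chosen so that ~98%
of juveniles round to the correct age on a curve separating consecutive
ages by ~20 cm), uniform allele-replacement genotyping error at 0.001
and 2% missing calls. Genotypes are dropped down the pedigree by fair
Mendelian transmission from founder frequencies drawn Uniform(0.1, 0.9),
genotyping only the sampled individuals' ancestor closure.

Deliberately absent: mutation, migration, selection, spatial structure,
physical linkage (all loci independent by construction), null alleles
and allelic dropout, and any non-uniform error process. Passing
recovery tests on these data therefore demonstrates correctness of the
estimators under their own assumptions — independent neutral loci in a
closed population — not robustness to linked loci, admixture or
structured error, which real reduced-representation data can violate.

The Wright–Fisher harness (`make_ideal_wf_population`) uses discrete
generations, random mating without selfing and multinomial offspring
numbers, with a 40-generation burn-in: the drift LD among unlinked loci
needs roughly that long to reach its equilibrium level, and shorter
burn-ins leave r² below equilibrium, biasing recovery upward. The
parent-pool harness (`sample_cohort_from_parent_pool`) pairs mothers and
sires bijectively by default so the pool's demographic Nb is close to
its nominal size; drawing sires with replacement instead exposes the
male-variance reduction of Nb.

## Validation conditions

The reference benchmarks (also run by `scripts/acceptance.py`): LD — 20
Wright–Fisher replicates at true Ne 200, S = 50, 3,000 loci, Pcrit 0.05;
median within ±15% and ≥80% jackknife-CI coverage required. SA — 10
replicates each at true Nb 50 and 200, 3,000 loci, 50 sampled from 1,000
offspring; median within ±20% of the realized demographic truth and
full-sib recall ≥ 0.95. HWE — exhaustive agreement with direct-counting
enumeration over all 285 genotype tables with n ≤ 10. Expectations —
deterministic vs forward at N₁ = 1,000, 10 replicates, 5% tolerance, and
strict Nb/Ne monotonicity across skip ∈ {0,1,2}. These sizes are the
package's reference conditions; they run in a few minutes on one CPU.

## Known limitations

* The LD sampling-bias constants assume random mating; no monogamy or
  two-sample (temporal) variants are provided.
* Pairwise sibship reconstruction can, at low marker counts, split true
  families (lowering Q₃) or chain unrelated dyads through weak links;
  the margin rule trades recall for precision. Agreement with
  full-pedigree-likelihood tools is statistical, not exact.
* Bootstrap sibship CIs hold the reconstruction fixed, so they reflect
  resampling of dyad fractions, not uncertainty in the clustering
  itself.
* CI-based variance recovery in the combiner is approximate (lognormal
  assumption); the exact weighting used by any particular published
  analysis may differ in detail.
* The deterministic calculator cannot represent carry-over effects such
  as skip breeding — that is precisely what the forward simulator adds.
* No polyploidy, phased haplotypes, or sequence-level input; genotype
  calling is upstream of this package.
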