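# cohortnb

Estimating the **effective number of breeders (Nb)** per birth cohort from
juvenile genotypes — and relating it to census adult numbers and to
generational effective population size (Ne) through life-history
simulation.

## The problem

For long-lived, hard-to-count marine species (sharks are the motivating
case), monitoring abundance directly is often impossible, but tissue
samples of juveniles accumulate through tagging and bather-protection
programmes. A single cohort of juveniles carries a genetic imprint of how
many adults actually bred in the cycle that produced it. `cohortnb` is a
library for population geneticists who want to turn such samples into a
year-by-year Nb series:

1. **Ageing & cohorts** — convert fork length to total length by a fitted
   linear regression, invert the von Bertalanffy growth function
   L(t) = L∞(1 − e^(−k(t−t₀))) to get an age, and bin samples into
   birth-year cohorts (retained when n > 25).
2. **QC** — locus reproducibility, minor-allele count, read depth,
   one-SNP-per-fragment, individual missingness, exact Hardy–Weinberg
   mid-p and F_IS screens, duplicate detection, a PCA outlier-locus scan
   and a divergent-individual (migrant) screen.
3. **Nb(LD)** — the linkage-disequilibrium method: the weighted mean
   squared composite (Burrows) correlation r̂² between unlinked loci,
   corrected for the sampling contribution E[r̂²|S], inverted through
   N̂ = 1/[3(r̂² − 1/S)] (with second-order refinements) and given a
   delete-one-individual jackknife CI.
4. **Nb(SA)** — the sibship-assignment method: maximum-likelihood
   classification of every dyad as unrelated / half-sib / full-sib,
   clustering into maternal families and paternal groups, then
   1/N̂ = [(1+3α)/4](Q₁ + Q₂ + 2Q₃) − (α/2)(1/N₁ + 1/N₂),
   with Q₁/Q₂/Q₃ the paternal half-sib, maternal half-sib and full-sib
   dyad fractions and N₁/N₂ the father/mother counts.
5. **Combination & ratios** — inverse-variance-weighted harmonic mean
   Nb(LD+SA), Nb/Na against a census adult estimate, and an
   across-cohort CI-overlap stability screen.
6. **Expectations** — a deterministic hybrid Felsenstein–Hill calculator
   (Ne = 4N₁T/(Vk+2)) and a forward-time age-structured pedigree
   simulator with female skip-breeding, giving the expected Nb/Ne ratio
   for a given life table.

Everything is validated end-to-end against the built-in synthetic-data
engine (`cohortnb.synthdata`), which simulates pedigreed age-structured
populations whose true demographic Nb and Ne are known exactly
(Crow–Denniston: Ne = (k̄N−2)/(k̄−1+Vk/k̄)).

## Worked example

`examples/04_nb_ld.py` samples 50 individuals from an ideal
Wright–Fisher population of true size 200 and runs the LD estimator on
1,500 unlinked SNPs:

```text
true Ne                : 200
mean r^2               : 0.022881 over 965,355 pairs
E[r^2 | S=50 sampling] : 0.021276
drift signal           : 0.001605
Nb(LD)                 : 205.6 (95% CI 147.9 - 337.3)
```

The mean pairwise r² (0.0229) is mostly an artefact of sampling only 50
individuals (0.0213 expected with no drift at all); the excess 0.0016 is
the drift signal, and 1/(3·0.0016) ≈ 206 breeders — within sampling error
of the true 200, with a jackknife interval that covers it.

`examples/07_expectations.py` shows the life-history side on a synthetic
long-lived shark-like life table (N₁ = 1,000 recruits/cycle):

```text
deterministic (Felsenstein-Hill hybrid):
  generation length T = 20.0 cycles, adults ~ 2933
  Nb = 2713.2, Ne = 3434.4, Nb/Ne = 0.79

forward pedigree simulation (5 replicates, 50+50 cycles):
  skip=0: Nb =  2696.5, Ne =  3417.2, Nb/Ne = 0.79  <- matches the deterministic model
  skip=1: Nb =  1845.5, Ne =  3508.5, Nb/Ne = 0.53
  skip=2: Nb =  1359.4, Ne =  3549.1, Nb/Ne = 0.38
```

The no-skip simulation reproduces the deterministic calculator (mutual
validation); forcing females to skip one or two cycles after breeding —
as expected under a multi-season gestation — lowers Nb per cycle while
leaving generational Ne nearly unchanged, so Nb underestimates Ne in
species with intermittent breeding.

The other examples cover study-like data generation with known truth
(`01`), ageing and cohort assignment (`02`), the QC cascade (`03`), the
sibship estimator (`05`) and estimate combination with Nb/Na ratios
(`06`).

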