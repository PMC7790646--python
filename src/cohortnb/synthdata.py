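"""Synthetic pedigreed populations with known Nb/Ne and study-like outputs.

This module is the ground-truth engine of the package: it simulates
age-structured populations forward in time under a life table and a
breeding scheme (optionally with female skip-breeding), drops unlinked
genotypes down the pedigree, and emits capture-style metadata (fork lengths
from a von Bertalanffy curve plus measurement noise, capture years), so
that every downstream stage - ageing, QC, the LD and sibship estimators,
estimate combination and the demographic expectations - can be tested
against known truth without external data.

Simplifications relative to real data: loci are unlinked by construction,
there is no mutation, migration, selection or spatial structure, and
genotyping error is uniform allele replacement.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._demography import combine_sexes, crow_denniston, k_stats
from .rng import stream
from .types import (
    BreedingScheme,
    GenotypeMatrix,
    LengthConversion,
    LifeTable,
    Pedigree,
    SampleRecord,
    VBGFParams,
)

__all__ = [
    "white_shark_life_table",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_lengths",
    "make_ideal_wf_population",
    "sample_cohort_from_parent_pool",
    "simulate_study",
    "FIXTURE_VBGF",
    "FIXTURE_CONVERSION",
]

# Fixture growth constants. These are NOT estimates for any real population:
# the VBGF parameters of the study system live in its own supplementary
# growth literature, so real analyses must supply their own curve. Tests
# only need *a* monotone curve with ~20 cm/yr juvenile growth.
FIXTURE_VBGF = VBGFParams(L_inf=600.0, k=0.056, t0=-4.3)
FIXTURE_CONVERSION = LengthConversion(intercept=6.80, slope=1.07, r_squared=1.0, n=0)


def white_shark_life_table(n1: int = 1000, max_age: int = 40) -> LifeTable:
    """Synthetic white-shark-like life table (iteroparous, late maturity).

    Annual survival 0.9 at all ages, female maturity at age 15, male
    maturity at age 10, flat adult fecundity. A synthetic stand-in for
    species-specific vital rates, chosen to be demographically plausible
    for a long-lived shark; not fitted to any dataset.
    """
    ages = np.arange(1, max_age + 1)
    surv = np.full(max_age, 0.9)
    surv[-1] = 0.0
    fec_f = np.where(ages >= 15, 1.0, 0.0)
    fec_m = np.where(ages >= 10, 1.0, 0.0)
    return LifeTable(ages, {"F": surv, "M": surv.copy()}, {"F": fec_f, "M": fec_m}, n1)


def _as_rng(seed: Union[int, np.random.Generator], name: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return stream(seed, name)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    life_table: LifeTable,
    scheme: BreedingScheme,
    n_cycles: int,
    n1_recruits: Optional[int] = None,
    seed: Union[int, np.random.Generator] = 0,
) -> Pedigree:
    """Forward-time, age-structured pedigree simulation.

    Each cycle, exactly ``n1_recruits`` offspring that survive to age 1 are
    produced by parents drawn from the alive, mature, non-skipping adults
    with probability proportional to their age-specific fecundity. Under
    female monogamy a breeding female has a single sire for her litter
    (males may sire several litters); under ``both-polygamous`` every
    offspring draws its father independently. A female that breeds is
    ineligible for the next ``skip_pattern`` cycles (applied to a
    ``skip_fraction`` of breeders). Survival to the next age follows the
    life table; the population is seeded at the stable age distribution.

    The returned pedigree carries a ``cycle_info`` DataFrame with, per
    cycle, the eligible parent-pool sizes, distinct mother/father counts
    and the realized demographic Nb of that cycle (per-sex Crow-Denniston
    combined across sexes).

    ``death_cycle`` is the cycle at whose end the individual died, or -1 if
    alive when the simulation ended.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = _as_rng(seed, "synthdata.pedigree")
    n1 = int(n1_recruits) if n1_recruits is not None else life_table.n1
    if n1 < 2:
        raise ValueError("need at least 2 recruits per cycle")
    max_age = life_table.max_age

    # seed founders at the stable age distribution
    founders = []
    for sex in LifeTable.SEXES:
        l = life_table.survivorship(sex)
        for a_i, a in enumerate(life_table.ages):
            count = int(round(n1 / 2.0 * l[a_i]))
            founders.extend([(sex, 1 - int(a))] * count)
    n_founders = len(founders)
    capacity = n_founders + n_cycles * n1
    sex = np.empty(capacity, dtype="U1")
    birth = np.zeros(capacity, dtype=np.int32)
    mother = np.full(capacity, -1, dtype=np.int32)
    father = np.full(capacity, -1, dtype=np.int32)
    death = np.full(capacity, -1, dtype=np.int32)
    for i, (s, b) in enumerate(founders):
        sex[i], birth[i] = s, b
    n_total = n_founders
    alive = np.ones(capacity, dtype=bool)
    alive[n_total:] = False
    skip_until = np.zeros(capacity, dtype=np.int32)

    fec = {s: life_table.fecundity[s] for s in LifeTable.SEXES}
    surv = {s: life_table.survival[s] for s in LifeTable.SEXES}
    info_rows = []

    for t in range(1, n_cycles + 1):
        age = t - birth[:n_total]
        alive_now = alive[:n_total]
        valid_age = (age >= 1) & (age <= max_age)

        def eligible(s: str, t=t, age=age, alive_now=alive_now, valid_age=valid_age):
            mask = alive_now & valid_age & (sex[:n_total] == s)
            idx = np.nonzero(mask)[0]
            w = fec[s][age[idx] - 1]
            idx = idx[w > 0]
            w = w[w > 0]
            if s == "F":
                ok = skip_until[idx] < t
                idx, w = idx[ok], w[ok]
            return idx, w

        fem_idx, fem_w = eligible("F")
        mal_idx, mal_w = eligible("M")
        if len(fem_idx) == 0 or len(mal_idx) == 0:
            raise RuntimeError(f"no eligible {'females' if len(fem_idx) == 0 else 'males'} "
                               f"in cycle {t}")

        if scheme.family_size == "negative-binomial":
            fem_w = fem_w * rng.gamma(scheme.nb_dispersion, 1.0 / scheme.nb_dispersion, len(fem_w))
            fem_w = np.maximum(fem_w, 1e-12)
        moms = rng.choice(fem_idx, size=n1, p=fem_w / fem_w.sum())
        if scheme.mating_system == "female-monogamy":
            uniq_moms = np.unique(moms)
            sires = rng.choice(mal_idx, size=len(uniq_moms), p=mal_w / mal_w.sum())
            sire_of = dict(zip(uniq_moms.tolist(), sires.tolist()))
            dads = np.array([sire_of[m] for m in moms.tolist()], dtype=np.int64)
        else:
            dads = rng.choice(mal_idx, size=n1, p=mal_w / mal_w.sum())

        new = slice(n_total, n_total + n1)
        sex[new] = np.where(rng.random(n1) < 0.5, "F", "M")
        birth[new] = t
        mother[new] = moms
        father[new] = dads
        alive[new] = True
        n_total += n1

        # realized per-cycle demographic Nb over the eligible pools
        kf = np.bincount(moms, minlength=n_total)[fem_idx]
        km = np.bincount(dads, minlength=n_total)[mal_idx]
        kbar_f, vk_f = k_stats(kf)
        kbar_m, vk_m = k_stats(km)
        nb_f = crow_denniston(kbar_f, vk_f, len(fem_idx)) if kbar_f > 0 else math.inf
        nb_m = crow_denniston(kbar_m, vk_m, len(mal_idx)) if kbar_m > 0 else math.inf
        info_rows.append(
            {
                "cycle": t,
                "n_eligible_f": len(fem_idx),
                "n_eligible_m": len(mal_idx),
                "n_mothers": len(np.unique(moms)),
                "n_fathers": len(np.unique(dads)),
                "nb_demo": combine_sexes(nb_f, nb_m),
            }
        )

        # skip-breeding bookkeeping
        if scheme.skip_pattern > 0:
            breeders = np.unique(moms)
            if scheme.skip_fraction < 1.0:
                breeders = breeders[rng.random(len(breeders)) < scheme.skip_fraction]
            skip_until[breeders] = t + scheme.skip_pattern

        # survival to the next cycle (recruits of this cycle are age 0 and
        # survive to age 1 by construction of N1)
        age_all = t - birth[:n_total]
        candidates = np.nonzero(alive[:n_total] & (age_all >= 1))[0]
        p_surv = np.empty(len(candidates))
        for s in LifeTable.SEXES:
            m = sex[candidates] == s
            p_surv[m] = surv[s][np.minimum(age_all[candidates][m], max_age) - 1]
        dies = rng.random(len(candidates)) >= p_surv
        died = candidates[dies]
        alive[died] = False
        death[died] = t

    ids = np.array([f"I{i:07d}" for i in range(n_total)])
    ped = Pedigree(ids, sex[:n_total], birth[:n_total], mother[:n_total],
                   father[:n_total], death[:n_total])
    ped.cycle_info = pd.DataFrame(info_rows)
    return ped


# ---------------------------------------------------------------------------
# genotype dropping
# ---------------------------------------------------------------------------

def drop_genotypes(
    pedigree: Pedigree,
    n_loci: int,
    founder_allele_freqs: Optional[np.ndarray] = None,
    error_rate: float = 0.001,
    missing_rate: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
    for_ids: Optional[Sequence[str]] = None,
    n_alleles: int = 2,
) -> GenotypeMatrix:
    """Mendelian gene-dropping of unlinked loci down a pedigree.

    Founders draw alleles from ``founder_allele_freqs`` (shape (L,) for
    diallelic frequencies of allele 1, or (L, A) for multi-allelic);
    non-founders receive one fair-Mendelian allele from each parent.
    Per-call genotyping error replaces an allele by a uniform draw from the
    locus's allele set at ``error_rate``; calls are masked at
    ``missing_rate``. When ``for_ids`` is given, only those individuals and
    their ancestor closure are genotyped and only ``for_ids`` returned.
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = _as_rng(seed, "synthdata.genedrop")

    if founder_allele_freqs is None:
        p = rng.uniform(0.1, 0.9, n_loci)
        freqs = np.stack([1 - p, p], axis=1)
    else:
        freqs = np.asarray(founder_allele_freqs, dtype=float)
        if freqs.ndim == 1:
            freqs = np.stack([1 - freqs, freqs], axis=1)
        if freqs.shape[0] != n_loci:
            raise ValueError("founder_allele_freqs must have one row per locus")
        if not np.allclose(freqs.sum(axis=1), 1.0):
            raise ValueError("founder allele frequencies must sum to 1 per locus")
    A = freqs.shape[1]
    if error_rate > 0 and np.any((freqs > 0).sum(axis=1) < 2):
        warnings.warn("monomorphic founder locus with error_rate > 0: "
                      "errors at it are partially unobservable")

    # ancestor closure
    if for_ids is not None:
        index = {s: i for i, s in enumerate(pedigree.ids)}
        want = [index[s] for s in for_ids]
        closure = set()
        frontier = list(want)
        while frontier:
            i = frontier.pop()
            if i in closure:
                continue
            closure.add(i)
            for p_ in (pedigree.mother[i], pedigree.father[i]):
                if p_ >= 0 and p_ not in closure:
                    frontier.append(int(p_))
        rows = np.array(sorted(closure))
    else:
        want = list(range(len(pedigree)))
        rows = np.arange(len(pedigree))

    local = {int(g): i for i, g in enumerate(rows)}
    n = len(rows)
    geno = np.zeros((n, n_loci, 2), dtype=np.int16)
    # process in birth order so parents are genotyped first
    order = np.argsort(pedigree.birth_cycle[rows], kind="stable")
    cum = np.cumsum(freqs, axis=1)
    for start in _birth_groups(pedigree.birth_cycle[rows][order]):
        grp = rows[order[start]]
        loc = np.array([local[int(g)] for g in grp])
        is_f = pedigree.mother[grp] < 0
        if is_f.any():
            fl = loc[is_f]
            u = rng.random((len(fl), n_loci, 2))
            geno[fl] = (u[..., :, None] >= cum[None, :, None, :]).sum(axis=3).astype(np.int16)
        if (~is_f).any():
            gl = loc[~is_f]
            gg = grp[~is_f]
            for parent_col, slot in ((pedigree.mother, 0), (pedigree.father, 1)):
                prows = np.array([local[int(p_)] for p_ in parent_col[gg]])
                pick = rng.integers(0, 2, size=(len(gl), n_loci))
                pg = geno[prows]
                geno[gl, :, slot] = np.take_along_axis(pg, pick[:, :, None], axis=2)[:, :, 0]

    out_rows = np.array([local[i] for i in want])
    calls = geno[out_rows].copy()
    m = len(out_rows)
    if error_rate > 0:
        err = rng.random((m, n_loci, 2)) < error_rate
        repl = rng.integers(0, A, size=(m, n_loci, 2)).astype(np.int16)
        calls[err] = repl[err]
    calls = np.sort(calls, axis=2)
    if missing_rate > 0:
        miss = rng.random((m, n_loci)) < missing_rate
        calls[miss] = -1
    sample_ids = [pedigree.ids[i] for i in want]
    meta = pd.DataFrame({"alleles": [tuple(range(A))] * n_loci})
    return GenotypeMatrix(sample_ids, [f"L{j:05d}" for j in range(n_loci)], calls, meta)


def _birth_groups(sorted_birth: np.ndarray):
    """Yield index arrays of equal-birth-cycle runs in an already-sorted vector."""
    if len(sorted_birth) == 0:
        return
    boundaries = np.nonzero(np.diff(sorted_birth))[0] + 1
    start = 0
    for b in list(boundaries) + [len(sorted_birth)]:
        yield np.arange(start, b)
        start = b


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def simulate_lengths(
    pedigree_sample: Sequence[tuple[str, int]],
    vbgf_params: VBGFParams,
    sd_noise: float,
    capture_years: Sequence[int],
    seed: Union[int, np.random.Generator] = 0,
    conversion: LengthConversion = FIXTURE_CONVERSION,
    max_age: Optional[int] = None,
    include_tl: bool = False,
) -> list[SampleRecord]:
    """Emit capture records with VBGF lengths plus Gaussian measurement noise.

    ``pedigree_sample`` is a sequence of (sample_id, birth_year) pairs
    aligned with ``capture_years``. TL is placed on the growth curve at the
    true age with N(0, sd_noise) noise (truncated positive); FL is
    back-computed through the inverse of the linear FL->TL conversion. By
    default only FL is reported (TL at capture unavailable), exercising the
    conversion downstream.
    """
    rng = _as_rng(seed, "synthdata.lengths")
    if len(pedigree_sample) != len(capture_years):
        raise ValueError("capture_years must align with pedigree_sample")
    records = []
    for (sid, birth_year), cy in zip(pedigree_sample, capture_years):
        age = int(cy) - int(birth_year)
        if age < 0:
            raise ValueError(f"{sid}: capture before birth")
        if max_age is not None and age > max_age:
            raise ValueError(f"{sid}: age {age} beyond life-table maximum {max_age}")
        tl = vbgf_params.length_at_age(age)
        if sd_noise > 0:
            noisy = tl + rng.normal(0.0, sd_noise)
            while noisy <= 0:
                noisy = tl + rng.normal(0.0, sd_noise)
            tl = noisy
        fl = (tl - conversion.intercept) / conversion.slope
        records.append(
            SampleRecord(
                sample_id=sid,
                capture_year=int(cy),
                fork_length_cm=float(fl),
                total_length_cm=float(tl) if include_tl else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# idealized Wright-Fisher population (LD-method validation harness)
# ---------------------------------------------------------------------------

def make_ideal_wf_population(
    ne_true: int,
    n_loci: int,
    n_samples: int,
    seed: Union[int, np.random.Generator] = 0,
    n_generations: int = 40,
    init_freq_range: tuple[float, float] = (0.1, 0.9),
) -> GenotypeMatrix:
    """Sample a single cohort from a closed, randomly mating population of
    constant size ``ne_true`` after ``n_generations`` of burn-in.

    The default burn-in (40 generations) is chosen so the drift LD among
    unlinked loci has reached its equilibrium level; shorter burn-ins
    leave r^2 visibly below equilibrium and bias recovery tests upward.

    Discrete generations, Poisson-equivalent multinomial offspring numbers,
    no monogamy, unlinked diallelic loci: the drift LD in the sampled
    cohort reflects the parental Ne = ``ne_true``.
    """
    if ne_true < 2:
        raise ValueError("ne_true must be >= 2")
    if n_samples > ne_true:
        raise ValueError("cannot sample more individuals than the population holds")
    rng = _as_rng(seed, "synthdata.wf")
    p0 = rng.uniform(*init_freq_range, n_loci)
    dosage = rng.binomial(2, p0[None, :], size=(ne_true, n_loci)).astype(np.int8)
    for _ in range(n_generations):
        pairs = np.array([rng.choice(ne_true, size=2, replace=False) for _ in range(ne_true)])
        gm = dosage[pairs[:, 0]].astype(np.float32) / 2.0
        gf = dosage[pairs[:, 1]].astype(np.float32) / 2.0
        dosage = (
            (rng.random((ne_true, n_loci)) < gm).astype(np.int8)
            + (rng.random((ne_true, n_loci)) < gf).astype(np.int8)
        )
    take = rng.choice(ne_true, size=n_samples, replace=False)
    d = dosage[take]
    calls = np.empty((n_samples, n_loci, 2), dtype=np.int16)
    calls[:, :, 0] = (d == 2).astype(np.int16)
    calls[:, :, 1] = (d >= 1).astype(np.int16)
    meta = pd.DataFrame({"alleles": [(0, 1)] * n_loci})
    ids = [f"W{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(ids, [f"L{j:05d}" for j in range(n_loci)], calls, meta)


# ---------------------------------------------------------------------------
# single-cycle cohort from a known parent pool (SA validation harness)
# ---------------------------------------------------------------------------

def sample_cohort_from_parent_pool(
    n_parents: int,
    n_offspring: int,
    n_sampled: int,
    n_loci: int,
    seed: Union[int, np.random.Generator] = 0,
    mating_system: str = "female-monogamy",
    error_rate: float = 0.001,
    missing_rate: float = 0.0,
    bijective_pairs: bool = True,
) -> tuple[GenotypeMatrix, Pedigree, dict]:
    """One cohort bred by an ideal pool of ``n_parents`` parents.

    Half the pool are mothers, half fathers; litters are multinomial
    (Poisson-like) across mothers, each mother with a single sire under
    female monogamy. With ``bijective_pairs`` (default) mothers and sires
    are matched one-to-one, so both sexes have near-binomial offspring
    variance and the pool's demographic Nb is close to ``n_parents``;
    otherwise each mother's sire is drawn with replacement (male polygamy,
    which inflates male offspring variance and lowers Nb below the pool
    size). Returns the sampled juveniles' genotypes, the full pedigree and
    a truth dict (realized demographic Nb, true parents of each sampled
    individual).
    """
    if n_parents % 2:
        raise ValueError("n_parents must be even (equal sex ratio)")
    rng = _as_rng(seed, "synthdata.parentpool")
    nf = nm = n_parents // 2
    sex = np.array(["F"] * nf + ["M"] * nm)
    moms = rng.integers(0, nf, size=n_offspring)
    if mating_system == "female-monogamy":
        if bijective_pairs:
            sires = rng.permutation(np.arange(nf, n_parents))
        else:
            sires = rng.integers(nf, n_parents, size=nf)
        dads = sires[moms]
    else:
        dads = rng.integers(nf, n_parents, size=n_offspring)
    n_total = n_parents + n_offspring
    ids = np.array([f"P{i:05d}" for i in range(n_parents)]
                   + [f"O{i:05d}" for i in range(n_offspring)])
    birth = np.concatenate([np.zeros(n_parents, int), np.ones(n_offspring, int)])
    mother = np.concatenate([np.full(n_parents, -1), moms])
    father = np.concatenate([np.full(n_parents, -1), dads])
    sex_all = np.concatenate([sex, np.where(rng.random(n_offspring) < 0.5, "F", "M")])
    ped = Pedigree(ids, sex_all, birth, mother, father, np.full(n_total, -1))

    kf = np.bincount(moms, minlength=nf)
    km = np.bincount(dads - nf, minlength=nm)
    nb_f = crow_denniston(*k_stats(kf), nf)
    nb_m = crow_denniston(*k_stats(km), nm)
    take = rng.choice(n_offspring, size=n_sampled, replace=False) + n_parents
    matrix = drop_genotypes(
        ped, n_loci, error_rate=error_rate, missing_rate=missing_rate,
        seed=rng, for_ids=[ids[i] for i in take],
    )
    mom_of = {ids[i]: int(mother[i]) for i in take}
    dad_of = {ids[i]: int(father[i]) for i in take}
    truth = {
        "nb_demo": combine_sexes(nb_f, nb_m),
        "n_parents": n_parents,
        "mother_of": mom_of,
        "father_of": dad_of,
    }
    return matrix, ped, truth


# ---------------------------------------------------------------------------
# full study-like fixture
# ---------------------------------------------------------------------------

def simulate_study(
    seed: int = 0,
    life_table: Optional[LifeTable] = None,
    scheme: Optional[BreedingScheme] = None,
    n_cohorts: int = 4,
    n_per_cohort: int = 50,
    n_loci: int = 3000,
    first_birth_year: int = 2010,
    capture_year_range: tuple[int, int] = (2015, 2018),
    sd_noise: float = 4.0,
    error_rate: float = 0.001,
    missing_rate: float = 0.02,
    vbgf: VBGFParams = FIXTURE_VBGF,
    conversion: LengthConversion = FIXTURE_CONVERSION,
) -> dict:
    """Generate a complete study-like dataset with known truth.

    Emulates the real sampling design: ``n_cohorts`` consecutive birth
    cohorts, ~30-70 juveniles sampled per cohort, thousands of diallelic
    loci, parent pools of order 10^2-10^3 per cycle, female skip-breeding,
    VBGF-distributed lengths with measurement noise. Returns a dict with
    keys ``genotypes`` (sampled juveniles), ``samples`` (capture records),
    ``pedigree``, ``cohort_cycles`` (birth year -> pedigree cycle) and
    ``truth`` (per-cohort demographic Nb and parent counts).
    """
    life_table = life_table or white_shark_life_table()
    scheme = scheme or BreedingScheme(mating_system="female-monogamy", skip_pattern=1)
    rng = stream(seed, "synthdata.study")
    burn_in = life_table.max_age
    n_cycles = burn_in + n_cohorts
    ped = simulate_pedigree(life_table, scheme, n_cycles, seed=rng)

    cohort_cycles = {first_birth_year + i: burn_in + 1 + i for i in range(n_cohorts)}
    sampled_ids: list[str] = []
    birth_years: list[int] = []
    for year, cyc in cohort_cycles.items():
        members = ped.cohort_members(cyc)
        take = rng.choice(members, size=n_per_cohort, replace=False)
        sampled_ids.extend(ped.ids[i] for i in take)
        birth_years.extend([year] * n_per_cohort)

    genotypes = drop_genotypes(
        ped, n_loci, error_rate=error_rate, missing_rate=missing_rate,
        seed=rng, for_ids=sampled_ids,
    )
    capture_years = rng.integers(capture_year_range[0], capture_year_range[1] + 1,
                                 size=len(sampled_ids))
    samples = simulate_lengths(
        list(zip(sampled_ids, birth_years)), vbgf, sd_noise, capture_years.tolist(),
        seed=rng, conversion=conversion, max_age=life_table.max_age,
    )
    info = ped.cycle_info.set_index("cycle")
    truth = {
        "nb_demo_by_cohort": {
            int(y): float(info.loc[c, "nb_demo"]) for y, c in cohort_cycles.items()
        },
        "n_mothers_by_cohort": {
            int(y): int(info.loc[c, "n_mothers"]) for y, c in cohort_cycles.items()
        },
        "n_fathers_by_cohort": {
            int(y): int(info.loc[c, "n_fathers"]) for y, c in cohort_cycles.items()
        },
        "birth_year_of": dict(zip(sampled_ids, birth_years)),
    }
    return {
        "genotypes": genotypes,
        "samples": samples,
        "pedigree": ped,
        "cohort_cycles": cohort_cycles,
        "truth": truth,
    }
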