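"""Life-history expectations for generational Ne and per-cycle Nb.

Single-sample genetic estimators applied to one juvenile cohort return the
effective number of breeders Nb of one reproductive cycle, not the
generational Ne. For a long-lived iteroparous species the two are linked
through the life table: this module provides (a) a deterministic
discrete-time hybrid Felsenstein-Hill calculator that turns sex-specific
survival and fecundity schedules into expected Ne per generation and Nb
per cycle, and (b) a forward-time, age-structured pedigree simulator
(delegating to :mod:`cohortnb.synthdata`) that computes the same
quantities from realized lifetime reproductive success, with optional
female intermittent (skip) breeding - which the deterministic method
cannot represent because it assumes reproduction is independent of past
events. With no skipping the two routes agree, which is used as a mutual
cross-check; skip breeding lowers Nb per cycle relative to Ne per
generation.

All effective sizes here are demographic (from offspring-number means and
variances via the Crow-Denniston discrete form), not genetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._demography import combine_sexes, crow_denniston, k_stats
from .rng import stream
from .types import BreedingScheme, LifeTable

__all__ = [
    "DemographicRecord",
    "agene",
    "forward_expectations",
    "demographic_ne",
]


@dataclass
class DemographicRecord:
    """Demographic Ne/Nb summary (deterministic or cross-replicate)."""

    kbar: float  # mean lifetime offspring number per cohort member
    vk: float  # variance of lifetime offspring number
    ne: float  # effective size per generation
    nb: float  # effective number of breeders per cycle
    nb_ne_ratio: float
    generation_length: float  # mean age of parents of newborns, in cycles
    adult_census: float  # expected number of mature individuals alive
    stable_age: Optional[pd.DataFrame] = None
    per_replicate: Optional[pd.DataFrame] = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# deterministic hybrid Felsenstein-Hill calculator
# ---------------------------------------------------------------------------

def agene(life_table: LifeTable, phi: float = 1.0) -> DemographicRecord:
    """Deterministic Ne/Nb from a life table (hybrid Felsenstein-Hill).

    Assumes a stationary population recruiting N1 age-1 individuals per
    cycle, survivorship l_a from the life table, and within-age offspring
    numbers with mean b_a (rescaled so each sex's newborn cohort replaces
    itself: sum_a l_a b_a = 2) and variance phi * b_a (phi = 1: Poisson).
    Reproduction at different ages is independent. Then per sex

        E[k]  = sum_a l_a b_a = 2
        E[k2] = sum_a l_a (phi b_a + b_a^2) + 2 sum_{a<c} l_c b_a b_c
        Vk    = E[k2] - 4

    and Ne = 4 N1 T / (Vk + 2) with T the age-weighted mean age of
    parents and Vk pooled across sexes. Nb is computed within one cycle
    from the mature pools: per sex, the N_x = (N1/2) l_x adults at each
    reproducing age produce season offspring with mean b_x (rescaled to a
    season total of N1) and variance phi b_x; the resulting offspring-
    number mean/variance enter the Crow-Denniston form and the sexes are
    combined as 4 Nf Nm / (Nf + Nm).
    """
    n1 = life_table.n1
    per_sex = {}
    for sex in LifeTable.SEXES:
        l = life_table.survivorship(sex)
        b_rel = life_table.fecundity[sex]
        tot = float((l * b_rel).sum())
        if tot <= 0:
            raise ValueError(f"no reproduction for sex {sex}")
        b = b_rel * (2.0 / tot)  # lifetime replacement: sum l_a b_a = 2
        ages = life_table.ages.astype(float)
        T = float((ages * l * b).sum()) / 2.0

        ek2 = float((l * (phi * b + b * b)).sum())
        cross = 0.0
        for ai in range(len(ages)):
            for ci in range(ai + 1, len(ages)):
                cross += l[ci] * b[ai] * b[ci]
        vk_life = ek2 + 2.0 * cross - 4.0

        # one cycle: mature pool and season offspring-number moments
        nx = (n1 / 2.0) * l
        mature = b_rel > 0
        pool = float(nx[mature].sum())
        b_season = np.zeros_like(b_rel)
        denom = float((nx * b_rel).sum())
        b_season[mature] = b_rel[mature] * (n1 / denom)
        kbar_cycle = n1 / pool
        w = nx[mature] / pool
        ek2_cycle = float((w * (phi * b_season[mature] + b_season[mature] ** 2)).sum())
        vk_cycle = ek2_cycle - kbar_cycle**2
        nb_sex = crow_denniston(kbar_cycle, vk_cycle, int(round(pool)))
        per_sex[sex] = {
            "T": T, "vk_life": vk_life, "nb": nb_sex, "pool": pool,
            "stable_age": nx,
        }

    T = (per_sex["F"]["T"] + per_sex["M"]["T"]) / 2.0
    vk = (per_sex["F"]["vk_life"] + per_sex["M"]["vk_life"]) / 2.0
    ne = 4.0 * n1 * T / (vk + 2.0)
    nb = combine_sexes(per_sex["F"]["nb"], per_sex["M"]["nb"])
    stable = pd.DataFrame(
        {
            "age": life_table.ages,
            "n_female": per_sex["F"]["stable_age"],
            "n_male": per_sex["M"]["stable_age"],
        }
    )
    adult_census = per_sex["F"]["pool"] + per_sex["M"]["pool"]
    return DemographicRecord(
        kbar=2.0, vk=vk, ne=ne, nb=nb, nb_ne_ratio=nb / ne,
        generation_length=T, adult_census=adult_census, stable_age=stable,
        extras={"nb_f": per_sex["F"]["nb"], "nb_m": per_sex["M"]["nb"]},
    )


# ---------------------------------------------------------------------------
# forward-time simulator (pedigree-truth demography)
# ---------------------------------------------------------------------------

def forward_expectations(
    life_table: LifeTable,
    skip: int = 0,
    cycles: int = 50,
    burn_in: int = 50,
    reps: int = 10,
    seed: Union[int, np.random.Generator] = 0,
    skip_fraction: float = 1.0,
    mating_system: str = "both-polygamous",
) -> DemographicRecord:
    """Demographic Ne/Nb from replicated forward pedigree simulations.

    Each replicate runs the age-structured simulator for ``burn_in`` +
    ``cycles`` reproductive cycles at the life table's N1. Per-cycle Nb is
    the Crow-Denniston size of that cycle's eligible parent pools (sexes
    combined); generational Ne is the Crow-Denniston size of the lifetime
    offspring-number distribution over completed cohorts, multiplied by
    the realized generation length. Reported values are harmonic means of
    Ne and Nb and arithmetic means of k-bar and Vk across replicates.
    Females breeding in a cycle skip the following ``skip`` cycles
    (applied to ``skip_fraction`` of breeders).
    """
    from . import synthdata  # local import; synthdata is this module's engine

    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "expectations.forward")
    scheme = BreedingScheme(
        mating_system=mating_system, skip_pattern=skip, skip_fraction=skip_fraction
    )
    total = burn_in + cycles
    max_age = life_table.max_age
    rows = []
    for rep in range(reps):
        ped = synthdata.simulate_pedigree(life_table, scheme, total, seed=rng)
        info = ped.cycle_info
        window = info[info["cycle"] > burn_in]
        nb_vals = window["nb_demo"].to_numpy()
        nb_rep = _harmonic(nb_vals)

        # lifetime reproductive success of completed cohorts
        last_complete = total - max_age
        k_all = ped.offspring_counts()
        complete = (ped.birth_cycle >= 1) & (ped.birth_cycle <= last_complete)
        if not complete.any():
            raise ValueError("no completed cohorts; run more cycles or shrink burn_in")
        kbar, vk = k_stats(k_all[complete])
        n1 = life_table.n1
        ne_percohort = crow_denniston(kbar, vk, n1)

        # realized generation length: mean parent age at offspring birth
        off = np.nonzero(ped.mother >= 0)[0]
        ages_m = ped.birth_cycle[off] - ped.birth_cycle[ped.mother[off]]
        ages_f = ped.birth_cycle[off] - ped.birth_cycle[ped.father[off]]
        T = float(np.concatenate([ages_m, ages_f]).mean())
        ne_rep = ne_percohort * T
        rows.append(
            {
                "replicate": rep, "kbar": kbar, "vk": vk, "T": T,
                "nb": nb_rep, "ne": ne_rep, "nb_ne_ratio": nb_rep / ne_rep,
            }
        )
    per_rep = pd.DataFrame(rows)
    nb = _harmonic(per_rep["nb"].to_numpy())
    ne = _harmonic(per_rep["ne"].to_numpy())
    return DemographicRecord(
        kbar=float(per_rep["kbar"].mean()),
        vk=float(per_rep["vk"].mean()),
        ne=ne,
        nb=nb,
        nb_ne_ratio=nb / ne,
        generation_length=float(per_rep["T"].mean()),
        adult_census=math.nan,
        per_replicate=per_rep,
        extras={"skip": skip, "skip_fraction": skip_fraction, "reps": reps},
    )


def _harmonic(vals: np.ndarray) -> float:
    vals = np.asarray(vals, dtype=float)
    if len(vals) == 0:
        return math.nan
    inv = np.where(np.isinf(vals), 0.0, 1.0 / vals)
    m = inv.mean()
    return math.inf if m == 0 else float(1.0 / m)


def demographic_ne(parents_k: Sequence[float], n: Optional[int] = None) -> float:
    """Crow-Denniston effective size from a complete offspring-count list.

    ``parents_k`` holds the (lifetime or single-cycle) offspring counts of
    all N potential parents, zeros included; ``n`` defaults to the list
    length. Applied within one cycle this yields Nb, applied to lifetime
    counts of a newborn cohort it yields the per-cohort Ne (multiply by
    the generation length for Ne per generation).
    """
    k = np.asarray(parents_k, dtype=float)
    n = len(k) if n is None else int(n)
    if n < len(k):
        raise ValueError("n cannot be smaller than the number of counts given")
    if n > len(k):  # parents with zero offspring not listed explicitly
        k = np.concatenate([k, np.zeros(n - len(k))])
    kbar, vk = k_stats(k)
    return crow_denniston(kbar, vk, n)
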