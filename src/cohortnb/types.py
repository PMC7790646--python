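"""Core data containers shared across the pipeline.

Genotypes are held as unordered, unphased allele pairs: every estimator in
this package (Burrows-composite LD, pairwise sibship likelihoods) is defined
on unphased genotype data. Missing calls are encoded explicitly as ``-1`` in
both allele slots, never as a sentinel allele, because QC missingness counts
depend on the distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleRecord",
    "NbEstimate",
    "LengthConversion",
    "VBGFParams",
    "CohortPartition",
    "LifeTable",
    "Pedigree",
    "BreedingScheme",
]


class GenotypeMatrix:
    """Individuals x loci genotype calls with per-locus metadata.

    Parameters
    ----------
    sample_ids
        Unique opaque sample identifiers, one per row.
    locus_ids
        Unique opaque locus identifiers, one per column.
    calls
        Integer array of shape ``(n_samples, n_loci, 2)`` holding allele
        indices (into ``locus_meta['alleles']``), or ``MISSING`` in both
        slots for a missing call. Allele order within a call carries no
        information.
    locus_meta
        Optional DataFrame with one row per locus. Recognised columns:
        ``alleles`` (tuple of allele labels), ``reproducibility`` (in [0,1]),
        ``depth`` (mean read depth, >= 0), ``clone_id`` (tag grouping SNPs
        from the same sequenced fragment, for one-SNP-per-locus filtering).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray,
        locus_meta: Optional[pd.DataFrame] = None,
    ):
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.locus_ids)}, 2)"
            )
        self.calls = calls
        if locus_meta is None:
            locus_meta = pd.DataFrame(index=range(len(self.locus_ids)))
        self.locus_meta = locus_meta.reset_index(drop=True)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample_ids are not unique")
        if len(self.locus_ids) != len(set(self.locus_ids)):
            raise ValueError("locus_ids are not unique")

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.locus_ids),
            self.calls.copy(),
            self.locus_meta.copy(),
        )

    # -- masks and summaries -------------------------------------------
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def dosage(self) -> np.ndarray:
        """Diallelic dosage matrix: count of allele index 1, NaN if missing."""
        d = (self.calls == 1).sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def allele_counts(self, locus: int) -> dict[int, int]:
        col = self.calls[:, locus, :].ravel()
        col = col[col != MISSING]
        vals, cnts = np.unique(col, return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def allele_freqs(self, locus: int) -> dict[int, float]:
        counts = self.allele_counts(locus)
        tot = sum(counts.values())
        if tot == 0:
            return {}
        return {a: c / tot for a, c in counts.items()}

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per locus (diallelic; NaN if no calls)."""
        d = self.dosage()
        p = np.nanmean(d, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def minor_allele_count(self) -> np.ndarray:
        """Copies of the rarer allele per locus (diallelic)."""
        d = self.dosage()
        alt = np.nansum(d, axis=0)
        called = (~np.isnan(d)).sum(axis=0)
        ref = 2.0 * called - alt
        return np.minimum(alt, ref)

    def genotype_counts(self, locus: int) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) for a diallelic locus."""
        d = self.dosage()[:, locus]
        d = d[~np.isnan(d)]
        return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())

    def is_diallelic(self) -> np.ndarray:
        out = np.zeros(self.n_loci, dtype=bool)
        for j in range(self.n_loci):
            out[j] = len(self.allele_counts(j)) <= 2
        return out

    # -- subsetting ----------------------------------------------------
    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in keep],
            list(self.locus_ids),
            self.calls[keep],
            self.locus_meta.copy(),
        )

    def subset_samples_by_id(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset_samples([index[s] for s in ids])

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in keep],
            self.calls[:, keep],
            self.locus_meta.iloc[keep].reset_index(drop=True),
        )

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_loci} loci>"


@dataclass
class SampleRecord:
    """Capture metadata for one sampled individual.

    Lengths are in centimetres; ``total_length_cm`` may be absent, in which
    case it is derived from fork length via the fitted linear conversion.
    """

    sample_id: str
    capture_year: int
    fork_length_cm: Optional[float] = None
    total_length_cm: Optional[float] = None
    sex: Optional[str] = None
    locality: Optional[str] = None

    def __post_init__(self):
        for name in ("fork_length_cm", "total_length_cm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.sample_id}: {name} must be positive, got {v}")


@dataclass
class NbEstimate:
    """A point estimate of the effective number of breeders with 95% CI.

    Negative internal estimates and unbounded intervals are represented as
    ``+inf`` (no drift signal detectable at this sample size), matching the
    reporting convention of single-sample Ne estimators.
    """

    point: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    method: str = ""
    n_samples: int = 0
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def is_finite(self) -> bool:
        return (
            math.isfinite(self.point)
            and math.isfinite(self.ci_low)
            and math.isfinite(self.ci_high)
        )


@dataclass
class LengthConversion:
    """Linear fork-length -> total-length conversion: TL = intercept + slope*FL."""

    intercept: float
    slope: float
    r_squared: float = math.nan
    n: int = 0

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError("conversion slope must be positive")


@dataclass
class VBGFParams:
    """von Bertalanffy growth parameters: L(t) = L_inf * (1 - exp(-k (t - t0)))."""

    L_inf: float
    k: float
    t0: float

    def __post_init__(self):
        if not (self.L_inf > 0 and self.k > 0):
            raise ValueError("VBGF requires L_inf > 0 and k > 0")

    def length_at_age(self, age: float) -> float:
        return self.L_inf * (1.0 - math.exp(-self.k * (age - self.t0)))


@dataclass
class CohortPartition:
    """Assignment of samples to year-of-birth cohorts."""

    birth_year: dict[str, int]
    cohorts: dict[int, list[str]]
    retained: dict[int, bool]
    min_n: int
    table: pd.DataFrame  # sample_id, FL, TL, age, birth_year, retained

    def retained_years(self) -> list[int]:
        return sorted(y for y, r in self.retained.items() if r)


class LifeTable:
    """Sex-specific survival and fecundity by age.

    Parameters
    ----------
    ages
        Integer ages (1..max_age).
    survival
        Mapping sex -> array of probabilities of surviving from age a to
        a+1 (the last entry is ignored; nobody survives past max age).
    fecundity
        Mapping sex -> array of relative fecundities b_a >= 0. Fecundities
        are relative weights; the simulators and the deterministic
        calculator rescale them so each cycle produces exactly N1 recruits.
    n1
        Recruits per cycle surviving to age 1 (both sexes pooled).
    """

    SEXES = ("F", "M")

    def __init__(self, ages, survival, fecundity, n1: int):
        self.ages = np.asarray(ages, dtype=int)
        if self.ages[0] != 1 or np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be consecutive integers starting at 1")
        self.survival = {s: np.asarray(survival[s], dtype=float) for s in self.SEXES}
        self.fecundity = {s: np.asarray(fecundity[s], dtype=float) for s in self.SEXES}
        self.n1 = int(n1)
        for s in self.SEXES:
            if len(self.survival[s]) != len(self.ages) or len(self.fecundity[s]) != len(self.ages):
                raise ValueError("survival/fecundity must have one entry per age")
            if np.any(self.survival[s] < 0) or np.any(self.survival[s] > 1):
                raise ValueError("survival probabilities must lie in [0, 1]")
            if np.any(self.fecundity[s] < 0):
                raise ValueError("fecundities must be non-negative")
        for s in self.SEXES:
            if np.all(self.fecundity[s] == 0):
                raise ValueError(f"life table has no reproducing ages for sex {s}")
        if self.n1 < 2:
            raise ValueError("n1 must be at least 2")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def survivorship(self, sex: str) -> np.ndarray:
        """l_a: probability a recruit (age 1) is alive at age a; l_1 = 1."""
        s = self.survival[sex]
        l = np.ones(len(self.ages))
        l[1:] = np.cumprod(s[:-1])
        return l

    def stable_age_numbers(self, sex: str) -> np.ndarray:
        """Expected number alive at each age under stationarity (per-sex N1/2)."""
        return (self.n1 / 2.0) * self.survivorship(sex)


@dataclass
class BreedingScheme:
    """Per-cycle mating rules for the pedigree simulator.

    ``skip_pattern`` applies to females only: a female that breeds in cycle
    t is ineligible for the following ``skip_pattern`` cycles (e.g. a
    multi-season gestation). ``skip_fraction`` is the proportion of breeding
    females subject to the skip rule.
    """

    mating_system: str = "female-monogamy"  # or "both-polygamous"
    skip_pattern: int = 0
    skip_fraction: float = 1.0
    family_size: str = "poisson"  # or "negative-binomial"
    nb_dispersion: float = 1.0  # negative-binomial overdispersion (var = mu + mu^2/r)

    def __post_init__(self):
        if self.mating_system not in ("female-monogamy", "both-polygamous"):
            raise ValueError(f"unknown mating system {self.mating_system!r}")
        if self.skip_pattern not in (0, 1, 2):
            raise ValueError("skip_pattern must be 0, 1 or 2")
        if not 0.0 <= self.skip_fraction <= 1.0:
            raise ValueError("skip_fraction must lie in [0, 1]")


class Pedigree:
    """Individuals with parent links, birth/death cycles and offspring counts.

    Ground truth for estimator-recovery tests and for demographic Ne/Nb.
    Stored columnar (numpy arrays) for speed; ``to_frame`` gives a tidy view.
    """

    def __init__(self, ids, sex, birth_cycle, mother, father, death_cycle):
        self.ids = np.asarray(ids)
        self.sex = np.asarray(sex)  # 'F'/'M'
        self.birth_cycle = np.asarray(birth_cycle, dtype=int)
        self.mother = np.asarray(mother, dtype=int)  # row index, -1 for founders
        self.father = np.asarray(father, dtype=int)
        self.death_cycle = np.asarray(death_cycle, dtype=int)
        n = len(self.ids)
        for arr in (self.sex, self.birth_cycle, self.mother, self.father, self.death_cycle):
            if len(arr) != n:
                raise ValueError("pedigree columns must have equal length")
        self._validate()

    def _validate(self):
        has_mother = self.mother >= 0
        has_father = self.father >= 0
        if np.any(has_mother != has_father):
            raise ValueError("individuals must have both parents or neither")
        if np.any(has_mother):
            m = self.mother[has_mother]
            f = self.father[has_mother]
            if np.any(self.sex[m] != "F") or np.any(self.sex[f] != "M"):
                raise ValueError("mothers must be female and fathers male")
            if np.any(self.birth_cycle[m] >= self.birth_cycle[has_mother]) or np.any(
                self.birth_cycle[f] >= self.birth_cycle[has_father]
            ):
                raise ValueError("parents must be born before their offspring")

    def __len__(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return self.mother < 0

    def offspring_counts(self) -> np.ndarray:
        """Lifetime offspring count k_i per individual."""
        k = np.zeros(len(self), dtype=int)
        for parent_col in (self.mother, self.father):
            idx, cnt = np.unique(parent_col[parent_col >= 0], return_counts=True)
            k[idx] += cnt
        return k

    def cohort_members(self, cycle: int) -> np.ndarray:
        return np.nonzero(self.birth_cycle == cycle)[0]

    def to_frame(self) -> pd.DataFrame:
        def _id(ix):
            return np.where(ix >= 0, self.ids[np.maximum(ix, 0)], None)

        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": self.sex,
                "birth_cycle": self.birth_cycle,
                "mother": _id(self.mother),
                "father": _id(self.father),
                "death_cycle": self.death_cycle,
                "k": self.offspring_counts(),
            }
        )
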