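"""Marker and individual quality control.

The cascade mirrors standard reduced-representation SNP hygiene before
single-sample Ne/Nb estimation: locus-level technical filters
(reproducibility, minor-allele count, read depth, one SNP per sequenced
fragment), individual missingness, Hardy-Weinberg exact mid-p and Fis
screens, duplicate-genotype detection, plus two multivariate screens —
a PCA-based outlier-locus scan (loci departing from the neutral covariance
structure) and a divergent-individual screen (putative migrants, which
create mixture LD that biases the LD estimator downward).

The threshold cascade is deterministic, order-logged and idempotent; the
multivariate screens are separate stages because their outcome depends on
the locus set they are given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_midp",
    "hwe_midp_multiallelic",
    "fis",
    "filter_loci",
    "filter_individuals",
    "filter_hwe_fis",
    "detect_duplicates",
    "detect_divergent_individuals",
    "outlier_scan",
    "run_qc",
]


@dataclass
class QcThresholds:
    """Thresholds of the QC cascade. All applied values are logged."""

    min_reproducibility: float = 0.98
    min_minor_allele_count: int = 3  # strict: keep MAC > 3
    depth_min: float = 5.0
    depth_max: float = 25.0
    max_individual_missing: float = 0.20  # strict: drop if missing > 0.20
    hwe_midp_min: float = 0.01
    fis_abs_max: float = 0.5  # inclusive removal at |Fis| >= 0.5
    outlier_fdr: float = 0.05
    outlier_k: int = 3
    duplicate_max_mismatch: float = 0.01
    divergent_mad_multiplier: float = 6.0


@dataclass
class QcReport:
    """Counts and per-locus statistics produced by the cascade."""

    removed_loci: dict[str, list[str]] = field(default_factory=dict)
    removed_individuals: dict[str, list[str]] = field(default_factory=dict)
    locus_stats: Optional[pd.DataFrame] = None
    log: list[str] = field(default_factory=list)

    def note(self, message: str) -> None:
        self.log.append(message)

    def n_removed_loci(self) -> int:
        return sum(len(v) for v in self.removed_loci.values())

    def merge(self, other: "QcReport") -> "QcReport":
        out = QcReport(
            dict(self.removed_loci),
            dict(self.removed_individuals),
            other.locus_stats if other.locus_stats is not None else self.locus_stats,
            self.log + other.log,
        )
        for k, v in other.removed_loci.items():
            out.removed_loci[k] = out.removed_loci.get(k, []) + v
        for k, v in other.removed_individuals.items():
            out.removed_individuals[k] = out.removed_individuals.get(k, []) + v
        return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact mid-p
# ---------------------------------------------------------------------------

def _levene_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote counts compatible with (n, n_a) and their log probabilities.

    Conditional (Levene) distribution of the heterozygote count given the
    minor-allele count n_a out of 2n alleles:
    P(h) = 2^h n! n_a! n_b! / [(2n)! ((n_a-h)/2)! h! ((n_b-h)/2)!]
    """
    n_b = 2 * n - n_a
    h_vals = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    lg = math.lgamma
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
    logp = np.array(
        [
            h * math.log(2.0)
            + const
            - lg((n_a - h) // 2 + 1)
            - lg(h + 1)
            - lg((n_b - h) // 2 + 1)
            for h in h_vals
        ]
    )
    return h_vals, logp


def hwe_midp(genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg mid-p for a diallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts; mid-p sums the probability of tables strictly less probable than
    the observed one plus half the probability of tables exactly as probable
    (the observed table included). A monomorphic locus has mid-p 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    minor = min(n_a, n_b)
    h_vals, logp = _levene_log_probs(n, minor)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.nonzero(h_vals == n_ab)[0][0]]
    tol = 1e-12 * max(obs, 1e-300)
    less = p[p < obs - tol].sum()
    equal = p[np.abs(p - obs) <= tol].sum()
    return float(less + 0.5 * equal)


def hwe_midp_multiallelic(
    calls: np.ndarray, n_permutations: int = 10_000, rng: Optional[np.random.Generator] = None
) -> float:
    """Monte-Carlo permutation HWE mid-p for a multi-allelic locus.

    ``calls`` is an (n, 2) array of allele indices (no missing rows). The
    test statistic is the conditional probability of the genotype table
    given the allele counts; alleles are permuted and re-paired.
    """
    calls = np.asarray(calls)
    if calls.ndim != 2 or calls.shape[1] != 2:
        raise ValueError("calls must be (n, 2)")
    rng = rng or np.random.default_rng()

    def log_stat(pairs: np.ndarray) -> float:
        a = np.minimum(pairs[:, 0], pairs[:, 1])
        b = np.maximum(pairs[:, 0], pairs[:, 1])
        het = int((a != b).sum())
        _, counts = np.unique(a.astype(np.int64) << 16 | b.astype(np.int64), return_counts=True)
        return het * math.log(2.0) - sum(math.lgamma(c + 1) for c in counts)

    obs = log_stat(calls)
    pool = calls.ravel().copy()
    less = equal = 0
    for _ in range(n_permutations):
        rng.shuffle(pool)
        s = log_stat(pool.reshape(-1, 2))
        if s < obs - 1e-9:
            less += 1
        elif abs(s - obs) <= 1e-9:
            equal += 1
    # observed table counts once in the equal set
    return (less + 0.5 * (equal + 1)) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Fis
# ---------------------------------------------------------------------------

def fis(matrix: GenotypeMatrix, locus: int) -> float:
    """Fis = 1 - Ho/He with Nei's unbiased expected heterozygosity.

    Positive values flag heterozygote deficit, negative values excess.
    Undefined (NaN) for monomorphic loci.
    """
    col = matrix.calls[:, locus]
    called = col[col[:, 0] >= 0]
    n = len(called)
    if n == 0:
        return math.nan
    ho = float((called[:, 0] != called[:, 1]).mean())
    freqs = np.array(list(matrix.allele_freqs(locus).values()))
    he = (1.0 - float((freqs**2).sum())) * (2 * n) / (2 * n - 1) if n > 0 else 0.0
    if he == 0.0:
        return math.nan
    return 1.0 - ho / he


# ---------------------------------------------------------------------------
# locus / individual threshold filters
# ---------------------------------------------------------------------------

def filter_loci(
    matrix: GenotypeMatrix, thresholds: Optional[QcThresholds] = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the locus-level technical filters, in a fixed logged order.

    Order: reproducibility -> minor-allele count -> mean depth -> one SNP
    per clone tag (first by file order kept) -> monomorphic removal.
    Filters whose metadata column is absent are skipped with a warning.
    """
    t = thresholds or QcThresholds()
    report = QcReport()
    keep = np.ones(matrix.n_loci, dtype=bool)
    meta = matrix.locus_meta

    def drop(mask_drop: np.ndarray, name: str, detail: str):
        mask_drop = mask_drop & keep
        ids = [matrix.locus_ids[j] for j in np.nonzero(mask_drop)[0]]
        report.removed_loci[name] = ids
        keep[mask_drop] = False
        report.note(f"filter_loci/{name}: removed {len(ids)} loci ({detail})")

    if "reproducibility" in meta.columns and meta["reproducibility"].notna().any():
        rep = meta["reproducibility"].to_numpy(float)
        drop(rep < t.min_reproducibility, "reproducibility",
             f"reproducibility < {t.min_reproducibility}")
    else:
        report.note("filter_loci/reproducibility: skipped (no metadata)")

    mac = matrix.minor_allele_count()
    drop(mac <= t.min_minor_allele_count, "minor_allele_count",
         f"minor-allele count <= {t.min_minor_allele_count}")

    if "depth" in meta.columns and meta["depth"].notna().any():
        depth = meta["depth"].to_numpy(float)
        drop((depth < t.depth_min) | (depth > t.depth_max), "depth",
             f"mean depth outside [{t.depth_min}, {t.depth_max}]")
    else:
        report.note("filter_loci/depth: skipped (no metadata)")

    if "clone_id" in meta.columns and meta["clone_id"].notna().any():
        seen: set = set()
        dup = np.zeros(matrix.n_loci, dtype=bool)
        for j in np.nonzero(keep)[0]:
            tag = meta["clone_id"].iloc[j]
            if pd.isna(tag):
                continue
            if tag in seen:
                dup[j] = True
            seen.add(tag)
        drop(dup, "one_snp_per_clone", "secondary SNPs on the same clone tag")
    else:
        report.note("filter_loci/one_snp_per_clone: skipped (no metadata)")

    drop(mac == 0, "monomorphic", "no minor allele observed")

    if not keep.any():
        raise ValueError("no loci survive the locus filters")
    return matrix.subset_loci(np.nonzero(keep)[0]), report


def filter_individuals(
    matrix: GenotypeMatrix, thresholds: Optional[QcThresholds] = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop individuals missing strictly more than the allowed locus fraction."""
    t = thresholds or QcThresholds()
    report = QcReport()
    frac = matrix.sample_missing_fraction()
    bad = frac > t.max_individual_missing
    ids = [matrix.sample_ids[i] for i in np.nonzero(bad)[0]]
    report.removed_individuals["missingness"] = ids
    report.note(
        f"filter_individuals: removed {len(ids)} individuals "
        f"(missing fraction > {t.max_individual_missing})"
    )
    return matrix.subset_samples(np.nonzero(~bad)[0]), report


def filter_hwe_fis(
    matrix: GenotypeMatrix, thresholds: Optional[QcThresholds] = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove loci failing the HWE exact mid-p or |Fis| screens (global)."""
    t = thresholds or QcThresholds()
    report = QcReport()
    midp = np.ones(matrix.n_loci)
    fis_vals = np.full(matrix.n_loci, np.nan)
    for j in range(matrix.n_loci):
        midp[j] = hwe_midp(matrix.genotype_counts(j))
        fis_vals[j] = fis(matrix, j)
    hwe_bad = midp < t.hwe_midp_min
    fis_bad = np.abs(fis_vals) >= t.fis_abs_max
    fis_bad &= ~np.isnan(fis_vals)
    fis_bad &= ~hwe_bad
    report.removed_loci["hwe_midp"] = [matrix.locus_ids[j] for j in np.nonzero(hwe_bad)[0]]
    report.removed_loci["fis"] = [matrix.locus_ids[j] for j in np.nonzero(fis_bad)[0]]
    report.note(f"filter_hwe_fis: removed {int(hwe_bad.sum())} loci (HWE mid-p < {t.hwe_midp_min})")
    report.note(f"filter_hwe_fis: removed {int(fis_bad.sum())} loci (|Fis| >= {t.fis_abs_max})")
    d = matrix.dosage()
    p = np.nanmean(d, axis=0) / 2.0
    ho = np.nanmean(d == 1, axis=0)
    report.locus_stats = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "maf": np.minimum(p, 1 - p),
            "ho": ho,
            "hwe_midp": midp,
            "fis": fis_vals,
        }
    )
    keep = ~(hwe_bad | fis_bad)
    if not keep.any():
        raise ValueError("no loci survive the HWE/Fis filters")
    return matrix.subset_loci(np.nonzero(keep)[0]), report


# ---------------------------------------------------------------------------
# duplicates, migrants, outlier loci
# ---------------------------------------------------------------------------

def detect_duplicates(
    matrix: GenotypeMatrix, max_mismatch_fraction: float = 0.01
) -> list[tuple[str, str, float]]:
    """Pairs of samples whose genotype mismatch rate over co-called loci is
    at or below the threshold; the second member of each pair is the
    conventional removal candidate."""
    code = np.where(
        matrix.calls[:, :, 0] < 0,
        -1,
        np.min(matrix.calls, axis=2).astype(np.int32) * 1024 + np.max(matrix.calls, axis=2),
    )
    n = matrix.n_samples
    pairs = []
    for i in range(n - 1):
        ci = code[i]
        both = (ci >= 0) & (code[i + 1 :] >= 0)
        mism = (ci != code[i + 1 :]) & both
        n_both = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            rate = np.where(n_both > 0, mism.sum(axis=1) / np.maximum(n_both, 1), np.nan)
        for off in np.nonzero((n_both > 0) & (rate <= max_mismatch_fraction))[0]:
            j = i + 1 + off
            pairs.append((matrix.sample_ids[i], matrix.sample_ids[j], float(rate[off])))
    return pairs


def _imputed_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Dosage with missing entries imputed by the per-locus mean."""
    d = matrix.dosage()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    return d


def _pc_scores(matrix: GenotypeMatrix, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left singular vectors (individual scores), singular values and the
    standardized dosage matrix."""
    d = _imputed_dosage(matrix)
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    z = d / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :k], s[:k], z


def detect_divergent_individuals(
    matrix: GenotypeMatrix,
    expected_groups: Optional[dict[str, Sequence[str]]] = None,
    n_axes: Optional[int] = None,
    mad_multiplier: float = 6.0,
) -> list[str]:
    """Flag putative migrants by centroid distance in PC space.

    Individuals whose distance from their group's (median) centroid
    exceeds the group median distance by more than ``mad_multiplier``
    median absolute deviations are flagged. By default the distance uses
    all principal axes weighted by their singular values - equivalently,
    distance in standardized genotype space - which makes an individual
    from a diverged source population stand far out while a duplicated
    sample (identical to a typical genotype) does not. Pass ``n_axes`` to
    restrict to the leading axes. With no declared groups, all samples
    form one group.
    """
    if matrix.n_samples < 10:
        raise ValueError("divergent-individual screen needs at least 10 samples")
    if n_axes is None:
        d = _imputed_dosage(matrix)
        d = d - d.mean(axis=0)
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        scores = d / sd
    else:
        u, s, _ = _pc_scores(matrix, min(n_axes, matrix.n_samples - 1))
        scores = u * s  # data-space distances on the leading axes
    groups = expected_groups or {"all": list(matrix.sample_ids)}
    index = {s: i for i, s in enumerate(matrix.sample_ids)}
    flagged = []
    for members in groups.values():
        rows = np.array([index[s] for s in members])
        pts = scores[rows]
        dist = np.linalg.norm(pts - np.median(pts, axis=0), axis=1)
        med = np.median(dist)
        mad = np.median(np.abs(dist - med))
        if mad == 0:
            continue
        for r, d_i in zip(rows, dist):
            if (d_i - med) / mad > mad_multiplier:
                flagged.append(matrix.sample_ids[r])
    return flagged


def outlier_scan(
    matrix: GenotypeMatrix, k: int = 3, fdr: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """PCA-based outlier-locus scan (loci departing from neutral structure).

    Each locus's standardized dosages are regressed on the first ``k``
    principal components; the k z-scores are combined into a Mahalanobis
    distance, corrected by the genomic inflation factor (median distance
    over the chi-square(k) median), converted to chi-square(k) p-values and
    screened at Benjamini-Hochberg q-value < ``fdr``.

    Returns (flagged locus ids, per-locus statistics).
    """
    n = matrix.n_samples
    if n < k + 2:
        raise ValueError(f"outlier scan with k={k} needs at least {k + 2} individuals")
    u, _, z = _pc_scores(matrix, k)
    # regressors are orthonormal, so beta = U^T g and var(beta) = sigma^2
    beta = u.T @ z  # (k, L)
    resid = z - u @ beta
    dof = max(n - k, 1)
    sigma = np.sqrt((resid**2).sum(axis=0) / dof)
    sigma[sigma == 0] = np.nan
    zscores = beta / sigma  # (k, L)
    finite = np.all(np.isfinite(zscores), axis=0)
    cov = np.cov(zscores[:, finite])
    cov = np.atleast_2d(cov)
    inv = np.linalg.pinv(cov)
    center = np.mean(zscores[:, finite], axis=1)
    dz = zscores - center[:, None]
    d2 = np.einsum("kl,km,ml->l", dz, inv, dz)
    lam = np.nanmedian(d2) / stats.chi2.median(df=k)
    pvals = stats.chi2.sf(d2 / lam, df=k)
    qvals = _bh_qvalues(pvals)
    stats_df = pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "mahalanobis_d2": d2,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    flagged = [matrix.locus_ids[j] for j in np.nonzero(qvals < fdr)[0]]
    return flagged, stats_df


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = ok.sum()
    if m == 0:
        return out
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    tmp = np.empty(m)
    tmp[order] = np.minimum(q, 1.0)
    out[ok] = tmp
    return out


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_qc(
    matrix: GenotypeMatrix,
    thresholds: Optional[QcThresholds] = None,
    remove_duplicates: bool = True,
    scan_outliers: bool = False,
    screen_divergent: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the deterministic QC cascade and optional multivariate screens.

    Cascade order (logged): locus technical filters -> individual
    missingness -> HWE/Fis -> duplicate removal. The optional outlier-locus
    scan and divergent-individual screen run last because their statistics
    depend on the surviving locus/sample set.
    """
    t = thresholds or QcThresholds()
    m, report = filter_loci(matrix, t)
    m, rep2 = filter_individuals(m, t)
    report = report.merge(rep2)
    m, rep3 = filter_hwe_fis(m, t)
    report = report.merge(rep3)
    if remove_duplicates:
        pairs = detect_duplicates(m, t.duplicate_max_mismatch)
        drop_ids = sorted({b for _, b, _ in pairs})
        if drop_ids:
            keep = [i for i, s in enumerate(m.sample_ids) if s not in set(drop_ids)]
            m = m.subset_samples(keep)
        report.removed_individuals["duplicates"] = drop_ids
        report.note(f"duplicates: removed {len(drop_ids)} individuals "
                    f"(mismatch rate <= {t.duplicate_max_mismatch})")
    if screen_divergent:
        flagged = detect_divergent_individuals(m, mad_multiplier=t.divergent_mad_multiplier)
        if flagged:
            keep = [i for i, s in enumerate(m.sample_ids) if s not in set(flagged)]
            m = m.subset_samples(keep)
        report.removed_individuals["divergent"] = flagged
        report.note(f"divergent individuals: removed {len(flagged)} "
                    f"(centroid distance > {t.divergent_mad_multiplier} MADs)")
    if scan_outliers:
        flagged, _ = outlier_scan(m, k=t.outlier_k, fdr=t.outlier_fdr)
        if flagged:
            keep = [j for j, l in enumerate(m.locus_ids) if l not in set(flagged)]
            m = m.subset_loci(keep)
        report.removed_loci["outlier_scan"] = flagged
        report.note(f"outlier scan: removed {len(flagged)} loci "
                    f"(q < {t.outlier_fdr}, k = {t.outlier_k})")
    return m, report
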