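"""Linkage-disequilibrium (single-sample) Nb estimation.

In a finite parental pool, drift generates association between alleles at
physically unlinked loci. The estimator averages the squared composite
(Burrows) correlation r^2 across all locus pairs in one cohort, subtracts
the expected contribution of sampling S individuals, and inverts the
drift relationship E[r^2_drift] ~ 1/(3Nb) (with the second-order
correction of the reference methods literature) to obtain the effective
number of breeders of that cohort's parents.

The composite r for a pair of diallelic loci is Burrows' Delta with the
homozygosity (Weir) correction in the denominator and an n/(n-1)
small-sample factor on Delta; algebraically this equals n/(n-1) times the
maximum-likelihood Pearson correlation of the two dosage vectors over
individuals called at both loci, which is how the all-pairs computation is
vectorised. Alleles rarer than Pcrit are excluded because rare alleles
bias r^2 upward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import GenotypeMatrix, NbEstimate

__all__ = [
    "LdSummary",
    "pair_r2",
    "mean_r2",
    "nb_from_r2",
    "jackknife_ci",
    "estimate_nb_ld",
]

MIN_PAIR_N = 5  # pairs with fewer complete individuals are skipped


@dataclass
class LdSummary:
    """Weighted mean composite r^2 and the effective sample size S."""

    mean_r2: float
    S: float  # harmonic mean of per-pair complete sample sizes
    n_pairs: int
    n_loci_used: int
    pcrit: float


# ---------------------------------------------------------------------------
# single pair (reference implementation, used directly and as a test oracle)
# ---------------------------------------------------------------------------

def pair_r2(
    locus_a: int,
    locus_b: int,
    matrix: GenotypeMatrix,
    small_sample_correction: bool = True,
    min_n: int = MIN_PAIR_N,
) -> tuple[float, int]:
    """Composite r^2 between two diallelic loci from unphased genotypes.

    Computed explicitly from Burrows' Delta over individuals with complete
    calls at both loci:

        Delta = [n/(n-1)] (sum(X Y)/(2 n) - 2 pA pB)
        r = Delta / sqrt((pA qA + DA)(pB qB + DB))

    with X, Y allele-1 dosages, pA, pB allele-1 frequencies and
    DA = hom1_freq - pA^2 the departure-from-HWE correction. Returns
    (r^2, n_complete).
    """
    d = matrix.dosage()
    x, y = d[:, locus_a], d[:, locus_b]
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_n:
        raise ValueError(f"only {n} complete individuals at pair ({locus_a}, {locus_b})")
    x, y = x[ok], y[ok]
    pa, pb = x.mean() / 2.0, y.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("locus monomorphic among complete calls")
    delta = (x * y).sum() / (2.0 * n) - 2.0 * pa * pb
    if small_sample_correction:
        delta *= n / (n - 1.0)
    da = (x == 2).mean() - pa**2
    db = (y == 2).mean() - pb**2
    denom = (pa * (1 - pa) + da) * (pb * (1 - pb) + db)
    r = delta / math.sqrt(denom)
    return float(r * r), n


# ---------------------------------------------------------------------------
# all pairs, vectorised through per-pair sufficient statistics
# ---------------------------------------------------------------------------

def _pair_sufficient_stats(d: np.ndarray):
    """Per-pair complete-case sums as (L, L) matrices (float32).

    For loci a, b over individuals called at both: counts N, sums Sx, Sy,
    squares Sxx, Syy and cross products Sxy.
    """
    m = (~np.isnan(d)).astype(np.float32)
    df = np.nan_to_num(d).astype(np.float32)
    d2 = df * df
    N = m.T @ m
    Sx = df.T @ m
    Sxx = d2.T @ m
    Sxy = df.T @ df
    return N, Sx, Sxx, Sxy


def _r2_from_stats(N, Sx, Sxx, Sxy, min_n: int = MIN_PAIR_N):
    """(r^2, valid-pair mask) from sufficient-stat matrices; upper triangle."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = Sx / N
        cov = Sxy / N - mean_x * mean_x.T
        var_x = Sxx / N - mean_x**2
        denom = var_x * var_x.T
        corr = np.where(denom > 0, cov / np.sqrt(np.where(denom > 0, denom, 1.0)), np.nan)
        corr *= N / (N - 1.0)
        r2 = corr * corr
    L = N.shape[0]
    valid = np.triu(np.ones((L, L), bool), k=1)
    valid &= N >= min_n
    valid &= np.isfinite(r2)
    return r2, valid


def _screen_loci(matrix: GenotypeMatrix, pcrit: float) -> np.ndarray:
    maf = matrix.maf()
    keep = np.nonzero(np.nan_to_num(maf) >= pcrit)[0]
    return keep


def mean_r2(matrix: GenotypeMatrix, pcrit: float = 0.05) -> LdSummary:
    """Weighted mean composite r^2 across all eligible locus pairs.

    Loci with minor-allele frequency below ``pcrit`` are excluded; pairs
    are weighted by their complete-case sample size, and S is the harmonic
    mean of per-pair sample sizes.
    """
    keep = _screen_loci(matrix, pcrit)
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 loci pass Pcrit={pcrit}; cannot form locus pairs"
        )
    d = matrix.dosage()[:, keep]
    N, Sx, Sxx, Sxy = _pair_sufficient_stats(d)
    r2, valid = _r2_from_stats(N, Sx, Sxx, Sxy)
    if not valid.any():
        raise ValueError("no valid locus pairs (all below the complete-case minimum)")
    w = N[valid]
    vals = r2[valid]
    mean = float((w * vals).sum() / w.sum())
    S = float(len(w) / (1.0 / w).sum())
    return LdSummary(mean_r2=mean, S=S, n_pairs=int(valid.sum()),
                     n_loci_used=len(keep), pcrit=pcrit)


# ---------------------------------------------------------------------------
# r^2 -> Nb
# ---------------------------------------------------------------------------

def expected_sample_r2(S: float) -> float:
    """Expected r^2 from sampling S individuals with no drift signal
    (random mating; reference-implementation regression constants)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _invert_drift_r2(r2_drift: float, S: float) -> float:
    """Solve the quadratic drift relationship for Nb (random mating).

    A drift signal larger than the relationship can produce for any N
    (negative discriminant) collapses to the small-N boundary solution
    rather than infinity: a huge r^2 means a tiny parental pool.
    """
    if r2_drift <= 0:
        return math.inf
    a = 1.0 / 3.0 if S >= 30 else 0.308
    b = 2.76 if S >= 30 else 2.08
    disc = a * a - b * r2_drift
    ne = (a + math.sqrt(max(disc, 0.0))) / (2.0 * r2_drift)
    return ne if ne > 0 else math.inf


def nb_from_r2(summary: LdSummary, corrected: bool = True) -> NbEstimate:
    """Point estimate of Nb from an LD summary.

    With ``corrected`` (default) the expected sampling contribution to r^2
    is subtracted and the quadratic drift relationship inverted; otherwise
    the first-order relation Nb = 1/(3 (r^2 - 1/S)) is used. A
    non-positive drift signal maps to +inf: the data cannot distinguish
    the parental pool from an infinite one.
    """
    S = summary.S
    if corrected:
        r2_drift = summary.mean_r2 - expected_sample_r2(S)
        point = _invert_drift_r2(r2_drift, S)
    else:
        r2_drift = summary.mean_r2 - 1.0 / S
        point = 1.0 / (3.0 * r2_drift) if r2_drift > 0 else math.inf
        if point <= 0:
            point = math.inf
    return NbEstimate(
        point=float(point),
        method="LD",
        n_samples=int(round(S)),
        diagnostics={
            "mean_r2": summary.mean_r2,
            "S": S,
            "n_pairs": summary.n_pairs,
            "n_loci_used": summary.n_loci_used,
            "pcrit": summary.pcrit,
            "r2_drift": r2_drift,
        },
    )


# ---------------------------------------------------------------------------
# jackknife CI
# ---------------------------------------------------------------------------

def jackknife_ci(
    matrix: GenotypeMatrix,
    pcrit: float = 0.05,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Delete-one-individual jackknife CI for the LD estimate.

    Individuals (not locus pairs) are deleted one at a time, which
    accounts for the pseudo-replication created by the overlapping locus
    pairs sharing individuals. Jackknife variance is computed on the 1/Nb
    scale (where the estimator is approximately normal) and the interval
    back-transformed; non-positive bounds map to +inf. The locus screen
    (Pcrit) is fixed from the full sample.
    """
    n = matrix.n_samples
    if n < 10:
        raise ValueError("jackknife CI requires a cohort of at least 10 individuals")
    keep = _screen_loci(matrix, pcrit)
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 loci pass Pcrit={pcrit}")
    d = matrix.dosage()[:, keep]
    complete = not np.isnan(d).any()

    if complete:
        x_hat, x_del = _jackknife_complete(d, pcrit)
    else:
        x_hat, x_del = _jackknife_missing(d, pcrit)
    full_point = math.inf if x_hat == 0 else 1.0 / x_hat

    var_jack = (n - 1.0) / n * float(((x_del - x_del.mean()) ** 2).sum())
    se = math.sqrt(var_jack)
    if se == 0.0:
        warnings.warn("degenerate jackknife: all leave-one-out estimates identical")
        return full_point, full_point
    from scipy import stats as _st

    z = _st.norm.ppf(0.5 + confidence / 2.0)
    lo_x, hi_x = x_hat - z * se, x_hat + z * se
    ci_high = math.inf if lo_x <= 0 else 1.0 / lo_x
    ci_low = math.inf if hi_x <= 0 else 1.0 / hi_x
    return float(ci_low), float(ci_high)


def _nb_inverse_from_mean(mean: float, S: float) -> float:
    """1/Nb (0 when infinite or degenerate) from a mean r^2 at sample size S."""
    if math.isnan(mean):
        return 0.0
    point = _invert_drift_r2(mean - expected_sample_r2(S), S)
    return 0.0 if math.isinf(point) else 1.0 / point


def _jackknife_complete(d: np.ndarray, pcrit: float) -> tuple[float, np.ndarray]:
    """Leave-one-out 1/Nb values for a matrix with no missing calls.

    With complete data every pair shares the same sample size, so only the
    L x L cross-product matrix needs downdating per deletion; r^2 means are
    taken over the off-diagonal of the (symmetric) r^2 matrix.
    """
    n, L = d.shape
    df = d.astype(np.float32)
    s = df.sum(axis=0, dtype=np.float64).astype(np.float32)
    sq = (df * df).sum(axis=0, dtype=np.float64).astype(np.float32)
    G = df.T @ df

    def loo_stat(s_v, sq_v, G_m, m):
        mu = s_v / m
        var = sq_v / m - mu * mu
        pos = var > 0
        cov = G_m / m - np.outer(mu, mu)
        sd = np.sqrt(np.where(pos, var, 1.0))
        corr = cov / np.outer(sd, sd)
        corr *= m / (m - 1.0)
        r2 = corr * corr
        if not pos.all():
            r2[~pos, :] = 0.0
            r2[:, ~pos] = 0.0
        n_loci = int(pos.sum())
        n_pairs = n_loci * (n_loci - 1) // 2
        if n_pairs == 0:
            return math.nan, float(m)  # fully degenerate replicate
        total = (float(r2.sum(dtype=np.float64)) - float(np.trace(r2))) / 2.0
        return total / n_pairs, float(m)

    mean_full, S_full = loo_stat(s, sq, G, n)
    x_hat = _nb_inverse_from_mean(mean_full, S_full)
    x_del = np.empty(n)
    for i in range(n):
        di = df[i]
        mean_i, S_i = loo_stat(s - di, sq - di * di, G - np.outer(di, di), n - 1)
        x_del[i] = _nb_inverse_from_mean(mean_i, S_i)
    return x_hat, x_del


def _jackknife_missing(d: np.ndarray, pcrit: float) -> tuple[float, np.ndarray]:
    """Leave-one-out 1/Nb values with per-pair complete-case downdating."""
    n, L = d.shape
    m = (~np.isnan(d)).astype(np.float32)
    df = np.nan_to_num(d).astype(np.float32)
    N, Sx, Sxx, Sxy = _pair_sufficient_stats(d)
    summ = _summary_from_stats(N, Sx, Sxx, Sxy, L, pcrit)
    full = nb_from_r2(summ)
    x_hat = 0.0 if math.isinf(full.point) else 1.0 / full.point
    x_del = np.empty(n)
    for i in range(n):
        mi, di = m[i], df[i]
        Ni = N - np.outer(mi, mi)
        Sxi = Sx - np.outer(di, mi)
        Sxxi = Sxx - np.outer(di * di, mi)
        Sxyi = Sxy - np.outer(di, di)
        est = nb_from_r2(_summary_from_stats(Ni, Sxi, Sxxi, Sxyi, L, pcrit))
        x_del[i] = 0.0 if math.isinf(est.point) else 1.0 / est.point
    return x_hat, x_del


def _summary_from_stats(N, Sx, Sxx, Sxy, n_loci, pcrit) -> LdSummary:
    r2, valid = _r2_from_stats(N, Sx, Sxx, Sxy)
    if not valid.any():
        raise ValueError("no valid locus pairs")
    w = N[valid]
    vals = r2[valid]
    return LdSummary(
        mean_r2=float((w * vals).sum() / w.sum()),
        S=float(len(w) / (1.0 / w).sum()),
        n_pairs=int(valid.sum()),
        n_loci_used=n_loci,
        pcrit=pcrit,
    )


def estimate_nb_ld(
    matrix: GenotypeMatrix,
    pcrit: float = 0.05,
    confidence: float = 0.95,
    jackknife: bool = True,
) -> NbEstimate:
    """Full LD pipeline for one cohort: mean r^2, point estimate, CI."""
    summary = mean_r2(matrix, pcrit)
    est = nb_from_r2(summary)
    if jackknife and matrix.n_samples >= 10:
        est.ci_low, est.ci_high = jackknife_ci(matrix, pcrit, confidence)
    else:
        est.ci_low, est.ci_high = math.nan, math.nan
    return est
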