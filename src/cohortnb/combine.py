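"""Combining the LD and sibship Nb estimates and Nb/Na ratios.

Per cohort, the two single-sample estimates are merged into a single
inverse-variance-weighted harmonic mean: variances are recovered from the
reported 95% CIs by treating ln(Nb) as approximately normal, weights are
proportional to 1/var, and the combination is performed on the 1/Nb scale
(where both estimators are approximately unbiased). A cohort with any
infinite bound yields no combined estimate rather than a truncated one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .types import NbEstimate

__all__ = [
    "CombinedEstimate",
    "RatioResult",
    "variance_from_ci",
    "combine_estimates",
    "weighted_harmonic_mean",
    "nb_na_ratio",
    "stability_check",
]

Z95 = 1.959963984540054


@dataclass
class CombinedEstimate:
    value: float
    sd: float
    weights: tuple[float, float]  # (w_LD, w_SA)
    inputs: tuple[NbEstimate, NbEstimate]


@dataclass
class RatioResult:
    ratio: float
    interval: tuple[float, float]
    na_point: float
    na_range: tuple[float, float]


class InfiniteBoundError(ValueError):
    """An input estimate has an infinite point or CI bound; per the
    reporting convention no combined estimate is produced."""


def variance_from_ci(est: NbEstimate, scale: str = "log") -> float:
    """Recover an approximate sampling variance of the point estimate from
    its 95% CI.

    ``log`` (default): ln(Nb) ~ normal, sd_ln = (ln hi - ln lo)/(2 z),
    var(Nb) = Nb^2 sd_ln^2 by the delta method. ``inverse``: 1/Nb ~ normal,
    sd_inv = (1/lo - 1/hi)/(2 z), var(Nb) = Nb^4 sd_inv^2.
    """
    if not est.is_finite:
        raise InfiniteBoundError(f"{est.method}: infinite point or CI bound")
    if not 0 < est.ci_low <= est.ci_high:
        raise ValueError("CI bounds must be positive and ordered")
    if scale == "log":
        sd_ln = (math.log(est.ci_high) - math.log(est.ci_low)) / (2 * Z95)
        return est.point**2 * sd_ln**2
    if scale == "inverse":
        sd_inv = (1.0 / est.ci_low - 1.0 / est.ci_high) / (2 * Z95)
        return est.point**4 * sd_inv**2
    raise ValueError("scale must be 'log' or 'inverse'")


def weighted_harmonic_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """1 / (sum w_i / v_i) with weights normalised to sum to 1."""
    tot = sum(weights)
    return 1.0 / sum(w / tot / v for v, w in zip(values, weights))


def combine_estimates(
    ld: NbEstimate, sa: NbEstimate, variance_scale: str = "log"
) -> CombinedEstimate:
    """Inverse-variance-weighted harmonic-mean combination of the two
    estimates.

    Refuses (raises :class:`InfiniteBoundError`) when either input has an
    infinite point or bound. The combined sd is propagated by the delta
    method on the 1/Nb scale.
    """
    var_ld = variance_from_ci(ld, variance_scale)
    var_sa = variance_from_ci(sa, variance_scale)
    w_ld = (1.0 / var_ld) / (1.0 / var_ld + 1.0 / var_sa)
    w_sa = 1.0 - w_ld
    value = weighted_harmonic_mean((ld.point, sa.point), (w_ld, w_sa))
    # var(1/N_i) by the delta method, combined on the inverse scale
    var_inv = (
        w_ld**2 * var_ld / ld.point**4 + w_sa**2 * var_sa / sa.point**4
    )
    sd = value**2 * math.sqrt(var_inv)
    return CombinedEstimate(value=value, sd=sd, weights=(w_ld, w_sa), inputs=(ld, sa))


def nb_na_ratio(
    combined: float, na_point: float, na_low: float, na_high: float
) -> RatioResult:
    """Nb/Na ratio with an interval from the Na uncertainty range."""
    if not (0 < na_low <= na_point <= na_high):
        raise ValueError("require 0 < na_low <= na_point <= na_high")
    if not math.isfinite(combined):
        raise ValueError("combined estimate must be finite")
    return RatioResult(
        ratio=combined / na_point,
        interval=(combined / na_high, combined / na_low),
        na_point=na_point,
        na_range=(na_low, na_high),
    )


def stability_check(estimates_by_cohort: dict[int, NbEstimate]) -> dict:
    """Pairwise CI-overlap matrix across cohorts.

    A heuristic screen, not a hypothesis test: the across-cohort series is
    called "stable" iff every pair of cohort CIs overlaps. Infinite upper
    bounds overlap anything above their lower bound.
    """
    years = sorted(estimates_by_cohort)
    if len(years) < 2:
        raise ValueError("need at least 2 cohorts")
    overlap = {}
    stable = True
    for i, y1 in enumerate(years):
        for y2 in years[i + 1 :]:
            a, b = estimates_by_cohort[y1], estimates_by_cohort[y2]
            ok = a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
            overlap[(y1, y2)] = bool(ok)
            stable &= ok
    return {"overlap": overlap, "stable": bool(stable), "heuristic": True}
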