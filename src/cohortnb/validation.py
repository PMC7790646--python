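"""End-to-end validation experiments against synthetic truth.

These are the package's standard recovery benchmarks: they generate
populations with known effective sizes from :mod:`cohortnb.synthdata`, run
the full estimation pipelines, and report how well truth is recovered.
They are used by the test suite and the reproduction script; the sizes
below (replicate counts, locus counts, sample sizes) are the package's
reference validation conditions.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import expectations, ld, sibship, synthdata
from .rng import stream

__all__ = [
    "ld_recovery",
    "sa_recovery",
    "expectation_cross_check",
    "skip_ratio_curve",
]


def ld_recovery(
    ne_true: int = 200,
    n_loci: int = 3000,
    n_samples: int = 50,
    n_reps: int = 20,
    pcrit: float = 0.05,
    seed: int = 0,
    jackknife: bool = True,
) -> dict:
    """LD-method parameter recovery on ideal Wright-Fisher cohorts.

    Returns per-replicate point estimates and CIs, their median, and the
    fraction of 95% jackknife intervals covering the true Ne.
    """
    rng = stream(seed, "validation.ld")
    points, cis = [], []
    for _ in range(n_reps):
        m = synthdata.make_ideal_wf_population(ne_true, n_loci, n_samples, seed=rng)
        est = ld.estimate_nb_ld(m, pcrit=pcrit, jackknife=jackknife)
        points.append(est.point)
        cis.append((est.ci_low, est.ci_high))
    points_arr = np.array(points)
    out = {
        "ne_true": ne_true,
        "points": points,
        "median": float(np.median(points_arr)),
        "cis": cis,
    }
    if jackknife:
        cover = [lo <= ne_true <= hi for lo, hi in cis]
        out["coverage"] = float(np.mean(cover))
    return out


def sa_recovery(
    nb_true: int = 50,
    n_loci: int = 3000,
    n_samples: int = 50,
    n_offspring: int = 1000,
    n_reps: int = 10,
    seed: int = 0,
) -> dict:
    """Sibship-method recovery on cohorts bred by a known parent pool.

    Truth is the realized demographic Nb of the pool (close to ``nb_true``
    under the ideal bijective-monogamy design). Also reports pooled
    full-sib pair recall of the pairwise classifier against the pedigree.
    """
    rng = stream(seed, "validation.sa")
    points, truths = [], []
    tp = fn = 0
    for _ in range(n_reps):
        m, _, truth = synthdata.sample_cohort_from_parent_pool(
            nb_true, n_offspring, n_samples, n_loci, seed=rng
        )
        calls = sibship.classify_pairs(m)
        summary = sibship.build_sibgroups(calls, sample_ids=m.sample_ids)
        points.append(sibship.nb_from_sibship(summary).point)
        truths.append(truth["nb_demo"])
        mom, dad = truth["mother_of"], truth["father_of"]
        for c in calls:
            a, b = c.pair
            if mom[a] == mom[b] and dad[a] == dad[b]:
                tp += c.best == "full-sib"
                fn += c.best != "full-sib"
    ratios = np.array(points) / np.array(truths)
    return {
        "nb_true": nb_true,
        "points": points,
        "truths": truths,
        "median": float(np.median(points)),
        "median_ratio": float(np.median(ratios)),
        "fullsib_recall": tp / (tp + fn) if tp + fn else math.nan,
        "n_true_fullsib_pairs": tp + fn,
    }


def expectation_cross_check(
    seed: int = 0,
    reps: int = 10,
    cycles: int = 50,
    burn_in: int = 50,
    life_table=None,
) -> dict:
    """Deterministic calculator vs no-skip forward simulation.

    With no skip breeding the two routes model the same process; their
    relative discrepancy on Ne and Nb measures the fidelity of both.
    """
    lt = life_table or synthdata.white_shark_life_table()
    det = expectations.agene(lt)
    fwd = expectations.forward_expectations(
        lt, skip=0, cycles=cycles, burn_in=burn_in, reps=reps, seed=seed
    )
    return {
        "agene_nb": det.nb,
        "agene_ne": det.ne,
        "agene_ratio": det.nb_ne_ratio,
        "forward_nb": fwd.nb,
        "forward_ne": fwd.ne,
        "forward_ratio": fwd.nb_ne_ratio,
        "nb_rel_diff": abs(fwd.nb - det.nb) / det.nb,
        "ne_rel_diff": abs(fwd.ne - det.ne) / det.ne,
    }


def skip_ratio_curve(
    seed: int = 0,
    reps: int = 10,
    cycles: int = 50,
    burn_in: int = 50,
    life_table=None,
) -> dict:
    """Nb/Ne ratio under female skip-breeding scenarios (0, 1, 2 cycles)."""
    lt = life_table or synthdata.white_shark_life_table()
    out = {}
    for skip in (0, 1, 2):
        fwd = expectations.forward_expectations(
            lt, skip=skip, cycles=cycles, burn_in=burn_in, reps=reps, seed=seed
        )
        out[skip] = {"nb": fwd.nb, "ne": fwd.ne, "ratio": fwd.nb_ne_ratio}
    return out
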