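"""Shared demographic-Ne primitives (Crow-Denniston discrete form)."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["crow_denniston", "combine_sexes"]


def crow_denniston(kbar: float, vk: float, n: int) -> float:
    """Effective size from mean and variance of offspring number.

    Ne = (k_bar * N - 2) / (k_bar - 1 + Vk / k_bar), the discrete-time
    inbreeding effective size of N potential parents with offspring-number
    mean k_bar and variance Vk. Returns +inf when the denominator is not
    positive (less-than-binomial variance at small k_bar).
    """
    if n <= 0:
        raise ValueError("need at least one potential parent")
    if kbar <= 0:
        raise ValueError("mean offspring number must be positive")
    denom = kbar - 1.0 + vk / kbar
    num = kbar * n - 2.0
    if denom <= 0 or num <= 0:
        return math.inf
    return num / denom


def combine_sexes(ne_f: float, ne_m: float) -> float:
    """Wright's two-sex combination: Ne = 4 Nf Nm / (Nf + Nm)."""
    if not (np.isfinite(ne_f) and np.isfinite(ne_m)):
        return math.inf
    return 4.0 * ne_f * ne_m / (ne_f + ne_m)


def k_stats(k: np.ndarray) -> tuple[float, float]:
    """Mean and (population) variance of an offspring-count vector."""
    k = np.asarray(k, dtype=float)
    return float(k.mean()), float(k.var())
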