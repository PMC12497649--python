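"""Poisson models for AAV multiplicity of infection and dPCR quantification.

With k equimolar co-injected constructs at total mean MOI lambda, each
construct infects a cell an independent Poisson(lambda/k) number of times
(cells treated as exchangeable; regional tropism differences are out of
scope). The fraction of transduced cells expressing exactly m construct
types is then binomial in the per-construct presence probability
1 - exp(-lambda/k), conditioned on at least one type being present.
Episome molecule counts from digital PCR get exact (Garwood) Poisson
confidence intervals, and the count of Cre-inverted episomes divided by an
MOI upper bound gives a lower bound on the number of neurons screened.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def transduced_fraction(moi_mean: float) -> float:
    """Fraction of cells with at least one infection: 1 - exp(-lambda)."""
    if moi_mean < 0:
        raise ValueError("moi_mean must be >= 0")
    return float(-math.expm1(-moi_mean))


def coinfection_fractions(moi_mean: float, n_constructs: int) -> np.ndarray:
    """Among transduced cells, fractions expressing exactly 1..k construct types.

    Returns an array of length ``n_constructs`` whose m-th entry (1-based
    m) is C(k, m) p^m (1-p)^(k-m) / (1 - exp(-lambda)) with
    p = 1 - exp(-lambda/k). Entries sum to 1 for any lambda > 0. The
    all-k fraction grows with lambda while the exactly-one fraction tends
    to 1 as lambda -> 0+, the low-titer single-color regime.
    """
    if n_constructs < 1:
        raise ValueError("n_constructs must be >= 1")
    if moi_mean <= 0:
        if moi_mean == 0:
            raise ValueError(
                "moi_mean = 0: no cell is transduced, conditional fractions undefined"
            )
        raise ValueError("moi_mean must be >= 0")
    k = n_constructs
    p = -math.expm1(-moi_mean / k)
    m = np.arange(1, k + 1)
    raw = stats.binom.pmf(m, k, p)
    return raw / -math.expm1(-moi_mean)


def neurons_screened_bound(
    molecules: float, moi_upper: float, n_mice: int = 1
) -> float:
    """Lower bound on neurons screened from Cre-inverted episome counts.

    Every screened neuron carries at most ``moi_upper`` episomes, so
    ``molecules / moi_upper`` neurons at least must have contributed;
    multiplied by ``n_mice`` for a cohort bound. With 5e6 molecules and
    an MOI upper bound of 3 this gives ~1.67e6 neurons per brain.
    """
    if molecules < 0:
        raise ValueError("molecules must be >= 0")
    if moi_upper <= 0:
        raise ValueError("moi_upper must be > 0")
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    return molecules / moi_upper * n_mice


def dpcr_poisson_ci(count: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a molecule count.

    lower = chi2(alpha/2, 2c)/2 (0 when c = 0),
    upper = chi2(1 - alpha/2, 2c + 2)/2.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    upper = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2)
    return lower, upper


def inverted_fraction(
    inverted: float, total: float, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of recovered episomes carrying the Cre-inverted handle.

    Point estimate inverted/total with a conservative interval combining
    independent Poisson CIs on numerator and denominator
    (lower = num_lo/den_hi, upper = num_hi/den_lo). The upper limit is
    not capped at 1: numerator and denominator are separate dPCR
    measurements and their intervals may overlap.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if inverted < 0:
        raise ValueError("inverted must be >= 0")
    num_lo, num_hi = dpcr_poisson_ci(inverted, level)
    den_lo, den_hi = dpcr_poisson_ci(total, level)
    return inverted / total, (num_lo / den_hi, num_hi / den_lo)
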