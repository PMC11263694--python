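"""Bespoke statistics: Sarle's bimodality coefficient and the multi-sample
common-median test for circular data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

from .errors import InvalidInputError

#: Uniform-distribution benchmark of the bimodality coefficient; values
#: above it are conventionally flagged as bimodal.
BIMODALITY_THRESHOLD = 5.0 / 9.0


@dataclass
class BimodalityResult:
    coefficient: float
    n: int
    skewness: float
    excess_kurtosis: float
    bimodal: bool


@dataclass
class CircularTestResult:
    statistic: float
    p_value: float
    group_medians: list
    pooled_median: float


def warren_sarle(x, threshold: float = BIMODALITY_THRESHOLD) -> BimodalityResult:
    """Bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    g1 is the bias-corrected sample skewness and g2 the bias-corrected
    excess kurtosis.  b is 1/3 for a Gaussian, 5/9 for a uniform, and
    approaches 1 for well-separated two-point mixtures.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise InvalidInputError("bimodality coefficient needs n >= 4")
    g1 = float(ss.skew(x, bias=False))
    g2 = float(ss.kurtosis(x, fisher=True, bias=False))
    b = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return BimodalityResult(
        coefficient=float(b),
        n=n,
        skewness=g1,
        excess_kurtosis=g2,
        bimodal=bool(b > threshold),
    )


def _wrap(angles):
    """Normalize to (-pi, pi]."""
    a = np.mod(np.asarray(angles, dtype=float) + np.pi, 2 * np.pi) - np.pi
    a[a == -np.pi] = np.pi
    return a


def circular_distance(a, b):
    """Geodesic distance on the circle, in [0, pi]."""
    d = np.abs(_wrap(np.asarray(a) - np.asarray(b)))
    return d


def circular_median(angles) -> float:
    """Angle minimizing the mean circular distance to the sample.

    The minimizer is searched over the data points themselves and their
    antipodes (the objective is piecewise linear with breakpoints there);
    ties go to the smallest candidate angle.
    """
    a = _wrap(angles)
    if a.size == 0:
        raise InvalidInputError("empty angle sample")
    candidates = np.unique(np.concatenate([a, _wrap(a + np.pi)]))
    d = np.abs(_wrap(a[None, :] - candidates[:, None]))
    costs = d.mean(axis=1)
    best = costs.min()
    return float(candidates[np.isclose(costs, best, atol=1e-12)].min())


def circular_median_test(groups) -> CircularTestResult:
    """Fisher's multi-sample common-median test for circular data.

    The pooled circular median defines a diameter; counts of each group on
    either side form the test statistic

        P = N^2 / (M (N - M)) * sum_i m_i^2 / n_i - N M / (N - M)

    referred to chi-square with k-1 degrees of freedom, where m_i counts
    group-i angles in the half circle anticlockwise of the pooled median.
    """
    groups = [_wrap(g) for g in groups]
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    for g in groups:
        if g.size < 5:
            raise InvalidInputError("each group needs n >= 5")
    pooled = np.concatenate(groups)
    md = circular_median(pooled)
    N = pooled.size
    m = np.array(
        [np.sum(_wrap(g - md) > 0) for g in groups], dtype=float
    )
    n_i = np.array([g.size for g in groups], dtype=float)
    M = m.sum()
    if M == 0 or M == N:
        stat, p = 0.0, 1.0
    else:
        stat = N**2 / (M * (N - M)) * np.sum(m**2 / n_i) - N * M / (N - M)
        p = float(ss.chi2.sf(stat, len(groups) - 1))
    return CircularTestResult(
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        group_medians=[circular_median(g) for g in groups],
        pooled_median=md,
    )
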