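"""Overlapping coefficient (OVL) of two univariate normal densities.

The OVL is the area shared by two probability densities,

    OVL = integral of min(f1(x), f2(x)) dx,

bounded in [0, 1] and equal to 1 exactly when the two distributions
coincide.  For two normals it has a closed form built from the normal CDF:

* equal variances: the densities cross once, halfway between the means,
  and OVL = 2 * Phi(-|mu1 - mu2| / (2 * sigma));
* unequal variances: the densities cross at exactly two points, the roots
  of the quadratic obtained by equating log-densities, and the OVL is the
  sum of three CDF segment probabilities, taking on each segment whichever
  density is pointwise smaller.

:func:`ovl_numeric` is a brute-force trapezoidal integration of the same
quantity, retained as an independent cross-check of the analytic path.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import InvalidInputError

__all__ = ["ovl_normal", "ovl_numeric", "solve_sigma_equal"]

# Relative sigma difference below which the two-crossing geometry is treated
# as the degenerate single-crossing (equal variance) case.
_EQUAL_SIGMA_RTOL = 1e-12


def _validate_sigmas(sigma1: float, sigma2: float) -> None:
    if not (sigma1 > 0 and sigma2 > 0):
        raise InvalidInputError(
            f"standard deviations must be positive, got sigma1={sigma1}, sigma2={sigma2}"
        )


def ovl_normal(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """Analytic overlapping coefficient of N(mu1, sigma1^2) and N(mu2, sigma2^2).

    Parameters
    ----------
    mu1, mu2 : float
        Means of the two normal distributions.
    sigma1, sigma2 : float
        Standard deviations; must be strictly positive.

    Returns
    -------
    float
        The overlap probability in [0, 1].
    """
    _validate_sigmas(sigma1, sigma2)

    # Canonical argument order makes the result bitwise symmetric in the
    # two (mu, sigma) pairs.
    (mu1, sigma1), (mu2, sigma2) = sorted(((mu1, sigma1), (mu2, sigma2)))

    if abs(sigma1 - sigma2) <= _EQUAL_SIGMA_RTOL * max(sigma1, sigma2):
        # Single crossing at the midpoint of the means.
        return float(2.0 * norm.cdf(-abs(mu1 - mu2) / (2.0 * sigma1)))

    # Equate log densities: (x-mu1)^2/s1^2 - (x-mu2)^2/s2^2 + 2 ln(s1/s2) = 0.
    a = 1.0 / sigma1**2 - 1.0 / sigma2**2
    b = -2.0 * (mu1 / sigma1**2 - mu2 / sigma2**2)
    c = mu1**2 / sigma1**2 - mu2**2 / sigma2**2 + 2.0 * math.log(sigma1 / sigma2)
    disc = b * b - 4.0 * a * c
    # Two normals with distinct variances always cross twice; disc can only
    # graze zero through rounding, so clip.
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    x_lo, x_hi = sorted(((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)))

    total = 0.0
    segments = ((-np.inf, x_lo), (x_lo, x_hi), (x_hi, np.inf))
    probes = (x_lo - max(sigma1, sigma2), 0.5 * (x_lo + x_hi), x_hi + max(sigma1, sigma2))
    for (lo, hi), probe in zip(segments, probes):
        # Which density is the min on this segment: decide by evaluating at
        # an interior point.  Log densities, so far-tail probes cannot
        # underflow to a spurious 0-0 tie.
        if norm.logpdf(probe, mu1, sigma1) <= norm.logpdf(probe, mu2, sigma2):
            mu, sigma = mu1, sigma1
        else:
            mu, sigma = mu2, sigma2
        total += norm.cdf(hi, mu, sigma) - norm.cdf(lo, mu, sigma)
    return float(min(total, 1.0))


def ovl_numeric(
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
    grid_step: float = 1e-4,
) -> float:
    """Trapezoidal integration of min(f1, f2) on a dense grid.

    Integration support is [min(mu) - 8*max(sigma), max(mu) + 8*max(sigma)],
    wide enough that the truncated tails contribute < 1e-15.  Used as the
    independent oracle against :func:`ovl_normal`; not meant for production
    calls (it is orders of magnitude slower).
    """
    _validate_sigmas(sigma1, sigma2)
    if not grid_step > 0:
        raise InvalidInputError(f"grid_step must be positive, got {grid_step}")
    s = max(sigma1, sigma2)
    lo = min(mu1, mu2) - 8.0 * s
    hi = max(mu1, mu2) + 8.0 * s
    x = np.arange(lo, hi + grid_step, grid_step)
    y = np.minimum(norm.pdf(x, mu1, sigma1), norm.pdf(x, mu2, sigma2))
    return float(np.trapezoid(y, x))


def solve_sigma_equal(delta: float, target_ovl: float) -> float:
    """Invert the equal-variance overlap for sigma.

    Finds the unique sigma > 0 with ``2 * Phi(-delta / (2*sigma)) == target_ovl``.
    The map sigma -> OVL is strictly increasing (larger spread, more overlap),
    so a bracketing root-find is exact to solver tolerance.  Used to seed the
    default-calibration recovery with equal-variance first guesses.
    """
    if not delta > 0:
        raise InvalidInputError(f"delta must be positive, got {delta}")
    if not 0.0 < target_ovl < 1.0:
        raise InvalidInputError(
            f"target_ovl must lie strictly inside (0, 1), got {target_ovl}"
        )

    def objective(sigma: float) -> float:
        return 2.0 * norm.cdf(-delta / (2.0 * sigma)) - target_ovl

    # OVL -> 0 as sigma -> 0 and -> 1 as sigma -> inf; expand the bracket
    # until it straddles the root.
    lo, hi = 1e-12, 1.0
    while objective(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid targets
            raise InvalidInputError("failed to bracket sigma")
    return float(brentq(objective, lo, hi, xtol=1e-15, rtol=8.9e-16))
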