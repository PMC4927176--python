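"""Beta-Binomial likelihood in the mean/precision parameterization.

The observation model for a survey with ``n`` sighted dugongs and ``y``
calves is Binomial with a Beta-distributed success probability:

    y | p ~ Binomial(n, p),    p ~ Beta(a, b),   a = theta * pi,  b = theta * (1 - pi)

so ``pi`` is the mean calf proportion and ``theta`` the precision: the
variance of y/n inflates the Binomial variance by ``1 + (n - 1)/(theta + 1)``,
and the Binomial is recovered as ``theta -> inf``.

Everything is computed through log-gamma functions, so counts up to 1e6 are
handled without overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln

__all__ = ["betabinomial_logpmf", "betabinomial_pmf", "overdispersion_factor"]


def betabinomial_logpmf(y, n, pi, theta):
    """Log pmf of the Beta-Binomial with mean ``pi`` and precision ``theta``.

    Parameters broadcast against each other. ``y`` outside ``0..n`` maps to
    ``-inf``; ``pi`` outside (0, 1) or ``theta <= 0`` raise ``ValueError``.
    """
    y = np.asarray(y)
    n = np.asarray(n)
    pi = np.asarray(pi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi must lie strictly in (0, 1)")
    if np.any(n < 0):
        raise ValueError("n must be non-negative")
    a = theta * pi
    b = theta * (1.0 - pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + betaln(y + a, n - y + b) - betaln(a, b)
        )
    out = np.where((y < 0) | (y > n), -np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def betabinomial_pmf(y, n, pi, theta):
    return np.exp(betabinomial_logpmf(y, n, pi, theta))


def overdispersion_factor(n, theta):
    """Variance inflation of y/n relative to Binomial: ``1 + (n-1)/(theta+1)``."""
    n = np.asarray(n, dtype=float)
    return 1.0 + (n - 1.0) / (float(theta) + 1.0)
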