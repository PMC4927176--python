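"""Low-rank thin-plate penalized spline basis for the temporal trend.

The smooth trend f(t) is parameterized as

    f(t) = beta0 + beta1 * t + sum_k r_k * z_k(t)

with K penalized columns built from the cubic radial basis |t - kappa_k|^3.
The raw radial columns are post-multiplied by Omega^{-1/2}, where
Omega[k, l] = |kappa_k - kappa_l|^3, which absorbs the thin-plate penalty
into an iid N(0, sigma_r^2) prior on the r_k — the standard low-rank
mixed-model representation of a penalized thin-plate spline.  The
polynomial null space (intercept and linear term) lives in the fixed
effects beta0, beta1.

Knots default to evenly spaced interior quantiles of the *distinct* time
values (25/50/75% for K = 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasis", "SplineBasisError", "build_spline_basis"]


class SplineBasisError(ValueError):
    """Too few distinct time values (or degenerate knots) for the basis."""


@dataclass(frozen=True)
class SplineBasis:
    """Thin-plate basis: knots, penalized design Z, and the Omega^{-1/2} map."""

    knots: np.ndarray            # (K,)
    times: np.ndarray            # (n,) time values the basis was built on
    penalized: np.ndarray        # (n, K) penalized columns z_tk
    _inv_sqrt_omega: np.ndarray  # (K, K)
    _column_means: np.ndarray    # (K,) centering constants (numerical hygiene)

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def design(self, times=None) -> np.ndarray:
        """Full trend design [1, t, z_1..z_K] at ``times`` (default: build times)."""
        if times is None:
            t, Z = self.times, self.penalized
        else:
            t = np.asarray(times, dtype=float)
            Z = self.evaluate(t)
        return np.column_stack([np.ones_like(t), t, Z])

    def evaluate(self, times) -> np.ndarray:
        """Penalized columns at arbitrary time values."""
        t = np.asarray(times, dtype=float)
        raw = np.abs(t[:, None] - self.knots[None, :]) ** 3
        return raw @ self._inv_sqrt_omega - self._column_means[None, :]


def build_spline_basis(time_values, n_knots: int = 3) -> SplineBasis:
    """Construct the low-rank thin-plate basis on standardized times.

    Requires at least ``n_knots + 2`` distinct time values so that knots
    (and the fixed intercept/slope) are identifiable.
    """
    t = np.asarray(time_values, dtype=float)
    if t.ndim != 1:
        raise SplineBasisError("time_values must be one-dimensional")
    distinct = np.unique(t)
    if len(distinct) < n_knots + 2:
        raise SplineBasisError(
            f"need >= {n_knots + 2} distinct time values for K={n_knots}, "
            f"got {len(distinct)}"
        )
    probs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(distinct, probs)
    if len(np.unique(knots)) != n_knots:
        raise SplineBasisError("degenerate (coincident) knots")

    omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    # Omega is symmetric but only conditionally positive definite; take the
    # matrix square root through the SVD, as is standard for this basis.
    u, s, vt = np.linalg.svd(omega)
    sqrt_omega = u @ (np.sqrt(s)[:, None] * vt)
    inv_sqrt = np.linalg.solve(sqrt_omega, np.eye(n_knots))

    raw = np.abs(t[:, None] - knots[None, :]) ** 3
    penalized = raw @ inv_sqrt
    # center the penalized columns on the build times: the removed constant
    # lives in the intercept's null space and centering decorrelates the
    # spline coefficients from beta0 in the sampler
    means = penalized.mean(axis=0)
    return SplineBasis(
        knots=knots, times=t, penalized=penalized - means,
        _inv_sqrt_omega=inv_sqrt, _column_means=means,
    )
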