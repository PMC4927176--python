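"""Shared MCMC plumbing: chain storage, adaptation, convergence diagnostics.

The model-specific samplers (temporal trend, variable selection) are
adaptive random-walk Metropolis-within-Gibbs schemes: each scalar parameter
(or indicator) is updated in turn, with per-parameter, per-chain proposal
scales tuned toward a 44% acceptance rate during burn-in and frozen
afterwards, so the retained draws form a valid Markov chain.

Chains are stored as plain arrays in a :class:`ChainSet`; convergence is
summarized by the Gelman-Rubin potential scale reduction factor computed
from between- and within-chain variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = ["ChainSet", "AdaptiveScales", "gelman_rubin", "psrf", "adaptive_metropolis"]

TARGET_ACCEPT = 0.44  # optimal for scalar random-walk updates


class ChainSet:
    """Posterior draws from several chains plus sampler metadata.

    ``draws`` maps parameter names to arrays of shape (chains, draws) for
    scalars or (chains, draws, dim) for vectors; every chain has the same
    retained length.
    """

    def __init__(self, draws: Mapping[str, np.ndarray], meta: dict | None = None,
                 warnings: list[str] | None = None):
        self.draws = {k: np.asarray(v) for k, v in draws.items()}
        shapes = {v.shape[:2] for v in self.draws.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent chain shapes: {shapes}")
        self.n_chains, self.n_draws = shapes.pop()
        self.meta = dict(meta or {})
        self.warnings = list(warnings or [])

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*draws,) or (chains*draws, dim)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Flatten vector parameters into named scalar series of shape (C, T)."""
        out: dict[str, np.ndarray] = {}
        for name, v in self.draws.items():
            if v.ndim == 2:
                out[name] = v
            else:
                for j in range(v.shape[2]):
                    out[f"{name}[{j}]"] = v[:, :, j]
        return out

    def subsample(self, target_total: int, rng=None) -> "ChainSet":
        """Uniformly subsample to about ``target_total`` pooled draws."""
        per_chain = max(1, target_total // self.n_chains)
        if per_chain >= self.n_draws:
            return self
        idx = np.linspace(0, self.n_draws - 1, per_chain).round().astype(int)
        draws = {k: v[:, idx] for k, v in self.draws.items()}
        meta = dict(self.meta, subsampled_to=per_chain * self.n_chains)
        return ChainSet(draws, meta=meta, warnings=self.warnings)


def psrf(chains: np.ndarray) -> tuple[float, bool]:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (m, n).  Returns (PSRF, degenerate): when the
    within-chain variance is zero the statistic is undefined and is
    reported as 1.0 with the degenerate flag set.
    """
    x = np.asarray(chains, dtype=float)
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    chain_means = x.mean(axis=1)
    within = float(np.mean(x.var(axis=1, ddof=1)))
    between_over_n = float(np.var(chain_means, ddof=1))  # B/n
    # a chain that is constant up to float rounding has no usable
    # within-chain variance; report the statistic as degenerate
    scale = float(np.abs(x).max(initial=0.0))
    if within <= (1e-9 * (1.0 + scale)) ** 2:
        return 1.0, True
    var_plus = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_plus / within)), False


def gelman_rubin(chains: ChainSet, min_draws: int = 10) -> dict[str, float]:
    """PSRF per (flattened) monitored parameter."""
    if chains.n_chains < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    if chains.n_draws < min_draws:
        raise ValueError(f"need >= {min_draws} retained draws per chain")
    return {name: psrf(series)[0] for name, series in chains.scalar_series().items()}


class AdaptiveScales:
    """Per-parameter, per-chain random-walk proposal scales.

    During burn-in the log-scale is nudged by a Robbins-Monro step toward
    the target acceptance rate; calling :meth:`freeze` stops adaptation so
    post-burn-in transitions leave the posterior invariant.
    """

    def __init__(self, n_params: int, n_chains: int, init: float = 0.2):
        self.log_scale = np.full((n_params, n_chains), np.log(init))
        self._step = 0
        self._frozen = False

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def scale(self, j: int) -> np.ndarray:
        return np.exp(self.log_scale[j])

    def update(self, j: int, accepted: np.ndarray, mask: np.ndarray | None = None) -> None:
        if self._frozen:
            return
        gamma = 1.0 / (1.0 + self._step / 100.0) ** 0.6
        step = gamma * (accepted.astype(float) - TARGET_ACCEPT)
        if mask is not None:
            step = np.where(mask, step, 0.0)
        self.log_scale[j] += step

    def tick(self) -> None:
        self._step += 1

    def freeze(self) -> None:
        self._frozen = True


def adaptive_metropolis(
    log_posterior: Callable[[float], float],
    x0: float,
    n_iter: int,
    burnin: int,
    thin: int = 1,
    chains: int = 2,
    seed: int = 0,
    init_jitter: float = 0.1,
    name: str = "x",
) -> ChainSet:
    """Generic one-dimensional adaptive random-walk Metropolis sampler.

    Used for small sub-models (e.g. the intercept-only Binomial check) and
    for validating the update machinery against closed forms; the big model
    samplers use the same adaptation rule on vectorized state.
    """
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    rng = np.random.default_rng(seed)
    x = x0 + init_jitter * rng.standard_normal(chains)
    lp = np.array([log_posterior(v) for v in x])
    # Fall back to x0 where the jittered start left the support.
    bad = ~np.isfinite(lp)
    x[bad] = x0
    lp[bad] = log_posterior(x0)
    scales = AdaptiveScales(1, chains)
    kept = []
    for it in range(n_iter):
        if it == burnin:
            scales.freeze()
        prop = x + scales.scale(0) * rng.standard_normal(chains)
        lp_prop = np.array([log_posterior(v) for v in prop])
        accept = np.log(rng.random(chains)) < lp_prop - lp
        x = np.where(accept, prop, x)
        lp = np.where(accept, lp_prop, lp)
        scales.update(0, accept)
        scales.tick()
        if it >= burnin and (it - burnin) % thin == 0:
            kept.append(x.copy())
    draws = np.array(kept).T  # (chains, draws)
    return ChainSet(
        {name: draws},
        meta={"chains": chains, "iterations": n_iter, "burnin": burnin,
              "thin": thin, "seed": seed},
    )
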