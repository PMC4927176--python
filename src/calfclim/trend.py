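"""Hierarchical Beta-Binomial penalized-spline model of the temporal trend.

For survey j in sub-region l the calf count is Beta-Binomial with mean
``pi`` on the logit scale:

    logit(pi_lj) = f(t_lj) + f_l(t_lj)
    f(t)   = beta0 + beta1 t + sum_k r_k z_k(t)
    f_l(t) = gamma0_l + gamma1_l t + sum_k s_lk z_k(t)      (l > 1)

The first sub-region is the reference: its deviation curve is identically
zero.  Spline coefficients r_k and deviation terms are shrunk by shared
variance components (sigma_r, sigma_s, sigma_gamma) whose standard
deviations carry half-Cauchy(scale 25) priors; the fixed effects beta0,
beta1 get diffuse normal priors; the Beta-Binomial precision theta is
Uniform(0, 100).

Sampling is adaptive random-walk Metropolis-within-Gibbs, vectorized across
chains, with the variance components updated on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .mcmc import AdaptiveScales, ChainSet, gelman_rubin
from .splines import SplineBasis
from .surveys import SubregionRegistry, SurveyTable

__all__ = [
    "PriorConfig",
    "ModelParameters",
    "TrendModel",
    "log_posterior",
    "sample_posterior",
    "trend_summary",
    "sample_intercept_binomial",
]

_PI_EPS = 1e-12


@dataclass(frozen=True)
class PriorConfig:
    """Prior hyper-parameters for both the trend and the global model."""

    fixed_effect_sd: float = 100.0       # diffuse normal on beta0, beta1
    half_cauchy_scale: float = 25.0      # on variance-component sds
    theta_lower: float = 0.0
    theta_upper: float = 100.0
    inclusion_prior: float = 0.5         # Bernoulli prior on term indicators
    slab_sd: float = 2.0                 # normal slab on covariate effects

    def __post_init__(self):
        if self.fixed_effect_sd <= 0 or self.half_cauchy_scale <= 0 or self.slab_sd <= 0:
            raise ValueError("prior scales must be positive")
        if not 0.0 < self.inclusion_prior < 1.0:
            raise ValueError("inclusion prior must lie in (0, 1)")


@dataclass(frozen=True)
class ModelParameters:
    """One point in the trend-model parameter space.

    ``gamma0``, ``gamma1`` have one entry per non-reference sub-region
    (l = 2..L) and ``s`` has shape (L-1, K); the reference deviations are
    implicitly zero.
    """

    beta0: float
    beta1: float
    r: np.ndarray
    gamma0: np.ndarray
    gamma1: np.ndarray
    s: np.ndarray
    theta: float
    sigma_r: float
    sigma_s: float
    sigma_gamma: float

    def coefficient_vector(self) -> np.ndarray:
        return np.concatenate([
            [self.beta0, self.beta1], np.ravel(self.r),
            np.ravel(self.gamma0), np.ravel(self.gamma1), np.ravel(self.s),
        ])


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2))))


class TrendModel:
    """Design matrices, priors and sampler for the trend model.

    The full coefficient vector stacks, in order: beta0, beta1, the K
    overall spline coefficients r, the deviation intercepts and slopes
    (gamma0_l, gamma1_l for l = 2..L), and the deviation spline
    coefficients s_lk.  Each coefficient belongs to a prior group
    ("fixed", "r", "gamma", "s") that determines its shrinkage variance.
    """

    #: index of each variance component in the log-sigma state block
    SIGMA_GROUPS = ("r", "s", "gamma")

    def __init__(self, surveys: SurveyTable, basis: SplineBasis,
                 priors: PriorConfig | None = None,
                 registry: SubregionRegistry | None = None):
        surveys = surveys.model_rows()
        self.surveys = surveys
        self.basis = basis
        self.priors = priors or PriorConfig()
        self.y = surveys.calves.astype(float)
        self.n = surveys.totals.astype(float)
        t = surveys.time_values
        if registry is not None:
            order = {name: registry.index_of(name) for name in set(surveys.subregions)}
            self.subregion_levels = sorted(order, key=order.get)
        else:
            seen: dict[str, None] = {}
            for name in surveys.subregions:
                seen.setdefault(name)
            self.subregion_levels = list(seen)
        self.n_subregions = len(self.subregion_levels)
        level_idx = {name: i for i, name in enumerate(self.subregion_levels)}
        lvl = np.array([level_idx[name] for name in surveys.subregions])

        K = basis.n_knots
        Z = basis.penalized
        cols = [np.ones_like(t), t] + [Z[:, k] for k in range(K)]
        names = ["beta0", "beta1"] + [f"r[{k}]" for k in range(K)]
        groups = ["fixed", "fixed"] + ["r"] * K
        for l in range(1, self.n_subregions):
            ind = (lvl == l).astype(float)
            cols.append(ind)
            names.append(f"gamma0[{self.subregion_levels[l]}]")
            groups.append("gamma")
        for l in range(1, self.n_subregions):
            ind = (lvl == l).astype(float)
            cols.append(ind * t)
            names.append(f"gamma1[{self.subregion_levels[l]}]")
            groups.append("gamma")
        for l in range(1, self.n_subregions):
            ind = (lvl == l).astype(float)
            for k in range(K):
                cols.append(ind * Z[:, k])
                names.append(f"s[{self.subregion_levels[l]},{k}]")
                groups.append("s")
        self.X = np.column_stack(cols)
        self.coef_names = names
        self.coef_groups = groups
        self.n_coef = self.X.shape[1]
        self.K = K
        # binomial coefficient, constant in all parameters: dropped inside the
        # sampler's kernels but needed for the exact joint log posterior
        self._log_binom_const = float(np.sum(
            gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)
        ))

    # -- likelihood pieces -------------------------------------------------

    def _ll_pi(self, eta: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Mean-dependent part of the Beta-Binomial log likelihood, per chain."""
        pi = expit(eta)
        np.clip(pi, _PI_EPS, 1.0 - _PI_EPS, out=pi)
        a = theta[..., None] * pi
        b = theta[..., None] - a
        out = gammaln(self.y + a)
        out += gammaln((self.n - self.y) + b)
        out -= gammaln(a)
        out -= gammaln(b)
        return out.sum(axis=-1)

    def _ll_theta(self, theta: np.ndarray) -> np.ndarray:
        """Precision-only part: len(y) * lngamma(theta) - sum lngamma(n + theta)."""
        return len(self.y) * gammaln(theta) - gammaln(
            self.n[None, :] + theta[..., None]
        ).sum(axis=-1)

    def loglik(self, eta: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return self._ll_pi(eta, theta) + self._ll_theta(theta)

    # -- full log posterior at a parameter point ---------------------------

    def log_posterior(self, params: ModelParameters) -> float:
        p = self.priors
        if not (p.theta_lower < params.theta < p.theta_upper):
            return -np.inf
        for sig in (params.sigma_r, params.sigma_s, params.sigma_gamma):
            if sig <= 0:
                return -np.inf
        coef = params.coefficient_vector()
        if len(coef) != self.n_coef:
            raise ValueError(
                f"parameter vector has {len(coef)} coefficients, model expects "
                f"{self.n_coef}"
            )
        eta = (self.X @ coef)[None, :]
        theta = np.array([params.theta])
        ll = float(self.loglik(eta, theta)[0]) + self._log_binom_const
        group_sd = {"fixed": p.fixed_effect_sd, "r": params.sigma_r,
                    "s": params.sigma_s, "gamma": params.sigma_gamma}
        lp = 0.0
        for x, g in zip(coef, self.coef_groups):
            sd = group_sd[g]
            lp += -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
        for sig in (params.sigma_r, params.sigma_s, params.sigma_gamma):
            lp += _half_cauchy_logpdf(sig, p.half_cauchy_scale)
        lp += -np.log(p.theta_upper - p.theta_lower)
        return ll + lp

    # -- sampler -----------------------------------------------------------

    def sample(
        self,
        chains: int = 3,
        iterations: int = 300_000,
        burnin: int = 50_000,
        thin: int = 10,
        seed: int = 0,
        iterations_are_total: bool = True,
        target_samples: int | None = None,
        psrf_limit: float = 1.05,
    ) -> ChainSet:
        """Run the adaptive Metropolis-within-Gibbs sampler.

        ``iterations`` is the total across chains when
        ``iterations_are_total`` (so 300,000 over three chains means
        100,000 each), else per chain; burn-in and thinning are per chain.
        ``target_samples`` optionally subsamples the retained pooled draws
        down to about that many.  Non-convergence (any PSRF above
        ``psrf_limit``) is recorded as a warning on the returned
        :class:`ChainSet`, not raised.
        """
        per_chain = iterations // chains if iterations_are_total else iterations
        if per_chain <= burnin:
            raise ValueError(
                f"per-chain iterations ({per_chain}) must exceed burnin ({burnin})"
            )
        rng = np.random.default_rng(seed)
        C = chains
        p = self.priors

        coef = 0.1 * rng.standard_normal((C, self.n_coef))
        coef[:, 0] += np.log(
            (self.y.sum() + 0.5) / (self.n.sum() - self.y.sum() + 0.5)
        )
        theta = 10.0 ** rng.uniform(0.5, 1.5, size=C)
        log_sigma = rng.uniform(-1.0, 0.5, size=(C, 3))

        eta = coef @ self.X.T
        ll_pi = self._ll_pi(eta, theta)
        scales = AdaptiveScales(self.n_coef + 4, C, init=0.2)
        group_index = {"r": 0, "s": 1, "gamma": 2}
        group_cols = {
            g: np.array([j for j, gg in enumerate(self.coef_groups) if gg == g])
            for g in self.SIGMA_GROUPS
        }

        kept_coef, kept_theta, kept_sigma = [], [], []
        retained = (per_chain - burnin) // thin
        for it in range(per_chain):
            if it == burnin:
                scales.freeze()
            # coefficient sweep
            for j in range(self.n_coef):
                delta = scales.scale(j) * rng.standard_normal(C)
                eta_prop = eta + delta[:, None] * self.X[None, :, j]
                ll_prop = self._ll_pi(eta_prop, theta)
                g = self.coef_groups[j]
                if g == "fixed":
                    sd = np.full(C, p.fixed_effect_sd)
                else:
                    sd = np.exp(log_sigma[:, group_index[g]])
                x = coef[:, j]
                dprior = -((x + delta) ** 2 - x**2) / (2.0 * sd**2)
                accept = np.log(rng.random(C)) < ll_prop - ll_pi + dprior
                coef[:, j] = np.where(accept, x + delta, x)
                eta = np.where(accept[:, None], eta_prop, eta)
                ll_pi = np.where(accept, ll_prop, ll_pi)
                scales.update(j, accept)
            # theta
            j_theta = self.n_coef
            prop = theta + scales.scale(j_theta) * rng.standard_normal(C)
            inside = (prop > p.theta_lower) & (prop < p.theta_upper)
            prop_safe = np.where(inside, prop, theta)
            ll_cur = ll_pi + self._ll_theta(theta)
            ll_pi_prop = self._ll_pi(eta, prop_safe)
            ll_new = ll_pi_prop + self._ll_theta(prop_safe)
            accept = inside & (np.log(rng.random(C)) < ll_new - ll_cur)
            theta = np.where(accept, prop_safe, theta)
            ll_pi = np.where(accept, ll_pi_prop, ll_pi)
            scales.update(j_theta, accept)
            # variance components (no likelihood involvement)
            for gi, g in enumerate(self.SIGMA_GROUPS):
                cols = group_cols[g]
                if len(cols) == 0:
                    continue
                jj = self.n_coef + 1 + gi
                ls = log_sigma[:, gi]
                ls_prop = ls + scales.scale(jj) * rng.standard_normal(C)
                ssq = (coef[:, cols] ** 2).sum(axis=1)
                m = len(cols)

                def _lp(lsig):
                    sig = np.exp(lsig)
                    prior = np.log(2.0 / (np.pi * p.half_cauchy_scale *
                                          (1.0 + (sig / p.half_cauchy_scale) ** 2)))
                    return (-m * lsig - ssq / (2.0 * sig**2) + prior + lsig)

                accept = np.log(rng.random(C)) < _lp(ls_prop) - _lp(ls)
                log_sigma[:, gi] = np.where(accept, ls_prop, ls)
                scales.update(jj, accept)
            scales.tick()
            if it >= burnin and (it - burnin) % thin == 0:
                kept_coef.append(coef.copy())
                kept_theta.append(theta.copy())
                kept_sigma.append(np.exp(log_sigma))

        coef_draws = np.stack(kept_coef, axis=1)     # (C, T, p)
        theta_draws = np.stack(kept_theta, axis=1)   # (C, T)
        sigma_draws = np.stack(kept_sigma, axis=1)   # (C, T, 3)
        draws = self._pack_draws(coef_draws, theta_draws, sigma_draws)
        meta = {
            "chains": C, "iterations_per_chain": per_chain, "burnin": burnin,
            "thin": thin, "seed": seed, "retained_per_chain": retained,
            "subregions": self.subregion_levels, "coef_names": self.coef_names,
        }
        chain_set = ChainSet(draws, meta=meta)
        if chain_set.n_draws >= 10 and C >= 2:
            diag = gelman_rubin(chain_set)
            worst = max(diag.values())
            chain_set.meta["max_psrf"] = worst
            if worst >= psrf_limit:
                bad = [k for k, v in diag.items() if v >= psrf_limit]
                chain_set.warnings.append(
                    f"non-convergence: PSRF >= {psrf_limit} for {bad}"
                )
        if target_samples is not None:
            chain_set = chain_set.subsample(target_samples)
        return chain_set

    def _pack_draws(self, coef, theta, sigma) -> dict[str, np.ndarray]:
        K, L = self.K, self.n_subregions
        groups = set(self.coef_groups)
        out = {
            "beta0": coef[:, :, 0],
            "beta1": coef[:, :, 1],
            "r": coef[:, :, 2:2 + K],
            "theta": theta,
        }
        # only monitor variance components that actually shrink something
        for gi, g in enumerate(self.SIGMA_GROUPS):
            if g in groups:
                out[f"sigma_{g}"] = sigma[:, :, gi]
        if L > 1:
            d = L - 1
            base = 2 + K
            out["gamma0"] = coef[:, :, base:base + d]
            out["gamma1"] = coef[:, :, base + d:base + 2 * d]
            out["s"] = coef[:, :, base + 2 * d:base + 2 * d + d * K]
        return out


def log_posterior(params: ModelParameters, surveys: SurveyTable,
                  basis: SplineBasis, priors: PriorConfig | None = None,
                  registry: SubregionRegistry | None = None) -> float:
    """Joint log posterior (likelihood + priors) at one parameter point."""
    return TrendModel(surveys, basis, priors, registry).log_posterior(params)


def sample_posterior(surveys: SurveyTable, basis: SplineBasis,
                     priors: PriorConfig | None = None,
                     registry: SubregionRegistry | None = None,
                     **kwargs) -> ChainSet:
    """Fit the trend model; see :meth:`TrendModel.sample` for settings."""
    return TrendModel(surveys, basis, priors, registry).sample(**kwargs)


def trend_summary(chains: ChainSet, basis: SplineBasis, surveys: SurveyTable,
                  years=None, levels: list[str] | None = None) -> pd.DataFrame:
    """Posterior median and 95% credible band of the fitted proportion.

    Evaluates inverse-logit(f(t) + f_l(t)) on a calendar-year grid for every
    sub-region, pooling draws across chains.  Columns: subregion, year,
    median, lower, upper.
    """
    if years is None:
        years = np.arange(surveys.years.min(), surveys.years.max() + 1)
    years = np.asarray(years)
    t = surveys.time_for_years(years)
    D = basis.design(t)                      # (G, 2+K)
    beta0 = chains.pooled("beta0")
    beta1 = chains.pooled("beta1")
    r = chains.pooled("r")
    overall = (np.column_stack([beta0, beta1, r]) @ D.T)  # (draws, G)
    if levels is None:
        levels = chains.meta.get("subregions")
    if levels is None:
        raise ValueError("sub-region levels unavailable; pass `levels`")
    K = basis.n_knots
    rows = []
    for l, name in enumerate(levels):
        eta = overall
        if l > 0 and "gamma0" in chains:
            g0 = chains.pooled("gamma0")[:, l - 1]
            g1 = chains.pooled("gamma1")[:, l - 1]
            s = chains.pooled("s")[:, (l - 1) * K:l * K]
            eta = overall + (
                np.column_stack([g0, g1, s]) @ D.T
            )
        prop = expit(eta)
        med, lo, hi = np.percentile(prop, [50, 2.5, 97.5], axis=0)
        for j, year in enumerate(years):
            rows.append({"subregion": name, "year": int(year),
                         "median": med[j], "lower": lo[j], "upper": hi[j]})
    return pd.DataFrame(rows)


def sample_intercept_binomial(surveys: SurveyTable, chains: int = 3,
                              iterations: int = 6000, burnin: int = 1000,
                              thin: int = 1, seed: int = 0) -> ChainSet:
    """Intercept-only Binomial sub-model with a flat Beta(1, 1) prior.

    Samples the common proportion directly with the package's adaptive
    random-walk machinery.  With a flat prior the posterior is
    Beta(sum(y) + 1, sum(n) - sum(y) + 1), so this sub-model doubles as a
    conjugate oracle for the sampler.
    """
    from .mcmc import adaptive_metropolis

    surveys = surveys.model_rows()
    y = surveys.calves.astype(float)
    n = surveys.totals.astype(float)

    def logpost(prob: float) -> float:
        if not 0.0 < prob < 1.0:
            return -np.inf
        return float(np.sum(y * np.log(prob) + (n - y) * np.log1p(-prob)))

    p0 = float((y.sum() + 1.0) / (n.sum() + 2.0))
    return adaptive_metropolis(logpost, p0, n_iter=iterations, burnin=burnin,
                               thin=thin, chains=chains, seed=seed,
                               init_jitter=0.02, name="p")
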