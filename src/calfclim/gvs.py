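"""Global model with Gibbs variable selection over lagged climate terms.

Every candidate term is one standardized driver-lag column restricted to one
sub-region, carrying its own coefficient and a binary inclusion indicator
with a Bernoulli(0.5) prior.  The linear predictor is

    logit(pi) = trend(t) + sum_m I_m * beta_m * x_m

When an indicator is off, its coefficient is refreshed from a *pseudo-prior*
(a normal centered at the coefficient's posterior mean and sd from a pilot
run with every indicator fixed on), the standard Gibbs-variable-selection
device: it leaves the joint posterior invariant while keeping the excluded
coefficients in a region where re-inclusion is plausible.  The posterior
mean of I_m is the term's posterior inclusion probability; terms exceeding
0.5 are flagged as important predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from scipy.optimize import minimize

from .betabinom import betabinomial_logpmf
from .climate import LaggedDesign
from .mcmc import AdaptiveScales, ChainSet, gelman_rubin
from .splines import SplineBasis
from .surveys import SubregionRegistry, SurveyTable
from .trend import PriorConfig, TrendModel, _PI_EPS

__all__ = [
    "TermSpec",
    "InclusionSummary",
    "PartialEffect",
    "GlobalModel",
    "build_global_model",
    "sample_with_gvs",
    "inclusion_probabilities",
    "partial_effects",
    "exhaustive_model_oracle",
]


@dataclass(frozen=True)
class TermSpec:
    """One candidate effect: a driver at a lag, specific to a sub-region."""

    driver: str
    lag: int
    subregion: str

    @property
    def column(self) -> str:
        return f"{self.driver}_lag{self.lag}"

    @property
    def label(self) -> str:
        return f"{self.subregion}:{self.column}"


class InclusionSummary:
    """Posterior inclusion probabilities per term, with the > 0.5 flag."""

    def __init__(self, frame: pd.DataFrame, threshold: float = 0.5):
        self.frame = frame.reset_index(drop=True)
        self.threshold = threshold

    def important(self) -> pd.DataFrame:
        return self.frame[self.frame["important"]].reset_index(drop=True)

    def probability(self, term: TermSpec) -> float:
        sel = self.frame["term"] == term.label
        if not sel.any():
            raise KeyError(f"unknown term {term.label}")
        return float(self.frame.loc[sel, "probability"].iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PartialEffect:
    """Conditional-on-inclusion effect of one term on the linear predictor.

    ``draws`` are logit-scale effects per +1 sd of the covariate from draws
    in which the term was included; ``percent_effect`` re-expresses them as
    the percent change of the fitted proportion at the average linear
    predictor.  ``significant`` means the 95% credibility interval excludes
    zero; negative effects mean the calf proportion declines as the driver
    increases.
    """

    term: TermSpec
    draws: np.ndarray
    median: float
    lower: float
    upper: float
    significant: bool
    inclusion_probability: float
    percent_effect_median: float
    percent_effect_lower: float
    percent_effect_upper: float
    n_included: int

    @property
    def empty(self) -> bool:
        return self.n_included == 0


class GlobalModel:
    """Trend model plus candidate lagged-driver terms under GVS.

    ``include_trend`` keeps the penalized-spline trend inside the global
    model (the default); tiny conjugate-style toys can instead fix the
    intercept (``fixed_intercept``) and the precision (``fixed_theta``) so
    the posterior over (coefficients, indicators) is exactly enumerable.
    """

    def __init__(
        self,
        surveys: SurveyTable,
        design: LaggedDesign,
        basis: SplineBasis | None = None,
        priors: PriorConfig | None = None,
        registry: SubregionRegistry | None = None,
        include_trend: bool = True,
        fixed_intercept: float | None = None,
        fixed_theta: float | None = None,
    ):
        if len(design.frame) != len(surveys.frame):
            raise ValueError(
                f"design rows ({len(design.frame)}) misaligned with survey rows "
                f"({len(surveys.frame)})"
            )
        keep = surveys.totals > 0
        model_surveys = surveys.model_rows()
        self.surveys = model_surveys
        self.priors = priors or PriorConfig()
        self.fixed_theta = fixed_theta
        self.fixed_intercept = fixed_intercept

        if include_trend:
            if basis is None:
                raise ValueError("include_trend=True requires a spline basis")
            self.trend = TrendModel(model_surveys, basis, self.priors, registry)
            self.subregion_levels = self.trend.subregion_levels
        else:
            self.trend = None
            if registry is not None:
                order = {n: registry.index_of(n) for n in set(model_surveys.subregions)}
                self.subregion_levels = sorted(order, key=order.get)
            else:
                seen: dict[str, None] = {}
                for name in model_surveys.subregions:
                    seen.setdefault(name)
                self.subregion_levels = list(seen)

        self.y = model_surveys.calves.astype(float)
        self.n = model_surveys.totals.astype(float)
        dframe = design.frame.loc[keep].reset_index(drop=True)
        lvl = np.array(model_surveys.subregions)

        self.terms: list[TermSpec] = []
        cols = []
        for name in self.subregion_levels:
            mask = (lvl == name).astype(float)
            for driver in design.drivers:
                for lag in design.lags:
                    col = f"{driver}_lag{lag}"
                    if col not in dframe.columns:
                        continue
                    self.terms.append(TermSpec(driver, int(lag), name))
                    cols.append(mask * dframe[col].to_numpy())
        self.U = np.column_stack(cols) if cols else np.empty((len(self.y), 0))
        self.n_terms = len(self.terms)

        if self.trend is not None:
            self.X = self.trend.X
            self.coef_groups = self.trend.coef_groups
            self.coef_names = self.trend.coef_names
        elif fixed_intercept is None:
            self.X = np.ones((len(self.y), 1))
            self.coef_groups = ["fixed"]
            self.coef_names = ["beta0"]
        else:
            self.X = np.empty((len(self.y), 0))
            self.coef_groups = []
            self.coef_names = []
        self.n_coef = self.X.shape[1]

    # -- likelihood (same Beta-Binomial pieces as the trend model) ---------

    def _ll_pi(self, eta, theta):
        pi = expit(eta)
        np.clip(pi, _PI_EPS, 1.0 - _PI_EPS, out=pi)
        a = theta[..., None] * pi
        b = theta[..., None] - a
        out = gammaln(self.y + a)
        out += gammaln((self.n - self.y) + b)
        out -= gammaln(a)
        out -= gammaln(b)
        return out.sum(axis=-1)

    def _ll_theta(self, theta):
        return len(self.y) * gammaln(theta) - gammaln(
            self.n[None, :] + theta[..., None]
        ).sum(axis=-1)

    # -- sampling ----------------------------------------------------------

    def sample(
        self,
        chains: int = 3,
        iterations: int = 30_000,
        burnin: int = 5_000,
        thin: int = 5,
        seed: int = 0,
        iterations_are_total: bool = True,
        pilot_iterations: int = 3_000,
        pilot_burnin: int = 1_000,
        pseudo_priors: tuple[np.ndarray, np.ndarray] | None = None,
        psrf_limit: float = 1.05,
    ) -> ChainSet:
        """Joint posterior over parameters and inclusion indicators.

        A pilot run with all indicators on supplies the pseudo-priors
        (posterior mean and sd per coefficient) unless they are passed
        explicitly.  Determinism: a fixed ``seed`` reproduces the chains
        bit for bit.
        """
        per_chain = iterations // chains if iterations_are_total else iterations
        if per_chain <= burnin:
            raise ValueError("per-chain iterations must exceed burnin")
        rng = np.random.default_rng(seed)
        p = self.priors
        C, M = chains, self.n_terms

        if pseudo_priors is None and M > 0:
            pseudo_mu, pseudo_sd = self._pilot_pseudo_priors(
                rng, pilot_iterations, pilot_burnin
            )
        elif pseudo_priors is not None:
            pseudo_mu, pseudo_sd = (np.asarray(a, dtype=float) for a in pseudo_priors)
        else:
            pseudo_mu = pseudo_sd = np.empty(0)

        coef = 0.1 * rng.standard_normal((C, self.n_coef))
        if self.n_coef and self.coef_names[0] == "beta0":
            coef[:, 0] += np.log(
                (self.y.sum() + 0.5) / (self.n.sum() - self.y.sum() + 0.5)
            )
        if self.fixed_theta is None:
            theta = 10.0 ** rng.uniform(0.5, 1.5, size=C)
        else:
            theta = np.full(C, float(self.fixed_theta))
        log_sigma = rng.uniform(-1.0, 0.5, size=(C, 3))
        beta_u = pseudo_mu[None, :] + pseudo_sd[None, :] * rng.standard_normal((C, M)) \
            if M else np.empty((C, 0))
        indicator = (rng.random((C, M)) < p.inclusion_prior).astype(float)

        eta_base = np.full((C, len(self.y)), float(self.fixed_intercept or 0.0)) \
            if self.n_coef == 0 else coef @ self.X.T
        if self.fixed_intercept is not None and self.n_coef == 0:
            eta_base[:] = self.fixed_intercept
        eta = eta_base + (beta_u * indicator) @ self.U.T
        ll_pi = self._ll_pi(eta, theta)

        scales = AdaptiveScales(self.n_coef + 4 + M, C, init=0.3)
        group_index = {"r": 0, "s": 1, "gamma": 2}
        group_cols = {
            g: np.array([j for j, gg in enumerate(self.coef_groups) if gg == g])
            for g in ("r", "s", "gamma")
        }
        log_odds_prior = np.log(p.inclusion_prior / (1.0 - p.inclusion_prior))

        kept = {"coef": [], "theta": [], "sigma": [], "beta": [], "ind": []}
        eta_bar_acc, eta_bar_n = 0.0, 0
        for it in range(per_chain):
            if it == burnin:
                scales.freeze()
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
            if self.fixed_theta is None:
                j_theta = self.n_coef
                prop = theta + scales.scale(j_theta) * rng.standard_normal(C)
                inside = (prop > p.theta_lower) & (prop < p.theta_upper)
                prop_safe = np.where(inside, prop, theta)
                ll_pi_prop = self._ll_pi(eta, prop_safe)
                delta_ll = (ll_pi_prop + self._ll_theta(prop_safe)) - (
                    ll_pi + self._ll_theta(theta)
                )
                accept = inside & (np.log(rng.random(C)) < delta_ll)
                theta = np.where(accept, prop_safe, theta)
                ll_pi = np.where(accept, ll_pi_prop, ll_pi)
                scales.update(j_theta, accept)
            for gi, g in enumerate(("r", "s", "gamma")):
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
                    return -m * lsig - ssq / (2.0 * sig**2) + prior + lsig

                accept = np.log(rng.random(C)) < _lp(ls_prop) - _lp(ls)
                log_sigma[:, gi] = np.where(accept, ls_prop, ls)
                scales.update(jj, accept)
            # --- term coefficients and indicators ---
            for m_i in range(M):
                u = self.U[:, m_i]
                jj = self.n_coef + 4 + m_i
                inc = indicator[:, m_i] > 0.5
                b = beta_u[:, m_i]
                # included chains: random-walk MH under the slab prior.
                # Skipped outright when every chain excludes the term — the
                # proposal would leave eta untouched and the coefficient is
                # refreshed exactly from the pseudo-prior below anyway.
                if inc.any():
                    delta = scales.scale(jj) * rng.standard_normal(C)
                    delta_eff = np.where(inc, delta, 0.0)
                    eta_prop = eta + delta_eff[:, None] * u[None, :]
                    ll_prop = self._ll_pi(eta_prop, theta)
                    dprior = -((b + delta) ** 2 - b**2) / (2.0 * p.slab_sd**2)
                    accept = inc & (np.log(rng.random(C)) < ll_prop - ll_pi + dprior)
                    beta_u[:, m_i] = np.where(accept, b + delta, b)
                    eta = np.where(accept[:, None], eta_prop, eta)
                    ll_pi = np.where(accept, ll_prop, ll_pi)
                    scales.update(jj, accept, mask=inc)  # adapt on included chains only
                # excluded chains: refresh from the pseudo-prior (exact Gibbs)
                fresh = pseudo_mu[m_i] + pseudo_sd[m_i] * rng.standard_normal(C)
                beta_u[:, m_i] = np.where(inc, beta_u[:, m_i], fresh)
                # indicator: exact Bernoulli full conditional.  One of the two
                # states is the current one, so only the toggled state needs a
                # fresh likelihood evaluation.
                b = beta_u[:, m_i]
                ind_m = indicator[:, m_i]
                eta0 = eta - (ind_m * b)[:, None] * u[None, :]
                eta_flip = eta + ((1.0 - 2.0 * ind_m) * b)[:, None] * u[None, :]
                ll_flip = self._ll_pi(eta_flip, theta)
                on = ind_m > 0.5
                ll1 = np.where(on, ll_pi, ll_flip)
                ll0 = np.where(on, ll_flip, ll_pi)
                lo = (ll1 - ll0 + log_odds_prior
                      - 0.5 * (b / p.slab_sd) ** 2 - np.log(p.slab_sd)
                      + 0.5 * ((b - pseudo_mu[m_i]) / pseudo_sd[m_i]) ** 2
                      + np.log(pseudo_sd[m_i]))
                new_ind = (rng.random(C) < expit(lo)).astype(float)
                indicator[:, m_i] = new_ind
                eta = eta0 + (new_ind * b)[:, None] * u[None, :]
                ll_pi = np.where(new_ind > 0.5, ll1, ll0)
            scales.tick()
            if it >= burnin and (it - burnin) % thin == 0:
                kept["coef"].append(coef.copy())
                kept["theta"].append(theta.copy())
                kept["sigma"].append(np.exp(log_sigma))
                kept["beta"].append(beta_u.copy())
                kept["ind"].append(indicator.copy())
                eta_bar_acc += float(eta.mean())
                eta_bar_n += 1

        draws: dict[str, np.ndarray] = {
            "theta": np.stack(kept["theta"], axis=1),
        }
        if M:
            draws["effects"] = np.stack(kept["beta"], axis=1)
            draws["indicators"] = np.stack(kept["ind"], axis=1)
        if self.n_coef:
            coef_draws = np.stack(kept["coef"], axis=1)
            if self.trend is not None:
                sigma_draws = np.stack(kept["sigma"], axis=1)
                draws.update(self.trend._pack_draws(
                    coef_draws, draws["theta"], sigma_draws
                ))
            else:
                draws["beta0"] = coef_draws[:, :, 0]
        meta = {
            "chains": C, "iterations_per_chain": per_chain, "burnin": burnin,
            "thin": thin, "seed": seed,
            "terms": [
                {"driver": t.driver, "lag": t.lag, "subregion": t.subregion}
                for t in self.terms
            ],
            "subregions": self.subregion_levels,
            "eta_bar": eta_bar_acc / max(eta_bar_n, 1),
            "pseudo_mu": pseudo_mu.tolist(), "pseudo_sd": pseudo_sd.tolist(),
        }
        chain_set = ChainSet(draws, meta=meta)
        monitored = {k: v for k, v in draws.items() if k != "indicators"}
        if chain_set.n_draws >= 10 and C >= 2:
            diag = gelman_rubin(ChainSet(monitored, meta=meta))
            chain_set.meta["max_psrf"] = max(diag.values())
            if chain_set.meta["max_psrf"] >= psrf_limit:
                chain_set.warnings.append(
                    f"non-convergence: max PSRF {chain_set.meta['max_psrf']:.3f}"
                )
        return chain_set

    def _pilot_pseudo_priors(self, rng, iterations, burnin):
        """Short all-terms-included run giving pseudo-prior centers/widths."""
        seed = int(rng.integers(0, 2**31 - 1))
        pilot = _AllInModel(self).sample(iterations=iterations, burnin=burnin,
                                         seed=seed)
        eff = pilot.pooled("effects")
        mu = eff.mean(axis=0)
        sd = np.maximum(eff.std(axis=0, ddof=1), 0.05)
        return mu, sd


class _AllInModel:
    """The global model with every indicator clamped on (pilot run)."""

    def __init__(self, parent: GlobalModel):
        self.parent = parent

    def sample(self, iterations=3000, burnin=1000, seed=0) -> ChainSet:
        gm = self.parent
        rng = np.random.default_rng(seed)
        C = 2
        M = gm.n_terms
        p = gm.priors
        coef = 0.1 * rng.standard_normal((C, gm.n_coef))
        if gm.n_coef and gm.coef_names[0] == "beta0":
            coef[:, 0] += np.log(
                (gm.y.sum() + 0.5) / (gm.n.sum() - gm.y.sum() + 0.5)
            )
        theta = np.full(C, float(gm.fixed_theta)) if gm.fixed_theta is not None \
            else 10.0 ** rng.uniform(0.5, 1.5, size=C)
        log_sigma = rng.uniform(-1.0, 0.0, size=(C, 3))
        beta_u = 0.1 * rng.standard_normal((C, M))
        eta = (coef @ gm.X.T if gm.n_coef else
               np.full((C, len(gm.y)), float(gm.fixed_intercept or 0.0)))
        eta = eta + beta_u @ gm.U.T
        ll_pi = gm._ll_pi(eta, theta)
        scales = AdaptiveScales(gm.n_coef + 1 + 3 + M, C, init=0.3)
        group_index = {"r": 0, "s": 1, "gamma": 2}
        group_cols = {
            g: np.array([j for j, gg in enumerate(gm.coef_groups) if gg == g])
            for g in ("r", "s", "gamma")
        }
        kept_beta = []
        for it in range(iterations):
            if it == burnin:
                scales.freeze()
            for j in range(gm.n_coef):
                delta = scales.scale(j) * rng.standard_normal(C)
                eta_prop = eta + delta[:, None] * gm.X[None, :, j]
                ll_prop = gm._ll_pi(eta_prop, theta)
                g = gm.coef_groups[j]
                sd = (np.full(C, p.fixed_effect_sd) if g == "fixed"
                      else np.exp(log_sigma[:, group_index[g]]))
                x = coef[:, j]
                dprior = -((x + delta) ** 2 - x**2) / (2.0 * sd**2)
                accept = np.log(rng.random(C)) < ll_prop - ll_pi + dprior
                coef[:, j] = np.where(accept, x + delta, x)
                eta = np.where(accept[:, None], eta_prop, eta)
                ll_pi = np.where(accept, ll_prop, ll_pi)
                scales.update(j, accept)
            if gm.fixed_theta is None:
                jt = gm.n_coef
                prop = theta + scales.scale(jt) * rng.standard_normal(C)
                inside = (prop > p.theta_lower) & (prop < p.theta_upper)
                prop_safe = np.where(inside, prop, theta)
                ll_pi_prop = gm._ll_pi(eta, prop_safe)
                delta_ll = (ll_pi_prop + gm._ll_theta(prop_safe)) - (
                    ll_pi + gm._ll_theta(theta))
                accept = inside & (np.log(rng.random(C)) < delta_ll)
                theta = np.where(accept, prop_safe, theta)
                ll_pi = np.where(accept, ll_pi_prop, ll_pi)
                scales.update(jt, accept)
            for gi, g in enumerate(("r", "s", "gamma")):
                cols = group_cols[g]
                if len(cols) == 0:
                    continue
                jj = gm.n_coef + 1 + gi
                ls = log_sigma[:, gi]
                ls_prop = ls + scales.scale(jj) * rng.standard_normal(C)
                ssq = (coef[:, cols] ** 2).sum(axis=1)
                mcols = len(cols)

                def _lp(lsig):
                    sig = np.exp(lsig)
                    prior = np.log(2.0 / (np.pi * p.half_cauchy_scale *
                                          (1.0 + (sig / p.half_cauchy_scale) ** 2)))
                    return -mcols * lsig - ssq / (2.0 * sig**2) + prior + lsig

                accept = np.log(rng.random(C)) < _lp(ls_prop) - _lp(ls)
                log_sigma[:, gi] = np.where(accept, ls_prop, ls)
                scales.update(jj, accept)
            for m_i in range(M):
                jj = gm.n_coef + 4 + m_i
                u = gm.U[:, m_i]
                delta = scales.scale(jj) * rng.standard_normal(C)
                eta_prop = eta + delta[:, None] * u[None, :]
                ll_prop = gm._ll_pi(eta_prop, theta)
                b = beta_u[:, m_i]
                dprior = -((b + delta) ** 2 - b**2) / (2.0 * p.slab_sd**2)
                accept = np.log(rng.random(C)) < ll_prop - ll_pi + dprior
                beta_u[:, m_i] = np.where(accept, b + delta, b)
                eta = np.where(accept[:, None], eta_prop, eta)
                ll_pi = np.where(accept, ll_prop, ll_pi)
                scales.update(jj, accept)
            scales.tick()
            if it >= burnin:
                kept_beta.append(beta_u.copy())
        return ChainSet({"effects": np.stack(kept_beta, axis=1)},
                        meta={"pilot": True})


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def build_global_model(surveys: SurveyTable, design: LaggedDesign,
                       basis: SplineBasis | None = None,
                       priors: PriorConfig | None = None,
                       registry: SubregionRegistry | None = None,
                       **kwargs) -> GlobalModel:
    return GlobalModel(surveys, design, basis, priors, registry, **kwargs)


def sample_with_gvs(model: GlobalModel, **kwargs) -> ChainSet:
    return model.sample(**kwargs)


def _terms_from_meta(chains: ChainSet) -> list[TermSpec]:
    terms = chains.meta.get("terms")
    if terms is None:
        raise ValueError("chain set carries no term metadata")
    return [TermSpec(t["driver"], t["lag"], t["subregion"]) for t in terms]


def inclusion_probabilities(chains: ChainSet, threshold: float = 0.5) -> InclusionSummary:
    """Per-term posterior inclusion probability, pooled across chains.

    ``important`` uses a strict comparison: a probability of exactly
    ``threshold`` is not flagged.
    """
    if "indicators" not in chains:
        raise ValueError("no inclusion-indicator draws in this chain set")
    terms = _terms_from_meta(chains)
    probs = chains.pooled("indicators").mean(axis=0)
    rows = [
        {
            "subregion": t.subregion, "driver": t.driver, "lag": t.lag,
            "term": t.label, "probability": float(pr),
            "important": bool(pr > threshold),
        }
        for t, pr in zip(terms, probs)
    ]
    return InclusionSummary(pd.DataFrame(rows), threshold=threshold)


def partial_effects(chains: ChainSet, term: TermSpec) -> PartialEffect:
    """Conditional-on-inclusion summary of one term's effect."""
    terms = _terms_from_meta(chains)
    labels = [t.label for t in terms]
    if term.label not in labels:
        raise KeyError(f"unknown term {term.label}; known: {labels}")
    m_i = labels.index(term.label)
    ind = chains.pooled("indicators")[:, m_i] > 0.5
    eff = chains.pooled("effects")[:, m_i]
    pip = float(ind.mean())
    included = eff[ind]
    if len(included) == 0:
        return PartialEffect(term, included, np.nan, np.nan, np.nan, False,
                             pip, np.nan, np.nan, np.nan, 0)
    lo, med, hi = np.percentile(included, [2.5, 50, 97.5])
    eta_bar = float(chains.meta.get("eta_bar", 0.0))
    base = expit(eta_bar)
    pct = 100.0 * (expit(eta_bar + included) - base) / base
    plo, pmed, phi = np.percentile(pct, [2.5, 50, 97.5])
    return PartialEffect(
        term=term, draws=included, median=float(med), lower=float(lo),
        upper=float(hi), significant=bool(lo > 0 or hi < 0),
        inclusion_probability=pip, percent_effect_median=float(pmed),
        percent_effect_lower=float(plo), percent_effect_upper=float(phi),
        n_included=int(ind.sum()),
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (p <= 4)
# ---------------------------------------------------------------------------

def exhaustive_model_oracle(
    y: np.ndarray,
    n: np.ndarray,
    covariates: np.ndarray,
    intercept: float,
    theta: float,
    slab_sd: float = 2.0,
    inclusion_prior: float = 0.5,
    grid_points: int = 41,
    grid_halfwidth: float = 6.0,
) -> dict:
    """Exact posterior model and inclusion probabilities by enumeration.

    For every subset S of the p candidate columns the marginal likelihood
    is computed by tensor-grid quadrature over the included coefficients
    (Beta-Binomial likelihood at fixed intercept and precision, normal
    slab prior), Laplace-centered so a modest grid is accurate.  Refuses
    p > 4.

    Returns ``{"model_probs": {subset: prob}, "inclusion_probs": array}``.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    U = np.asarray(covariates, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    p_terms = U.shape[1] if U.size else 0
    if p_terms > 4:
        raise ValueError(f"enumeration refuses p > 4 (got {p_terms})")

    def loglik(eta):
        pi = np.clip(expit(eta), _PI_EPS, 1 - _PI_EPS)
        return betabinomial_logpmf(y, n, pi, theta).sum(axis=-1)

    log_ml: dict[tuple[int, ...], float] = {}
    subsets = []
    for mask in range(2 ** p_terms):
        S = tuple(j for j in range(p_terms) if mask >> j & 1)
        subsets.append(S)
        if not S:
            log_ml[S] = float(loglik(np.full(len(y), intercept)))
            continue
        Xs = U[:, S]
        d = len(S)

        def neg_logpost(b):
            eta = intercept + Xs @ b
            return -(loglik(eta) - 0.5 * np.sum((b / slab_sd) ** 2)
                     - d * np.log(slab_sd * np.sqrt(2 * np.pi)))

        res = minimize(neg_logpost, np.zeros(d), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        mode = res.x
        # numerical Hessian for the Laplace width
        h = 1e-4
        H = np.zeros((d, d))
        f0 = neg_logpost(mode)
        for a in range(d):
            for bidx in range(a, d):
                ea = np.eye(d)[a] * h
                eb = np.eye(d)[bidx] * h
                H[a, bidx] = H[bidx, a] = (
                    neg_logpost(mode + ea + eb) - neg_logpost(mode + ea - eb)
                    - neg_logpost(mode - ea + eb) + neg_logpost(mode - ea - eb)
                ) / (4 * h * h)
        try:
            widths = np.sqrt(np.diag(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            widths = np.full(d, slab_sd)
        widths = np.where(np.isfinite(widths) & (widths > 0), widths, slab_sd)
        axes = [
            mode[a] + np.linspace(-grid_halfwidth, grid_halfwidth, grid_points)
            * widths[a]
            for a in range(d)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        B = np.column_stack([m.ravel() for m in mesh])        # (G, d)
        eta = intercept + B @ Xs.T                            # (G, N)
        lp = (loglik(eta)
              - 0.5 * np.sum((B / slab_sd) ** 2, axis=1)
              - d * np.log(slab_sd * np.sqrt(2 * np.pi)))
        log_dv = float(np.sum(np.log([ax[1] - ax[0] for ax in axes])))
        log_ml[S] = float(logsumexp(lp) + log_dv)

    logs = np.array([
        log_ml[S]
        + len(S) * np.log(inclusion_prior)
        + (p_terms - len(S)) * np.log(1.0 - inclusion_prior)
        for S in subsets
    ])
    probs = np.exp(logs - logsumexp(logs))
    model_probs = {S: float(pr) for S, pr in zip(subsets, probs)}
    inclusion = np.zeros(p_terms)
    for S, pr in model_probs.items():
        for j in S:
            inclusion[j] += pr
    return {"model_probs": model_probs, "inclusion_probs": inclusion,
            "log_marginal": {S: log_ml[S] for S in subsets}}
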