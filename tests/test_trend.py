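import numpy as np
import pytest
from scipy.special import expit

from calfclim.betabinom import betabinomial_logpmf
from calfclim.mcmc import ChainSet
from calfclim.splines import build_spline_basis
from calfclim.surveys import SurveyTable
from calfclim.trend import (
    ModelParameters,
    PriorConfig,
    TrendModel,
    log_posterior,
    trend_summary,
)
from conftest import make_survey_table


@pytest.fixture
def one_region_table():
    rows = [("southern_gbr", y, "spring_summer", 150 + 10 * i, 12 + i)
            for i, y in enumerate((1990, 1993, 1996, 1999, 2002, 2005, 2008))]
    return make_survey_table(rows)


def params_for(model, beta0=-2.0, beta1=0.1, theta=20.0):
    K = model.K
    d = model.n_subregions - 1
    return ModelParameters(
        beta0=beta0, beta1=beta1, r=0.05 * np.arange(1, K + 1),
        gamma0=0.1 * np.ones(d), gamma1=-0.05 * np.ones(d),
        s=np.zeros((d, K)), theta=theta,
        sigma_r=0.7, sigma_s=0.4, sigma_gamma=0.9,
    )


def halfcauchy_logpdf(x, scale):
    return np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2)))


def normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def test_log_posterior_matches_independent_computation(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    model = TrendModel(one_region_table, basis)
    params = params_for(model)

    t = one_region_table.time_values
    eta = params.beta0 + params.beta1 * t + basis.penalized @ params.r
    ll = betabinomial_logpmf(one_region_table.calves, one_region_table.totals,
                             expit(eta), params.theta).sum()
    lp = ll
    lp += normal_logpdf(params.beta0, 100.0) + normal_logpdf(params.beta1, 100.0)
    lp += sum(normal_logpdf(rk, params.sigma_r) for rk in params.r)
    for sig in (params.sigma_r, params.sigma_s, params.sigma_gamma):
        lp += halfcauchy_logpdf(sig, 25.0)
    lp += -np.log(100.0)   # Uniform(0, 100) on theta

    assert model.log_posterior(params) == pytest.approx(float(lp), abs=1e-8)
    # functional wrapper agrees
    assert log_posterior(params, one_region_table, basis) == pytest.approx(
        float(lp), abs=1e-8
    )


def test_log_posterior_outside_support(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    model = TrendModel(one_region_table, basis)
    p = params_for(model)
    from dataclasses import replace
    assert model.log_posterior(replace(p, theta=150.0)) == -np.inf
    assert model.log_posterior(replace(p, theta=-1.0)) == -np.inf
    assert model.log_posterior(replace(p, sigma_r=-0.5)) == -np.inf


def test_log_posterior_rejects_wrong_length(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    model = TrendModel(one_region_table, basis)
    p = params_for(model)
    from dataclasses import replace
    with pytest.raises(ValueError, match="coefficients"):
        model.log_posterior(replace(p, r=np.zeros(5)))


def test_log_posterior_invariant_to_record_order(table1_fixture):
    surveys = table1_fixture.surveys
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(surveys))
    shuffled = SurveyTable(surveys.frame.iloc[perm])
    b1 = table1_fixture.basis
    b2 = build_spline_basis(shuffled.time_values)
    m1 = TrendModel(surveys, b1, registry=table1_fixture.registry)
    m2 = TrendModel(shuffled, b2, registry=table1_fixture.registry)
    p1 = params_for(m1)
    assert m2.log_posterior(p1) == pytest.approx(m1.log_posterior(p1), abs=1e-8)


def test_design_matrix_layout(table1_fixture):
    model = TrendModel(table1_fixture.surveys, table1_fixture.basis,
                       registry=table1_fixture.registry)
    # 2 fixed + 3 spline + 4 gamma0 + 4 gamma1 + 12 deviation-spline
    assert model.n_coef == 25
    assert model.subregion_levels == [
        "torres_strait", "northern_gbr", "southern_gbr", "hervey_bay", "moreton_bay",
    ]
    assert model.coef_groups.count("fixed") == 2
    assert model.coef_groups.count("r") == 3
    assert model.coef_groups.count("gamma") == 8
    assert model.coef_groups.count("s") == 12


def test_sampler_deterministic(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    model = TrendModel(one_region_table, basis)
    kwargs = dict(chains=2, iterations=800, burnin=200, thin=2, seed=42)
    a = model.sample(**kwargs)
    b = model.sample(**kwargs)
    for name in a.draws:
        assert np.array_equal(a.get(name), b.get(name))
    assert a.meta["retained_per_chain"] == (400 - 200) // 2


def test_sampler_rejects_short_runs(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    model = TrendModel(one_region_table, basis)
    with pytest.raises(ValueError, match="exceed"):
        model.sample(chains=2, iterations=100, burnin=200)


def fake_chains(rng, n_levels, T=200, C=2, K=3):
    levels = ["torres_strait", "northern_gbr", "southern_gbr",
              "hervey_bay", "moreton_bay"][:n_levels]
    draws = {
        "beta0": rng.normal(-2.0, 0.1, size=(C, T)),
        "beta1": rng.normal(0.1, 0.05, size=(C, T)),
        "r": rng.normal(0, 0.02, size=(C, T, K)),
        "theta": rng.uniform(10, 30, size=(C, T)),
    }
    if n_levels > 1:
        d = n_levels - 1
        draws["gamma0"] = np.zeros((C, T, d))
        draws["gamma1"] = np.zeros((C, T, d))
        draws["s"] = np.zeros((C, T, d * K))
    return ChainSet(draws, meta={"subregions": levels})


def test_trend_summary_percentile_oracle(one_region_table):
    basis = build_spline_basis(one_region_table.time_values)
    rng = np.random.default_rng(3)
    chains = fake_chains(rng, n_levels=1)
    years = np.array([1990, 2000, 2008])
    out = trend_summary(chains, basis, one_region_table, years=years)
    D = basis.design(one_region_table.time_for_years(years))
    coefs = np.column_stack([
        chains.pooled("beta0"), chains.pooled("beta1"), chains.pooled("r"),
    ])
    prop = expit(coefs @ D.T)
    expected = np.percentile(prop, [50, 2.5, 97.5], axis=0)
    for j, year in enumerate(years):
        row = out[(out["year"] == year)].iloc[0]
        assert row["median"] == pytest.approx(expected[0, j], abs=1e-12)
        assert row["lower"] == pytest.approx(expected[1, j], abs=1e-12)
        assert row["upper"] == pytest.approx(expected[2, j], abs=1e-12)
    assert ((out["median"] > 0) & (out["median"] < 1)).all()
    assert (out["lower"] <= out["median"]).all()
    assert (out["median"] <= out["upper"]).all()


def test_trend_summary_zero_deviations_collapse_to_reference(table1_fixture):
    rng = np.random.default_rng(4)
    chains = fake_chains(rng, n_levels=5)
    out = trend_summary(chains, table1_fixture.basis, table1_fixture.surveys,
                        years=[1990, 2005])
    ref = out[out["subregion"] == "torres_strait"].set_index("year")
    for name in ("northern_gbr", "moreton_bay"):
        other = out[out["subregion"] == name].set_index("year")
        assert np.allclose(other["median"], ref["median"])
        assert np.allclose(other["lower"], ref["lower"])
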