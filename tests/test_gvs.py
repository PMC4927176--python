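import numpy as np
import pytest
from scipy.special import expit

from calfclim.gvs import (
    GlobalModel,
    TermSpec,
    exhaustive_model_oracle,
    inclusion_probabilities,
    partial_effects,
)
from calfclim.mcmc import ChainSet
from calfclim.surveys import SurveyTable


def test_term_spec_labels():
    term = TermSpec("SOI", 2, "southern_gbr")
    assert term.column == "SOI_lag2"
    assert term.label == "southern_gbr:SOI_lag2"


def test_global_model_enumerates_all_terms(table1_fixture):
    gm = GlobalModel(table1_fixture.surveys, table1_fixture.design,
                     table1_fixture.basis, registry=table1_fixture.registry)
    assert gm.n_terms == 80  # 5 sub-regions x 4 drivers x 4 lags
    labels = {t.label for t in gm.terms}
    assert "southern_gbr:SOI_lag2" in labels
    assert "torres_strait:TC_lag4" in labels
    # each term's column is masked to its own sub-region
    idx = [t.label for t in gm.terms].index("southern_gbr:SOI_lag2")
    col = gm.U[:, idx]
    lvl = np.array(gm.surveys.subregions)
    assert np.all(col[lvl != "southern_gbr"] == 0.0)
    assert np.any(col[lvl == "southern_gbr"] != 0.0)
    inside = table1_fixture.design.frame["SOI_lag2"].to_numpy()[lvl == "southern_gbr"]
    assert np.allclose(col[lvl == "southern_gbr"], inside)


def test_misaligned_design_rejected(table1_fixture, tiny_toy_fixture):
    with pytest.raises(ValueError, match="misaligned"):
        GlobalModel(table1_fixture.surveys, tiny_toy_fixture.design,
                    table1_fixture.basis)


def make_selection_chains(indicators, effects, terms, eta_bar=-2.0):
    C, T, M = indicators.shape
    return ChainSet(
        {"indicators": indicators, "effects": effects,
         "theta": np.full((C, T), 20.0)},
        meta={
            "terms": [{"driver": t.driver, "lag": t.lag, "subregion": t.subregion}
                      for t in terms],
            "eta_bar": eta_bar,
        },
    )


def test_inclusion_probabilities_exact_and_strict_threshold():
    terms = [TermSpec("SOI", 1, "hervey_bay"), TermSpec("TC", 2, "hervey_bay"),
             TermSpec("NINO34", 3, "hervey_bay")]
    ind = np.zeros((2, 4, 3))
    ind[:, :, 0] = 1.0                      # always in -> 1.0
    ind[0, :, 1] = 1.0                      # half the draws -> exactly 0.5
    eff = np.zeros((2, 4, 3))
    cs = make_selection_chains(ind, eff, terms)
    summary = inclusion_probabilities(cs)
    assert summary.probability(terms[0]) == 1.0
    assert summary.probability(terms[1]) == 0.5
    assert summary.probability(terms[2]) == 0.0
    # strict: exactly at the threshold is NOT flagged
    flagged = summary.important()["term"].tolist()
    assert flagged == ["hervey_bay:SOI_lag1"]
    with pytest.raises(KeyError):
        summary.probability(TermSpec("SOI", 4, "moreton_bay"))


def test_partial_effects_percentile_oracle():
    terms = [TermSpec("SOI", 1, "hervey_bay")]
    rng = np.random.default_rng(5)
    eff = rng.normal(-1.2, 0.2, size=(2, 500, 1))
    ind = np.ones((2, 500, 1))
    ind[0, :100, 0] = 0.0                   # excluded draws must be ignored
    cs = make_selection_chains(ind, eff, terms, eta_bar=-2.0)
    pe = partial_effects(cs, terms[0])
    included = eff.reshape(-1)[ind.reshape(-1) > 0.5]
    lo, med, hi = np.percentile(included, [2.5, 50, 97.5])
    assert pe.median == pytest.approx(med)
    assert pe.lower == pytest.approx(lo)
    assert pe.upper == pytest.approx(hi)
    assert pe.significant and pe.upper < 0
    assert pe.n_included == len(included)
    assert pe.inclusion_probability == pytest.approx(0.9)
    base = expit(-2.0)
    pct = 100 * (expit(-2.0 + included) - base) / base
    assert pe.percent_effect_median == pytest.approx(np.percentile(pct, 50))


def test_partial_effects_symmetric_draws_not_significant():
    terms = [TermSpec("SOI", 1, "hervey_bay")]
    rng = np.random.default_rng(6)
    eff = rng.normal(0.0, 0.5, size=(2, 400, 1))
    ind = np.ones((2, 400, 1))
    cs = make_selection_chains(ind, eff, terms)
    assert not partial_effects(cs, terms[0]).significant


def test_partial_effects_never_included_is_empty():
    terms = [TermSpec("SOI", 1, "hervey_bay")]
    cs = make_selection_chains(np.zeros((2, 50, 1)), np.zeros((2, 50, 1)), terms)
    pe = partial_effects(cs, terms[0])
    assert pe.empty and np.isnan(pe.median)
    assert pe.inclusion_probability == 0.0


def test_partial_effects_unknown_term():
    terms = [TermSpec("SOI", 1, "hervey_bay")]
    cs = make_selection_chains(np.ones((2, 5, 1)), np.zeros((2, 5, 1)), terms)
    with pytest.raises(KeyError):
        partial_effects(cs, TermSpec("TC", 1, "hervey_bay"))


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def test_oracle_empty_model():
    y = np.array([3.0, 5.0])
    n = np.array([30.0, 40.0])
    out = exhaustive_model_oracle(y, n, np.empty((2, 0)), intercept=-2.0,
                                  theta=20.0)
    assert out["model_probs"] == {(): 1.0}
    assert out["inclusion_probs"].size == 0


def test_oracle_probabilities_normalize_and_symmetrize():
    rng = np.random.default_rng(7)
    n = np.full(20, 200.0)
    x = rng.standard_normal(20)
    U = np.column_stack([x, x])             # identical duplicate columns
    pi = expit(-2.0 + 0.8 * x)
    y = rng.binomial(200, pi).astype(float)
    out = exhaustive_model_oracle(y, n, U, intercept=-2.0, theta=1e4,
                                  grid_points=31)
    total = sum(out["model_probs"].values())
    assert total == pytest.approx(1.0, abs=1e-10)
    p1, p2 = out["inclusion_probs"]
    assert p1 == pytest.approx(p2, abs=2e-3)    # symmetric by construction
    # the signal is real: something should be included with high probability
    assert out["model_probs"][()] < 0.05


def test_oracle_respects_inclusion_prior():
    rng = np.random.default_rng(8)
    n = np.full(15, 100.0)
    x = rng.standard_normal(15)
    y = rng.binomial(100, expit(-2.0), size=15).astype(float)  # pure noise column
    lo = exhaustive_model_oracle(y, n, x, intercept=-2.0, theta=1e4,
                                 inclusion_prior=0.1, grid_points=31)
    hi = exhaustive_model_oracle(y, n, x, intercept=-2.0, theta=1e4,
                                 inclusion_prior=0.9, grid_points=31)
    assert hi["inclusion_probs"][0] > lo["inclusion_probs"][0]


def test_oracle_refuses_large_spaces():
    with pytest.raises(ValueError, match="p > 4"):
        exhaustive_model_oracle(np.array([1.0]), np.array([10.0]),
                                np.zeros((1, 5)), intercept=-2.0, theta=20.0)


def test_gvs_sampler_deterministic(tiny_toy_fixture):
    truth = tiny_toy_fixture.truth
    gm = GlobalModel(tiny_toy_fixture.surveys, tiny_toy_fixture.design,
                     include_trend=False,
                     fixed_intercept=truth["fixed_intercept"],
                     fixed_theta=truth["fixed_theta"])
    kwargs = dict(chains=2, iterations=1200, burnin=200, thin=1, seed=9,
                  pilot_iterations=400, pilot_burnin=150)
    a = gm.sample(**kwargs)
    b = gm.sample(**kwargs)
    assert np.array_equal(a.get("indicators"), b.get("indicators"))
    assert np.array_equal(a.get("effects"), b.get("effects"))
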