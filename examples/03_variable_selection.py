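"""Gibbs variable selection over lagged climate terms on a dataset with one
planted effect (SOI at lag 2 in the southern GBR, standardized coefficient
-1), and the conditional partial effect of the recovered term.

Run:  python examples/03_variable_selection.py   (about two minutes)
"""

from calfclim.gvs import GlobalModel, TermSpec, inclusion_probabilities, partial_effects
from calfclim.simulate import PLANTED_TERM, make_fixture

bundle = make_fixture("single_strong_term", seed=7)
model = GlobalModel(bundle.surveys, bundle.design, bundle.basis,
                    registry=bundle.registry)
print(f"candidate terms: {model.n_terms} "
      f"(5 sub-regions x 4 drivers x 4 lags)")

chains = model.sample(chains=3, iterations=18_000, burnin=2_000, thin=2,
                      seed=7, pilot_iterations=2_000, pilot_burnin=800)

summary = inclusion_probabilities(chains)
top = summary.frame.sort_values("probability", ascending=False).head(5)
print("\ntop posterior inclusion probabilities:")
for _, row in top.iterrows():
    mark = " <- planted" if row.term == "southern_gbr:SOI_lag2" else ""
    print(f"  {row.term:<28} {row.probability:.3f}{mark}")

driver, lag, name = PLANTED_TERM
pe = partial_effects(chains, TermSpec(driver, lag, name))
print(f"\nplanted term {name}:{driver}_lag{lag}")
print(f"  inclusion probability : {pe.inclusion_probability:.3f}")
print(f"  effect per +1 sd      : {pe.median:.2f} [{pe.lower:.2f}, {pe.upper:.2f}]"
      f"  (true -1.0)")
print(f"  significant (CrI excludes 0): {pe.significant}")
print(f"  percent change of proportion: {pe.percent_effect_median:.1f}% "
      f"[{pe.percent_effect_lower:.1f}%, {pe.percent_effect_upper:.1f}%]")
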