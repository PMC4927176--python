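"""Fit the Beta-Binomial penalized-spline trend model and print the fitted
calf-proportion curves per sub-region.

Uses a moderate iteration budget so the example finishes in about a
minute; for final analyses use the reference settings (300,000 total
iterations, burn-in 50,000 per chain, thinning 10).

Run:  python examples/02_fit_trend.py
"""

import numpy as np

from calfclim.simulate import make_fixture
from calfclim.trend import TrendModel, trend_summary

bundle = make_fixture("table1_design_trend", seed=1)
model = TrendModel(bundle.surveys, bundle.basis, registry=bundle.registry)

chains = model.sample(chains=3, iterations=120_000, burnin=15_000, thin=5,
                      seed=42, iterations_are_total=True)
print(f"chains: {chains.n_chains} x {chains.n_draws} retained draws")
print(f"max PSRF: {chains.meta['max_psrf']:.4f}  (warnings: {chains.warnings})")
print(f"posterior median theta: {float(np.median(chains.pooled('theta'))):.1f}")

summary = trend_summary(chains, bundle.basis, bundle.surveys,
                        years=[1975, 1985, 1995, 2005, 2013])
print()
print("fitted calf proportion (median [2.5%, 97.5%]):")
for _, row in summary.iterrows():
    print(f"  {row.subregion:<14} {row.year}  {row['median']:.3f} "
          f"[{row.lower:.3f}, {row.upper:.3f}]")
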