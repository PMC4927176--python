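"""Generate a synthetic survey bundle and run the dispersion screening.

Run:  python examples/01_simulate_and_screen.py
"""

from calfclim import check_dispersion
from calfclim.simulate import make_fixture

bundle = make_fixture("table1_design_trend", seed=1)
surveys = bundle.surveys

print(f"fixture: {bundle.name}")
print(f"records: {len(surveys)} across {sorted(set(surveys.subregions))}")
p = surveys.proportions()
print(f"calf proportions: mean {p.mean():.3f}, range "
      f"[{p.min():.3f}, {p.max():.3f}]")

report = check_dispersion(surveys, seed=2)
print()
print("dispersion screening vs the null Binomial:")
print(f"  pooled proportion    {report.pooled_proportion:.4f}")
print(f"  Pearson ratio        {report.pearson_ratio:.2f}  "
      f"(1.0 = Binomial variance)")
print(f"  bootstrap p-value    {report.overdispersion_pvalue:.4f}")
print(f"  overdispersed        {report.overdispersed}")
print(f"  zero fraction        observed {report.observed_zero_fraction:.3f} "
      f"vs expected {report.expected_zero_fraction:.3f}")
print(f"  zero-inflated        {report.zero_inflated}")
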