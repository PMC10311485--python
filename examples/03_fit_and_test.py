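"""Fit the full model by FIML and test the two assortment mechanisms.

Simulates a cohort-sized dataset at the Finnish estimates, fits the full
A-S-E model with both copaths, the three nested submodels, and reports the
likelihood-ratio tests and the recovered decomposition with a profile
confidence interval for the phenotypic-assortment copath.
"""

import twinspouse as ts
from twinspouse.fitting import GroupedFamilies, ModelSpec, fit_model, lrt, profile_ci

table = ts.simulate_families(
    ts.SimulationDesign.from_counts(
        ts.preset_counts("finland"), ts.FINLAND, seed=5, total=2403
    )
)
grouped = GroupedFamilies(table)
spec = ModelSpec.full()
full = fit_model(spec, grouped, starts=3, seed=5)
print(full.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}"))

for name, drop in (
    ("no phenotypic assortment", ("delta_p",)),
    ("no social homogamy", ("delta_y",)),
    ("no assortment at all", ("delta_p", "delta_y")),
):
    sub = fit_model(spec.drop(*drop), grouped, starts=3, seed=5)
    res = lrt(full, sub)
    verdict = "rejected" if res.significant() else "not rejected"
    print(f"{name}: chi2({res.df}) = {res.statistic:.2f}, p = {res.p_value:.2g} "
          f"-> {verdict} at alpha 0.05")

d = ts.decompose(full.estimates)
print(f"\nrecovered: h2={d.h2:.2f} s2={d.s2:.2f} e2={d.e2:.2f}; spousal "
      f"correlation {d.mu_spouse:.2f} = {d.part_phenotypic:.2f} + {d.part_social:.2f}")
ci = profile_ci(spec, grouped, "delta_p", fit=full, seed=5)
print(f"profile 95% CI for delta_p: ({ci.lower:.3f}, {ci.upper:.3f})")
print("\nBoth mechanisms are needed: dropping either copath significantly "
      "worsens the fit at cohort sample sizes.")
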