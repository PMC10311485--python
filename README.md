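# twinspouse

Structural modelling of **assortative mating** in twin–spouse family data:
does spousal resemblance for a heritable trait (years of education) arise
from **phenotypic assortment** — choosing a partner on the trait itself — or
from **social homogamy** — choosing a partner from the same social stratum?
The two mechanisms predict the same spousal correlation but different
genetic consequences, and they can be separated with data on monozygotic
(MZ) and dizygotic (DZ) twins *and their spouses*.

The package is aimed at behaviour-genetics and social-science researchers
working with twin-family designs. It provides the model-implied moments,
full-information maximum-likelihood (FIML) estimation over arbitrary
missing-spouse configurations, likelihood-ratio tests, profile confidence
intervals, identifiability diagnostics, Monte-Carlo power, descriptive
correlation diagnostics, education-level harmonization, and a synthetic
cohort generator (cohort micro-data are access-restricted, so synthetic
families stand in for them everywhere).

## The model

Each member of a family quartet (twin 1, spouse 1, twin 2, spouse 2) has a
phenotype decomposed as

    P = a·A + s·S + e·E,          V = a² + s² + e²

with additive-genetic **A**, social-background **S** (absorbing the
classical twin shared environment) and unique-environment **E** factors.
Twins share S fully; their genetic correlation is 1 (MZ) or
α = ½(1 + Δp) (DZ, inflated above ½ by equilibrium assortment).  Two
*copaths* connect spouses to the family:

* **Δp** — phenotypic assortment, a direct copath between the phenotypes of
  each twin and their own spouse;
* **Δy** — social homogamy: the in-marrying spouses' strata correlate Δy
  with the twin family's stratum (and with each other).  As a copath it is
  not bounded by 1.

The standardized implied correlations (h² = a²/V, s² = s²/V):

| entry | value |
|---|---|
| twin–twin | α·h² + s² |
| twin–own spouse (r1) | Δp + s²·Δy |
| cotwin–spouse (r2) | Δp·(α·h² + s²) + s²·Δy |
| spouse–spouse (r3) | Δp²·(α·h² + s²) + 2·Δp·s²·Δy + s²·Δy |

Pure phenotypic assortment (Δy = 0) gives the strict descent r1 > r2 > r3;
pure social homogamy (Δp = 0) equalizes all three. Sex enters the means
only (μ plus β for women). The spousal correlation decomposes exactly as
r1 = Δp + s²·Δy — the two mechanisms' contributions.

## Worked example

```python
import twinspouse as ts

# country presets carry the published variance proportions and copaths
d = ts.decompose(ts.FINLAND)
print(f"{d.mu_spouse:.2f} = {d.part_phenotypic:.2f} + {d.part_social:.2f}")
# 0.51 = 0.35 + 0.16

# simulate a cohort-sized synthetic dataset and re-fit it
table = ts.simulate_families(ts.SimulationDesign.quartets(5000, ts.FINLAND, seed=1))
fit = ts.fit_model(ts.ModelSpec.full(), table, starts=3, seed=1)
print(ts.decompose(fit.estimates).h2, fit.estimates.delta_p, fit.estimates.beta_sex)
# 0.52  0.342  0.634   (generating values 0.55, 0.35, 0.64)
```

The first block reproduces the published decomposition: a spousal
correlation of 0.51 in Finland, of which 0.35 comes from direct phenotypic
assortment and 0.16 (= 0.392²·1.03) from social homogamy.  The second block
shows parameter recovery: FIML on 15,000 simulated quartet families returns
the generating heritability, copath and sex effect to within sampling error.

The `examples/` directory holds one narrative script per capability
(decomposition, simulation + descriptives, fitting + LRTs + profile CIs,
the agent-based mate-choice oracle, Monte-Carlo power), and the
`twinspouse` CLI exposes `simulate`, `harmonize`, `describe`, `fit`,
`power` and `run-all` verbs over YAML configurations.

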