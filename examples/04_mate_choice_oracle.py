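"""Mechanistic mate-choice simulation: the two mechanisms from first
principles.

Agents carry explicit genetic (A), social-background (S) and unique (E)
components; spouses are matched on a weighted similarity score.  Matching on
the phenotype orders the correlations r1 > r2 > r3 and, iterated over
generations, pushes the full-sib genetic correlation above 0.5 while the
genetic variance rises to an equilibrium plateau.  Matching on the social
stratum alone makes the three spousal correlations (nearly) equal.
"""

import twinspouse as ts

params = ts.ParameterSet.from_proportions(0.5, 0.3, 0.2)

pheno = ts.mate_choice_oracle(
    params, n_couples=6000, weights=(1.0, 0.0), generations=1, seed=3, noise_sd=1.0
)
print("phenotype matching:  "
      f"r1={pheno.r1:.3f}  r2={pheno.r2:.3f}  r3={pheno.r3:.3f}  (strict descent)")

strat = ts.mate_choice_oracle(
    params, n_couples=6000, weights=(0.0, 1.0), generations=1, seed=3, noise_sd=0.05
)
print("stratum matching:    "
      f"r1={strat.r1:.3f}  r2={strat.r2:.3f}  r3={strat.r3:.3f}  (near-equal)")

long = ts.mate_choice_oracle(
    params, n_couples=6000, weights=(1.0, 0.0), generations=30, seed=3, noise_sd=1.0
)
print(f"\nafter 30 generations of phenotypic assortment:")
print(f"  full-sib genetic correlation {long.sib_genetic_corr[-1]:.3f} (random mating: 0.5)")
print(f"  genetic variance {long.genetic_variance[0]:.3f} -> "
      f"{long.genetic_variance[-1]:.3f}, plateaued: {long.variance_plateaued}")
print("\nThese are the genetic consequences that distinguish the mechanisms: "
      "only phenotype-based choice changes the genetic structure.")
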