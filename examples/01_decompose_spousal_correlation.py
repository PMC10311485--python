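"""Split the implied spousal correlation into its two mechanisms.

Builds the model-implied twin-spouse quartet moments at the Finnish and
Dutch cohort estimates and decomposes the spousal correlation into the
phenotypic-assortment part (the copath delta_p itself) and the
social-homogamy part (s^2 * delta_y).
"""

import twinspouse as ts

for name, params in (("Finland", ts.FINLAND), ("Netherlands", ts.NETHERLANDS)):
    d = ts.decompose(params)
    rr = ts.implied_correlations(params, "MZ")
    print(f"{name}:")
    print(f"  variance proportions  h2={d.h2:.2f}  s2={d.s2:.2f}  e2={d.e2:.2f}")
    print(
        f"  spousal correlation {d.mu_spouse:.2f} = "
        f"phenotypic assortment {d.part_phenotypic:.2f} "
        f"+ social homogamy {d.part_social:.2f}"
    )
    print(
        f"  implied quartet entries: twin-twin(MZ)={rr['r_tw']:.2f} "
        f"r1={rr['r1']:.2f} r2={rr['r2']:.2f} r3={rr['r3']:.2f}"
    )

print(
    "\nIn both countries the direct phenotype copath contributes about twice "
    "as much spousal resemblance as shared social background."
)
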