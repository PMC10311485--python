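"""Simulate a synthetic cohort and inspect the diagnostic correlations.

Draws a family table with the cohort's zygosity-by-configuration mix at the
Finnish estimates, then computes the twin-twin and three spousal
correlations with double entry and labels the rank-order pattern.
"""

import twinspouse as ts

design = ts.SimulationDesign.from_counts(
    ts.preset_counts("finland"), ts.FINLAND, seed=11, total=2403
)
table = ts.simulate_families(design)
print(f"simulated {design.n_families} families "
      f"({table['twin2_years'].notna().sum()} with both twins)")

cs = ts.pairwise_correlations(table)
print(cs.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("rank-order labels:", ts.rank_order_diagnostic(cs))
print(
    "\nr1 > r2 with r3 not far below r2 is the signature of mixed assortment:\n"
    "a direct phenotype copath plus shared social background. Raw correlations\n"
    "sit slightly below the sex-adjusted model-implied values because spouses\n"
    "are opposite-sex and women average more schooling."
)
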