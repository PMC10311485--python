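"""Country presets: fitted parameter values and family-configuration counts.

The variance proportions, copaths and sex effects are the published cohort
estimates; the raw mean and variance set the years-of-education scale the
synthetic cohorts are generated on (grand means near 13 years, SDs near
2.2-2.4 years, matching the cohort descriptives).  All scale-free quantities
(proportions, copaths) are unaffected by the raw-scale choice.
"""

from __future__ import annotations

from types import MappingProxyType

from .model import ParameterSet

__all__ = [
    "FINLAND",
    "NETHERLANDS",
    "FINLAND_FAMILY_COUNTS",
    "NETHERLANDS_FAMILY_COUNTS",
    "preset_parameters",
    "preset_counts",
]

#: Finnish cohort: h2=0.55, s2=0.16, e2=0.29, delta_p=0.35, delta_y=1.03,
#: sex effect 0.64 years favouring women; raw scale mu=13.1 y, SD 2.4 y.
FINLAND = ParameterSet.from_proportions(
    0.55, 0.16, 0.29, variance=2.4**2, delta_p=0.35, delta_y=1.03,
    beta_sex=0.64, mu=13.1,
)

#: Dutch cohort: h2=0.66, s2=0.13, e2=0.21, delta_p=0.30, delta_y=1.18,
#: sex effect 0.20 years; raw scale mu=13.5 y, SD 2.1 y.
NETHERLANDS = ParameterSet.from_proportions(
    0.66, 0.13, 0.21, variance=2.1**2, delta_p=0.30, delta_y=1.18,
    beta_sex=0.20, mu=13.5,
)

# Families per zygosity x configuration, as collected in the two cohorts.
# Configuration keys follow twinspouse.model.CONFIGURATIONS.
FINLAND_FAMILY_COUNTS = MappingProxyType({
    ("MZ", "single_twin"): 133,
    ("MZ", "twin_spouse"): 64,
    ("MZ", "twin_pair"): 268,
    ("MZ", "pair_one_spouse"): 153,
    ("MZ", "quartet"): 128,
    ("SSDZ", "single_twin"): 182,
    ("SSDZ", "twin_spouse"): 97,
    ("SSDZ", "twin_pair"): 228,
    ("SSDZ", "pair_one_spouse"): 163,
    ("SSDZ", "quartet"): 109,
    ("OSDZ", "single_twin"): 224,
    ("OSDZ", "twin_spouse"): 138,
    ("OSDZ", "twin_pair"): 245,
    ("OSDZ", "pair_one_spouse"): 179,
    ("OSDZ", "quartet"): 92,
})

NETHERLANDS_FAMILY_COUNTS = MappingProxyType({
    ("MZ", "single_twin"): 378,
    ("MZ", "twin_spouse"): 259,
    ("MZ", "twin_pair"): 263,
    ("MZ", "pair_one_spouse"): 214,
    ("MZ", "quartet"): 156,
    ("SSDZ", "single_twin"): 277,
    ("SSDZ", "twin_spouse"): 183,
    ("SSDZ", "twin_pair"): 105,
    ("SSDZ", "pair_one_spouse"): 119,
    ("SSDZ", "quartet"): 86,
    ("OSDZ", "single_twin"): 282,
    ("OSDZ", "twin_spouse"): 195,
    ("OSDZ", "twin_pair"): 66,
    ("OSDZ", "pair_one_spouse"): 76,
    ("OSDZ", "quartet"): 43,
})

_PARAMS = {"finland": FINLAND, "netherlands": NETHERLANDS}
_COUNTS = {"finland": FINLAND_FAMILY_COUNTS, "netherlands": NETHERLANDS_FAMILY_COUNTS}


def preset_parameters(name: str) -> ParameterSet:
    """Look up a country preset ('finland' or 'netherlands')."""
    try:
        return _PARAMS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PARAMS)}") from None


def preset_counts(name: str):
    """Family-configuration counts for a country preset."""
    try:
        return _COUNTS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_COUNTS)}") from None
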