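"""Shared fixtures.

The two expensive fixtures (the large Finnish-scale recovery fit and the
500-replicate null calibration) are session-scoped so that acceptance and
property tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import twinspouse as ts
from twinspouse.fitting import GroupedFamilies, ModelSpec, fit_model, lrt


@pytest.fixture(scope="session")
def finnish_params() -> ts.ParameterSet:
    return ts.FINLAND


@pytest.fixture(scope="session")
def dutch_params() -> ts.ParameterSet:
    return ts.NETHERLANDS


@pytest.fixture(scope="session")
def small_table():
    """600 families at the Finnish set with the cohort configuration mix."""
    design = ts.SimulationDesign.from_counts(
        ts.preset_counts("finland"), ts.FINLAND, seed=202, total=600
    )
    return ts.simulate_families(design)


@pytest.fixture(scope="session")
def recovery_fit(finnish_params):
    """Full-model FIML fit on 5,000 complete quartets per zygosity simulated
    at the Finnish estimates (parameter-recovery conditions)."""
    design = ts.SimulationDesign.quartets(5000, finnish_params, seed=20230614)
    table = ts.simulate_families(design)
    fit = fit_model(ModelSpec.full(), GroupedFamilies(table), starts=3, seed=1)
    return fit


@pytest.fixture(scope="session")
def null_lrt_pvalues():
    """P-values of the joint copath LRT over 500 replicates simulated under
    no assortment (delta_p = delta_y = 0) at the Finnish cohort design."""
    gen = ts.FINLAND.replace(delta_p=0.0, delta_y=0.0)
    counts = dict(ts.preset_counts("finland"))
    rng = np.random.default_rng(555)
    full_spec = ModelSpec.full()
    sub_spec = full_spec.drop("delta_p", "delta_y")
    pvals = []
    for _ in range(500):
        seed = int(rng.integers(0, 2**31 - 1))
        table = ts.simulate_families(ts.SimulationDesign(counts, gen, seed))
        grouped = GroupedFamilies(table)
        f_sub = fit_model(
            sub_spec, grouped, starts=1, seed=seed, start_values=gen, compute_se=False
        )
        f_full = fit_model(
            full_spec, grouped, starts=1, seed=seed,
            start_values=f_sub.estimates, compute_se=False,
        )
        pvals.append(lrt(f_full, f_sub).p_value)
    return np.array(pvals)
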