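"""Model-implied moments: closed forms, latent oracle, decompositions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinspouse as ts
from twinspouse.model import (
    QUARTET,
    TWIN_SPOUSE,
    AdmissibilityError,
    DegenerateModelError,
    FamilyConfiguration,
    latent_loadings,
)


@pytest.mark.parametrize(
    "delta_p, zygosity, expected",
    [
        (0.0, "SSDZ", 0.5),     # random mating
        (0.35, "SSDZ", 0.675),  # equilibrium inflation by assortment
        (1.0, "SSDZ", 1.0),     # boundary
        (0.35, "MZ", 1.0),      # MZ always share genotype fully
        (0.2, "OSDZ", 0.6),
    ],
)
def test_twin_genetic_correlation(delta_p, zygosity, expected):
    assert ts.dz_alpha(delta_p, zygosity) == pytest.approx(expected)


def _admissible_params(h2, s2, dp, dy):
    e2 = 1.0 - h2 - s2
    return ts.ParameterSet.from_proportions(h2, s2, e2, delta_p=dp, delta_y=dy)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    h2=st.floats(0.05, 0.8),
    s2_frac=st.floats(0.05, 0.9),
    dp=st.floats(-0.4, 0.7),
    dy=st.floats(-0.4, 0.9),
    zyg=st.sampled_from(["MZ", "SSDZ", "OSDZ"]),
)
def test_observed_moments_equal_latent_construction(h2, s2_frac, dp, dy, zyg):
    """On the latent-admissible region the closed-form quartet covariance
    equals the loading-propagated latent covariance to 1e-10."""
    s2 = (1.0 - h2) * s2_frac * 0.9
    params = _admissible_params(h2, s2, dp, dy)
    try:
        sigma = ts.implied_latent_covariance(params, zyg)
    except AdmissibilityError:
        return  # outside the admissible region: nothing to compare
    lam = latent_loadings(params)
    implied = ts.implied_observed_moments(params, zyg, standardized=True)
    np.testing.assert_allclose(lam @ sigma @ lam.T, implied.cov, atol=1e-10)


def test_derived_dz_quartet_matches_latent_oracle():
    """Spot check of all 10 unique entries at a fixed DZ parameter set."""
    params = ts.ParameterSet.from_proportions(0.5, 0.2, 0.3, delta_p=0.2, delta_y=0.5)
    sigma = ts.implied_latent_covariance(params, "SSDZ")
    lam = latent_loadings(params)
    implied = ts.implied_observed_moments(params, "SSDZ", standardized=True)
    np.testing.assert_allclose(lam @ sigma @ lam.T, implied.cov, atol=1e-10)
    # and the closed-form entries are where they should be
    rr = ts.implied_correlations(params, "SSDZ")
    assert implied.cov[0, 2] == pytest.approx(rr["r_tw"])
    assert implied.cov[0, 1] == pytest.approx(rr["r1"])
    assert implied.cov[0, 3] == pytest.approx(rr["r2"])
    assert implied.cov[1, 3] == pytest.approx(rr["r3"])


def test_no_assortment_decouples_spouses():
    params = ts.ParameterSet.from_proportions(0.5, 0.2, 0.3)
    rr = ts.implied_correlations(params, "MZ")
    assert rr["r1"] == rr["r2"] == rr["r3"] == 0.0
    assert rr["r_tw"] == pytest.approx(0.7)
    sigma = ts.implied_latent_covariance(params, "MZ")
    # spouses' components independent of the twin family
    assert np.abs(sigma[0:3, 3:6]).max() == 0.0
    assert np.abs(sigma[3:6, 6:9]).max() == 0.0


def test_implied_spousal_correlation_matches_published_estimates(
    finnish_params, dutch_params
):
    r1_fi = ts.implied_correlations(finnish_params, "MZ")["r1"]
    r1_nl = ts.implied_correlations(dutch_params, "MZ")["r1"]
    assert round(r1_fi, 2) == 0.51
    assert round(r1_nl, 2) == 0.45


def test_homogamy_copath_above_one_is_latent_inadmissible_but_observed_ok(
    finnish_params,
):
    with pytest.raises(AdmissibilityError, match="delta_y"):
        ts.implied_latent_covariance(finnish_params, "MZ")
    # observed-level moments remain PSD with small s2
    mom = ts.implied_observed_moments(finnish_params, "MZ")
    assert np.linalg.eigvalsh(mom.cov).min() > 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    h2=st.floats(0.2, 0.7),
    dp=st.floats(0.0, 0.5),
    dy=st.floats(0.0, 0.9),
    bump=st.floats(0.01, 0.2),
)
def test_spousal_entry_monotone_in_both_copaths(h2, dp, dy, bump):
    s2 = 0.3 * (1.0 - h2)
    base = _admissible_params(h2, s2, dp, dy)
    r1 = ts.implied_correlations(base, "SSDZ")["r1"]
    up_p = ts.implied_correlations(base.replace(delta_p=dp + bump), "SSDZ")["r1"]
    up_y = ts.implied_correlations(base.replace(delta_y=dy + bump), "SSDZ")["r1"]
    assert up_p > r1
    assert up_y > r1  # s > 0 here


@settings(max_examples=60, deadline=None, derandomize=True)
@given(h2=st.floats(0.1, 0.7), dp=st.floats(0.05, 0.6), dy=st.floats(0.05, 0.95))
def test_rank_order_predictions(h2, dp, dy):
    """Pure phenotypic assortment orders r1 > r2 > r3; pure social homogamy
    equalizes the three spousal correlations."""
    s2 = 0.4 * (1.0 - h2)
    pheno = ts.implied_correlations(_admissible_params(h2, s2, dp, 0.0), "SSDZ")
    assert pheno["r1"] > pheno["r2"] > pheno["r3"]
    soc = ts.implied_correlations(_admissible_params(h2, s2, 0.0, dy), "SSDZ")
    assert soc["r1"] == pytest.approx(soc["r2"], abs=1e-12)
    assert soc["r2"] == pytest.approx(soc["r3"], abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(h2=st.floats(0.1, 0.8), dp=st.floats(-0.3, 0.95), dy=st.floats(-0.3, 0.9))
def test_mz_twin_correlation_dominates_dz(h2, dp, dy):
    s2 = 0.5 * (1.0 - h2)
    p = _admissible_params(h2, s2, dp, dy)
    assert (
        ts.implied_correlations(p, "MZ")["r_tw"]
        >= ts.implied_correlations(p, "SSDZ")["r_tw"]
    )


@pytest.mark.parametrize(
    "s_path, dy, expected",
    [(0.392, 1.03, 0.16), (0.362, 1.18, 0.15)],
)
def test_social_homogamy_contribution_worked_examples(s_path, dy, expected):
    """The published worked products s^2 * delta_y on the standardized scale."""
    e2 = 1.0 - 0.5 - s_path**2
    params = ts.ParameterSet.from_proportions(0.5, s_path**2, e2, delta_y=dy)
    assert round(ts.decompose(params).part_social, 2) == expected


def test_decomposition_identities(finnish_params):
    d = ts.decompose(finnish_params)
    assert d.h2 + d.s2 + d.e2 == pytest.approx(1.0, abs=1e-10)
    assert d.mu_spouse == d.part_phenotypic + d.part_social
    nod = ts.decompose(finnish_params.replace(delta_y=0.0))
    assert nod.part_social == 0.0
    assert nod.mu_spouse == finnish_params.delta_p


def test_degenerate_variance_raises():
    flat = ts.ParameterSet(0.0, 0.0, 0.0)
    with pytest.raises(DegenerateModelError):
        ts.decompose(flat)
    with pytest.raises(DegenerateModelError):
        ts.implied_observed_moments(flat, "MZ")


def test_configuration_restriction_and_sex_means(finnish_params):
    mom = ts.implied_observed_moments(
        finnish_params, "MZ", TWIN_SPOUSE, sexes={"twin1": "F", "spouse1": "M"}
    )
    assert mom.cov.shape == (2, 2)
    assert mom.mean[0] == pytest.approx(finnish_params.mu + finnish_params.beta_sex)
    assert mom.mean[1] == pytest.approx(finnish_params.mu)
    full = ts.implied_observed_moments(finnish_params, "MZ", QUARTET)
    np.testing.assert_allclose(mom.cov, full.cov[:2, :2])


def test_configuration_validation():
    with pytest.raises(ValueError, match="twin1"):
        FamilyConfiguration(("spouse1",))
    with pytest.raises(ValueError, match="unknown"):
        FamilyConfiguration(("twin1", "uncle"))
    # canonical ordering is enforced
    cfg = FamilyConfiguration(("twin2", "twin1"))
    assert cfg.roles_observed == ("twin1", "twin2")
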