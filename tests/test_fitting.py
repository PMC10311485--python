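"""FIML estimation, likelihood-ratio tests, profiling, identifiability."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinspouse as ts
from twinspouse.fitting import (
    FitError,
    GroupedFamilies,
    ModelSpec,
    fiml_loglik,
    fit_model,
    identifiability_check,
    lrt,
    power_by_simulation,
    profile_ci,
)


def _quartet_table(params, n, seed):
    return ts.simulate_families(ts.SimulationDesign.quartets(n, params, seed))


class TestLoglik:
    def test_complete_quartets_match_direct_density_sum(self, finnish_params):
        """FIML on complete data is the plain sum of 4-variate normal
        log-densities (independent oracle via scipy)."""
        table = _quartet_table(finnish_params, 40, seed=5)
        ll = fiml_loglik(finnish_params, table)
        direct = 0.0
        for _, row in table.iterrows():
            y = np.array([row[f"{r}_years"] for r in ts.ROLES])
            fem = np.array(
                [1.0 if row[f"{r}_sex"] == "F" else 0.0 for r in ts.ROLES]
            )
            mom = ts.implied_observed_moments(finnish_params, row["zygosity"])
            direct += stats.multivariate_normal(
                mean=mom.mean + finnish_params.beta_sex * fem, cov=mom.cov
            ).logpdf(y)
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_missing_spouse_contributes_marginal_density(self, finnish_params):
        table = _quartet_table(finnish_params, 10, seed=6)
        masked = table.copy()
        masked["spouse2_years"] = np.nan
        ll = fiml_loglik(finnish_params, masked)
        direct = 0.0
        for _, row in masked.iterrows():
            y = np.array([row[f"{r}_years"] for r in ts.ROLES[:3]])
            fem = np.array(
                [1.0 if row[f"{r}_sex"] == "F" else 0.0 for r in ts.ROLES[:3]]
            )
            mom = ts.implied_observed_moments(finnish_params, row["zygosity"])
            direct += stats.multivariate_normal(
                mean=mom.mean[:3] + finnish_params.beta_sex * fem, cov=mom.cov[:3, :3]
            ).logpdf(y)
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_single_twin_at_its_mean_with_unit_variance(self):
        params = ts.ParameterSet.from_proportions(0.5, 0.2, 0.3, mu=12.0)
        table = pd.DataFrame(
            {
                "family_id": [0],
                "zygosity": ["MZ"],
                "twin1_sex": ["M"],
                "twin1_years": [12.0],
            }
        )
        assert fiml_loglik(params, table) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            GroupedFamilies(pd.DataFrame(columns=["zygosity", "twin1_years"]))

    def test_nonpsd_parameters_get_finite_penalty(self, small_table):
        wild = ts.ParameterSet.from_proportions(
            0.1, 0.8, 0.1, delta_p=0.9, delta_y=1.4, mu=13.0
        )
        ll = fiml_loglik(wild, small_table)
        assert math.isfinite(ll) and ll < -1e10


class TestFit:
    def test_constant_phenotype_is_degenerate(self):
        table = pd.DataFrame(
            {
                "family_id": range(5),
                "zygosity": ["MZ"] * 5,
                "twin1_sex": ["M"] * 5,
                "twin1_years": [12.0] * 5,
            }
        )
        with pytest.raises(FitError, match="degenerate"):
            fit_model(ModelSpec.full(), table, starts=1, seed=0)

    def test_full_model_dominates_nested(self, small_table):
        grouped = GroupedFamilies(small_table)
        full = fit_model(ModelSpec.full(), grouped, starts=2, seed=0)
        for dropped in (("delta_p",), ("delta_y",), ("delta_p", "delta_y")):
            sub = fit_model(
                ModelSpec.full().drop(*dropped), grouped, starts=2, seed=0
            )
            assert full.loglik >= sub.loglik - 1e-6

    def test_lrt_invariant_to_affine_phenotype_transform(self, small_table):
        grouped = GroupedFamilies(small_table)
        shifted = small_table.copy()
        for r in ts.ROLES:
            shifted[f"{r}_years"] = 2.5 * shifted[f"{r}_years"] - 7.0
        g2 = GroupedFamilies(shifted)
        spec = ModelSpec.full()
        sub = spec.drop("delta_p")
        s1 = lrt(
            fit_model(spec, grouped, starts=2, seed=3),
            fit_model(sub, grouped, starts=2, seed=3),
        ).statistic
        s2 = lrt(
            fit_model(spec, g2, starts=2, seed=3),
            fit_model(sub, g2, starts=2, seed=3),
        ).statistic
        assert s1 == pytest.approx(s2, abs=0.02)

    def test_parameter_recovery_at_cohort_estimates(self, recovery_fit, finnish_params):
        """With 5,000 quartets per zygosity every standardized estimate sits
        within 3 Monte-Carlo SEs of its generating value."""
        est = recovery_fit.estimates
        assert recovery_fit.converged
        truth = ts.decompose(finnish_params)
        fitted = ts.decompose(est)
        for name, true_val in (
            ("delta_p", finnish_params.delta_p),
            ("delta_y", finnish_params.delta_y),
            ("beta_sex", finnish_params.beta_sex),
            ("mu", finnish_params.mu),
        ):
            se = recovery_fit.se[name]
            assert abs(est.as_dict()[name] - true_val) < 3 * se, name
        for prop, true_val in (("h2", truth.h2), ("s2", truth.s2), ("e2", truth.e2)):
            se = recovery_fit.se_of(lambda p, q=prop: getattr(ts.decompose(p), q))
            assert abs(getattr(fitted, prop) - true_val) < 3 * se, prop


class TestLRT:
    def test_identical_logliks_give_zero_statistic(self, small_table):
        from twinspouse.fitting import FitResult

        g = GroupedFamilies(small_table)
        sub = fit_model(
            ModelSpec.full().drop("delta_p"), g, starts=1, seed=0, compute_se=False
        )
        full_same = FitResult(
            spec=ModelSpec.full(),
            estimates=sub.estimates,
            loglik=sub.loglik,
            n_params=7,
            converged=True,
            n_families=sub.n_families,
            se={},
            ci={},
        )
        res = lrt(full_same, sub)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi_square_reference_identities(self, small_table):
        g = GroupedFamilies(small_table)
        spec = ModelSpec.full()
        full = fit_model(spec, g, starts=1, seed=0, compute_se=False)
        sub = fit_model(spec.drop("delta_p"), g, starts=1, seed=0, compute_se=False)
        res = lrt(full, sub)
        assert res.df == 1
        assert res.statistic >= -1e-6
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(max(res.statistic, 0), 1))
        )
        both = lrt(full, fit_model(spec.drop("delta_p", "delta_y"), g, starts=1,
                                   seed=0, compute_se=False))
        assert both.df == 2
        # the canonical quantile identity
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_specs_rejected(self, small_table):
        g = GroupedFamilies(small_table)
        a = fit_model(ModelSpec.full().drop("delta_p"), g, starts=1, seed=0,
                      compute_se=False)
        b = fit_model(ModelSpec.full().drop("delta_y"), g, starts=1, seed=0,
                      compute_se=False)
        with pytest.raises(ValueError, match="not nested"):
            lrt(a, b)

    def test_null_pvalues_approximately_uniform(self, null_lrt_pvalues):
        """Under no-assortment truth the LRT p-values are close to uniform
        (Kolmogorov distance below 0.1 at 500 replicates)."""
        ks = stats.kstest(null_lrt_pvalues, "uniform").statistic
        assert ks < 0.1


class TestProfile:
    def test_endpoints_sit_at_the_chi_square_threshold(self, small_table):
        g = GroupedFamilies(small_table)
        spec = ModelSpec.full()
        fit = fit_model(spec, g, starts=2, seed=4)
        ci = profile_ci(spec, g, "delta_p", fit=fit, seed=4)
        assert ci.lower < fit.estimates.delta_p < ci.upper
        for endpoint, is_open in ((ci.lower, ci.lower_open), (ci.upper, ci.upper_open)):
            if is_open:
                continue
            sub = ModelSpec(
                free=tuple(p for p in spec.free if p != "delta_p"),
                fixed={"delta_p": endpoint},
            )
            prof = fit_model(sub, g, starts=2, seed=4, compute_se=False)
            assert 2.0 * (fit.loglik - prof.loglik) == pytest.approx(3.841, abs=1e-2)

    def test_fixed_parameter_cannot_be_profiled(self, small_table):
        g = GroupedFamilies(small_table)
        spec = ModelSpec.full().drop("delta_y")
        with pytest.raises(ValueError, match="fixed"):
            profile_ci(spec, g, "delta_y", seed=0)


class TestIdentifiability:
    POINT = dict(a=1.78, s=0.96, e=1.29, delta_p=0.35, delta_y=1.03,
                 beta_sex=0.64, mu=13.1)

    def test_base_model_with_both_copaths_is_full_rank(self):
        rep = identifiability_check(ModelSpec.full(), self.POINT)
        assert rep.full_rank
        assert rep.rank == 7

    def test_separate_shared_environment_is_rank_deficient(self):
        point = dict(self.POINT, s=0.68, c=0.68)
        rep = identifiability_check(
            ("a", "c", "s", "e", "delta_p", "delta_y", "beta_sex", "mu"), point
        )
        assert not rep.full_rank
        assert rep.rank == 7  # one null direction: the c/s trade-off
        null = dict(zip(rep.parameters, rep.null_directions[0]))
        assert abs(null["c"]) > 1e-3 and abs(null["s"]) > 1e-3

    def test_homogamy_copath_unidentified_without_social_variance(self):
        point = dict(self.POINT, s=0.0)
        rep = identifiability_check(
            ("a", "e", "delta_p", "delta_y", "beta_sex", "mu"), point
        )
        assert rep.rank == 5
        null = dict(zip(rep.parameters, rep.null_directions[0]))
        assert abs(null["delta_y"]) == pytest.approx(1.0, abs=1e-6)


class TestPower:
    def test_alpha_one_rejects_always(self, finnish_params):
        counts = {("MZ", "quartet"): 40, ("SSDZ", "quartet"): 40, ("OSDZ", "quartet"): 40}
        res = power_by_simulation(
            finnish_params, counts, alpha=1.0, reps=3, seed=9, tests=("delta_p",)
        )
        assert res["power"].iloc[0] == 1.0

    def test_zero_reps_rejected(self, finnish_params):
        with pytest.raises(ValueError, match="reps"):
            power_by_simulation(finnish_params, {("MZ", "quartet"): 10}, reps=0)

    def test_power_increases_with_family_count(self, finnish_params):
        small = ts.SimulationDesign.from_counts(
            ts.preset_counts("finland"), finnish_params, 0, total=60
        ).counts
        large = ts.SimulationDesign.from_counts(
            ts.preset_counts("finland"), finnish_params, 0, total=900
        ).counts
        p_small = power_by_simulation(
            finnish_params, small, reps=40, seed=12, tests=("both",)
        )["power"].iloc[0]
        p_large = power_by_simulation(
            finnish_params, large, reps=40, seed=12, tests=("both",)
        )["power"].iloc[0]
        assert p_large > p_small
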