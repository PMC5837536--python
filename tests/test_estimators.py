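import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm

from ivbalance import (
    DegenerateInstrumentError,
    first_stage,
    iv_bias_component,
    ols_bias_component,
    wald_estimate,
)
from ivbalance.estimators import _slope_fit

from conftest import make_cohort, random_cohort


def group_mean_diff(values, arm):
    """Brute-force oracle: mean difference of values across a binary arm."""
    values, arm = np.asarray(values, dtype=float), np.asarray(arm, dtype=float)
    return values[arm == 1].mean() - values[arm == 0].mean()


class TestWaldEstimate:
    def test_equals_ratio_of_subsample_mean_differences(self):
        # ybar1=0.3, ybar0=0.2, xbar1=0.6, xbar0=0.2 -> psi = 0.1/0.4 = 0.25
        cohort = make_cohort(
            x=[1, 1, 1, 0, 0, 1, 0, 0, 0, 0],
            z=[1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            y=[0.5, 0.4, 0.3, 0.2, 0.1, 0.6, 0.2, 0.1, 0.1, 0.0],
            c=np.zeros(10) + np.arange(10) * 0.1,
        )
        z, x, y = cohort.instrument, cohort.exposure, cohort.column("y")
        psi = group_mean_diff(y, z) / group_mean_diff(x, z)
        est = wald_estimate(cohort, "y")
        assert est.estimate == pytest.approx(psi, abs=1e-12)

    def test_zero_numerator_gives_zero_estimate(self):
        cohort = make_cohort(x=[1, 1, 0, 0, 1, 0], z=[1, 1, 1, 0, 0, 0],
                             y=[1.0, 2.0, 3.0, 3.0, 2.0, 1.0],
                             c=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        z, y = cohort.instrument, cohort.column("y")
        assert group_mean_diff(y, z) == 0.0
        assert wald_estimate(cohort, "y").estimate == pytest.approx(0.0, abs=1e-12)

    def test_zero_first_stage_raises(self):
        cohort = make_cohort(x=[1, 0, 1, 0], z=[1, 1, 0, 0],
                             y=[1.0, 2.0, 3.0, 4.0], c=[0.1, 0.2, 0.3, 0.4])
        with pytest.raises(DegenerateInstrumentError):
            wald_estimate(cohort, "y")

    def test_ci_symmetric_with_normal_quantile_width(self, rng):
        cohort = random_cohort(rng, n=120)
        est = wald_estimate(cohort, "y", level=0.95)
        z975 = stats.norm.ppf(0.975)
        assert est.ci_high - est.ci_low == pytest.approx(2 * z975 * est.se, rel=1e-12)
        assert est.ci_low <= est.estimate <= est.ci_high


class TestBiasComponents:
    def test_ols_component_is_covariate_mean_difference(self):
        # C means 0.5 exposed vs 0.3 unexposed -> 0.2
        cohort = make_cohort(x=[1, 1, 0, 0], z=[1, 0, 1, 0],
                             y=[1.0, 1.0, 0.0, 0.0], c=[0.6, 0.4, 0.35, 0.25])
        est = ols_bias_component(cohort, "c")
        assert est.estimate == pytest.approx(0.2, abs=1e-12)

    def test_ols_component_zero_when_balanced(self):
        cohort = make_cohort(x=[1, 1, 0, 0], z=[1, 0, 1, 0],
                             y=[1.0, 1.0, 0.0, 0.0], c=[0.3, 0.5, 0.4, 0.4])
        assert ols_bias_component(cohort, "c").estimate == pytest.approx(0.0, abs=1e-12)

    def test_iv_component_is_wald_ratio_of_group_means(self):
        # C diff across Z = 0.02, X diff across Z = 0.4 -> 0.05
        cohort = make_cohort(
            x=[1, 1, 1, 0, 0, 1, 0, 0, 0, 0],
            z=[1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            y=np.arange(10, dtype=float),
            c=[0.30, 0.28, 0.26, 0.24, 0.22, 0.30, 0.26, 0.24, 0.22, 0.18],
        )
        z, x, c = cohort.instrument, cohort.exposure, cohort.column("c")
        expected = group_mean_diff(c, z) / group_mean_diff(x, z)
        assert expected == pytest.approx(0.05, abs=1e-12)
        assert iv_bias_component(cohort, "c").estimate == pytest.approx(expected, abs=1e-12)

    def test_components_coincide_when_instrument_equals_exposure(self, rng):
        x = (rng.random(40) < 0.5).astype(float)
        x[:2] = [0, 1]
        cohort = make_cohort(x=x, z=x, y=rng.standard_normal(40),
                             c=rng.standard_normal(40), doc=rng.integers(0, 5, 40))
        o = ols_bias_component(cohort, "c")
        i = iv_bias_component(cohort, "c")
        assert i.estimate == pytest.approx(o.estimate, abs=1e-12)
        assert i.se == pytest.approx(o.se, abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_random_tables_match_group_mean_oracles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        cohort = random_cohort(rng)
        z, x, c = cohort.instrument, cohort.exposure, cohort.column("c")
        assert ols_bias_component(cohort, "c").estimate == pytest.approx(
            group_mean_diff(c, x), abs=1e-10)
        assert iv_bias_component(cohort, "c").estimate == pytest.approx(
            group_mean_diff(c, z) / group_mean_diff(x, z), abs=1e-10)

    def test_constant_covariate_flagged_degenerate(self):
        cohort = make_cohort(x=[1, 0, 1, 0], z=[1, 0, 0, 1],
                             y=[1.0, 2.0, 3.0, 4.0], c=[0.7, 0.7, 0.7, 0.7])
        for fn in (ols_bias_component, iv_bias_component):
            est = fn(cohort, "c")
            assert est.degenerate
            assert est.estimate == 0.0 and est.se == 0.0

    def test_wald_on_covariate_equals_iv_component(self, rng):
        cohort = random_cohort(rng)
        w = wald_estimate(cohort, "c")
        i = iv_bias_component(cohort, "c")
        assert w.estimate == pytest.approx(i.estimate, abs=1e-12)
        assert w.se == pytest.approx(i.se, abs=1e-12)


class TestFirstStage:
    def test_instrument_identical_to_exposure_gives_unit_risk_difference(self):
        x = [1, 0, 1, 0, 1, 0]
        cohort = make_cohort(x=x, z=x, y=np.arange(6, dtype=float),
                             c=np.arange(6, dtype=float))
        fs = first_stage(cohort)
        assert fs.risk_difference.estimate == pytest.approx(1.0, abs=1e-12)

    def test_balanced_table_gives_zero_risk_difference(self):
        cohort = make_cohort(x=[1, 0, 1, 0], z=[1, 1, 0, 0],
                             y=[1.0, 2.0, 3.0, 4.0], c=[0.1, 0.2, 0.3, 0.4])
        fs = first_stage(cohort)
        assert fs.risk_difference.estimate == pytest.approx(0.0, abs=1e-12)

    def test_independent_instrument_small_partial_f(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = (rng.random(n) < 0.3).astype(float)
        z = (rng.random(n) < 0.2).astype(float)
        cohort = make_cohort(x=x, z=z, y=rng.standard_normal(n),
                             c=rng.standard_normal(n))
        fs = first_stage(cohort)
        # MC error of the risk difference is ~0.011 at this n
        assert abs(fs.risk_difference.estimate) < 0.033
        assert fs.partial_F < 10.0

    def test_partial_f_is_squared_t_ratio(self, rng):
        cohort = random_cohort(rng, n=200)
        fs = first_stage(cohort)
        t = fs.risk_difference.estimate / fs.risk_difference.se
        assert fs.partial_F == pytest.approx(t**2, rel=1e-12)


class TestInvariances:
    def test_row_order_invariance(self, rng):
        cohort = random_cohort(rng, n=60)
        perm = rng.permutation(60)
        shuffled = make_cohort(cohort.exposure[perm], cohort.instrument[perm],
                               cohort.column("y")[perm], cohort.column("c")[perm],
                               cohort.cluster[perm])
        for fn in (lambda co: ols_bias_component(co, "c"),
                   lambda co: iv_bias_component(co, "c"),
                   lambda co: wald_estimate(co, "y")):
            a, b = fn(cohort), fn(shuffled)
            assert b.estimate == pytest.approx(a.estimate, abs=1e-10)
            assert b.se == pytest.approx(a.se, abs=1e-10)

    def test_cluster_relabeling_invariance(self, rng):
        cohort = random_cohort(rng, n=60, n_clusters=6)
        relabeled = make_cohort(cohort.exposure, cohort.instrument,
                                cohort.column("y"), cohort.column("c"),
                                np.array([f"dr_{int(g)}" for g in cohort.cluster]))
        a = iv_bias_component(cohort, "c")
        b = iv_bias_component(relabeled, "c")
        assert b.estimate == pytest.approx(a.estimate, abs=1e-12)
        assert b.se == pytest.approx(a.se, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(k=st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_scaling_covariate_scales_components_and_ses(self, k, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng)
        scaled = make_cohort(cohort.exposure, cohort.instrument, cohort.column("y"),
                             cohort.column("c") * k, cohort.cluster)
        for fn in (ols_bias_component, iv_bias_component):
            a, b = fn(cohort, "c"), fn(scaled, "c")
            assert b.estimate == pytest.approx(a.estimate * k, rel=1e-9)
            assert b.se == pytest.approx(a.se * k, rel=1e-9)


class TestAgainstStatsmodels:
    def test_cluster_robust_ols_matches_statsmodels_up_to_df_factor(self, rng):
        """Our sandwich uses only G/(G-1); statsmodels adds (n-1)/(n-k)."""
        cohort = random_cohort(rng, n=90, n_clusters=9)
        est = _slope_fit(cohort.column("c"), cohort.exposure, cohort.exposure,
                         cohort.cluster, level=0.95)
        X = sm.add_constant(cohort.exposure)
        fit = sm.OLS(cohort.column("c"), X).fit(cov_type="cluster",
                                                cov_kwds={"groups": cohort.cluster})
        n, k = 90, 2
        assert est.estimate == pytest.approx(fit.params[1], rel=1e-10)
        sm_var_unadj = fit.cov_params()[1, 1] * (n - k) / (n - 1)
        assert est.se**2 == pytest.approx(sm_var_unadj, rel=1e-8)

    def test_heteroskedastic_iv_matches_hc0_when_unclustered(self, rng):
        """Each row its own cluster: our IV sandwich should match the textbook
        HC0 2SLS variance (up to the n/(n-1) cluster factor)."""
        cohort = random_cohort(rng, n=150, n_clusters=150)
        est = _slope_fit(cohort.column("c"), cohort.exposure, cohort.instrument,
                         np.arange(150), level=0.95)
        n = 150
        X = np.column_stack([np.ones(n), cohort.exposure])
        Z = np.column_stack([np.ones(n), cohort.instrument])
        theta = np.linalg.solve(Z.T @ X, Z.T @ cohort.column("c"))
        e = cohort.column("c") - X @ theta
        A = Z.T @ X / n
        B = (Z * e[:, None]).T @ (Z * e[:, None]) / n
        V = np.linalg.inv(A) @ B @ np.linalg.inv(A).T / n * n / (n - 1)
        assert est.se**2 == pytest.approx(V[1, 1], rel=1e-10)
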