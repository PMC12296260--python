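"""Local-linear jump estimation, bandwidth selection and the fuzzy estimand."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdnat import CohortConfig, generate_cohort
from rdnat.continuity import (
    FuzzyRD,
    fuzzy_rd,
    local_linear_jump,
    select_bandwidth_mse,
    triangular_weights,
)


class TestTriangularWeights:
    def test_shape(self):
        w = triangular_weights([0.0, 5.0, -5.0, 10.0, 12.0], 10.0)
        np.testing.assert_allclose(w, [1.0, 0.5, 0.5, 0.0, 0.0])

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            triangular_weights([0.0], 0.0)

    @given(st.floats(min_value=0.1, max_value=1e3), st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
    def test_bounds_and_support(self, h, xs):
        w = triangular_weights(xs, h)
        assert ((w >= 0) & (w <= 1)).all()
        assert (w[np.abs(np.asarray(xs)) >= h] == 0).all()


# fixed 12-row fixture for the weighted-least-squares oracle
WLS_FIXTURE = pd.DataFrame(
    {
        "x": [-5.0, -4.0, -3.0, -2.5, -2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0, 4.5],
        "y": [2.1, 1.8, 2.4, 2.0, 1.7, 2.2, 3.1, 2.9, 3.4, 3.0, 3.6, 3.2],
    }
)


def _wls_intercept_oracle(x, y, w):
    """Explicit weighted-normal-equations solution, independent of the
    estimator implementation."""
    design = np.column_stack([np.ones_like(x), x])
    wmat = np.diag(w)
    beta = np.linalg.inv(design.T @ wmat @ design) @ design.T @ wmat @ y
    return beta[0]


class TestLocalLinearJump:
    def test_wls_oracle_on_fixture(self):
        x = WLS_FIXTURE["x"].to_numpy()
        y = WLS_FIXTURE["y"].to_numpy()
        h = 5.0
        w = np.maximum(0.0, 1.0 - np.abs(x) / h)
        left, right = (w > 0) & (x < 0), (w > 0) & (x >= 0)
        expected = _wls_intercept_oracle(x[right], y[right], w[right]) - _wls_intercept_oracle(
            x[left], y[left], w[left]
        )
        est = local_linear_jump(x, y, h)
        assert est.jump == pytest.approx(expected, abs=1e-10)
        assert est.n_eff_left == int(left.sum())
        assert est.n_eff_right == int(right.sum())

    def test_continuous_linear_function_has_zero_jump(self):
        x = np.arange(-30, 30, dtype=float)
        y = 2.0 + 0.1 * x
        est = local_linear_jump(x, y, 20.0)
        assert abs(est.jump) < 1e-12

    def test_pure_step_recovered_exactly(self):
        x = np.arange(-30, 30, dtype=float)
        y = 3.0 * (x >= 0)
        est = local_linear_jump(x, y, 20.0)
        assert est.jump == pytest.approx(3.0, abs=1e-12)

    def test_too_few_support_points(self):
        x = np.array([-1.0, -1.0, -1.0, 0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="distinct"):
            local_linear_jump(x, np.ones_like(x), 5.0)


class TestBandwidthSelection:
    def test_affine_invariance(self, null_cohort):
        x = null_cohort["mdob"].to_numpy(float)
        y = null_cohort["SA"].to_numpy(float)
        h0 = select_bandwidth_mse(x, y).h
        h1 = select_bandwidth_mse(x, 3.7 * y - 11.0).h
        assert h1 == pytest.approx(h0, abs=1e-8)

    def test_clamped_to_half_range(self, null_cohort):
        sel = select_bandwidth_mse(
            null_cohort["mdob"].to_numpy(float), null_cohort["SA"].to_numpy(float)
        )
        assert 0 < sel.h <= 120
        assert sel.method == "imbens-kalyanaraman"
        assert "sigma2_cutoff" in sel.pilot_quantities

    def test_running_variable_rescaling_equivariance(self, null_cohort):
        """Relabeling months as days scales h by the same factor and leaves
        the jump estimate unchanged."""
        x = null_cohort["mdob"].to_numpy(float)
        y = null_cohort["SA"].to_numpy(float)
        h = select_bandwidth_mse(x, y).h
        h_days = select_bandwidth_mse(30.0 * x, y).h
        assert h_days == pytest.approx(30.0 * h, rel=1e-8)
        est = local_linear_jump(x, y, h)
        est_days = local_linear_jump(30.0 * x, y, 30.0 * h)
        assert est_days.jump == pytest.approx(est.jump, abs=1e-10)

    def test_too_few_support_points(self):
        x = np.repeat(np.arange(-5, 5), 10).astype(float)
        with pytest.raises(ValueError, match="fixed bandwidth"):
            select_bandwidth_mse(x, np.random.default_rng(0).standard_normal(x.size))

    def test_zero_variance_outcome(self, null_cohort):
        with pytest.raises(ValueError, match="variance"):
            select_bandwidth_mse(null_cohort["mdob"].to_numpy(float), np.zeros(len(null_cohort)))


class TestFuzzyRD:
    def test_sharp_limit_equals_reduced_form(self, null_cohort):
        res = FuzzyRD(null_cohort, "SA", first_stage="rosla").fit(24.0)
        assert res.first_stage == pytest.approx(1.0, abs=1e-10)
        assert res.estimate == pytest.approx(res.reduced_form, abs=1e-10)

    def test_ratio_definition_and_identity(self, null_cohort):
        res = FuzzyRD(null_cohort, "SA", first_stage="stayed16").fit(36.0)
        assert res.estimate == pytest.approx(res.reduced_form / res.first_stage, abs=1e-12)
        assert res.reduced_form == pytest.approx(res.estimate * res.first_stage, abs=1e-12)

    def test_identity_holds_with_covariates_and_mse_bandwidth(self, null_cohort):
        res = FuzzyRD(
            null_cohort, "CT", first_stage="stayed16",
            covariates=("sex", "motion", "site"),
        ).fit("mse")
        assert res.reduced_form == pytest.approx(res.estimate * res.first_stage, abs=1e-12)
        assert res.n_eff_left > 0 and res.n_eff_right > 0
        assert res.ci_low < res.ci_high

    def test_noise_free_construction_oracle(self):
        """Complier effect 1.0 with a 0.10 compliance jump: LATE is exactly
        1.0 and the ITT equals the realized first-stage jump."""
        cfg = CohortConfig(
            months_range=(-24, 23), n_per_month=50, effect_delta=1.0,
            noise_sd=0.0, outcome_trend=(0.0, 0.005), covariate_effects={},
            site_effects=(0.0, 0.0, 0.0), missing_covariate_rate=0.0, seed=21,
        )
        tab = generate_cohort(cfg)
        res = FuzzyRD(tab, "SA", first_stage="stayed16").fit(24.0)
        assert res.estimate == pytest.approx(1.0, abs=1e-10)
        assert res.reduced_form == pytest.approx(res.first_stage, abs=1e-10)
        assert 0.05 < res.first_stage < 0.15

    def test_outcome_equivariance(self, null_cohort):
        a, b = -2.5, 7.0
        scaled = null_cohort.copy()
        scaled["SA"] = a * scaled["SA"] + b
        res0 = FuzzyRD(null_cohort, "SA", first_stage="stayed16").fit(30.0)
        res1 = FuzzyRD(scaled, "SA", first_stage="stayed16").fit(30.0)
        assert res1.reduced_form == pytest.approx(a * res0.reduced_form, rel=1e-9)
        assert res1.estimate == pytest.approx(a * res0.estimate, rel=1e-9)

    def test_weak_instrument_suppresses_late(self, null_cohort):
        weak = null_cohort.copy()
        weak["nojump"] = 0.0  # treatment probability never moves at the cutoff
        res = FuzzyRD(weak, "SA", first_stage="nojump").fit(24.0)
        assert res.weak_instrument
        assert np.isnan(res.estimate)
        assert np.isfinite(res.reduced_form)  # ITT still reported

    def test_functional_wrapper_and_summary(self, null_cohort):
        res = fuzzy_rd(null_cohort, "SA", first_stage_col="stayed16", bandwidth=24.0)
        text = res.summary()
        assert "reduced form" in text and "LATE" in text
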