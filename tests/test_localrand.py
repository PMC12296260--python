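"""Window selection, autoscaled priors, the Bayesian linear model and
Savage-Dickey Bayes factors."""

import numpy as np
import pytest
from scipy import stats

from rdnat import CohortConfig, generate_cohort
from rdnat.localrand import (
    BayesLinearResults,
    LocalRandomization,
    PriorSpec,
    association_analysis,
    autoscale_prior,
    fit_bayes_linear,
    grade_evidence,
    grade_evidence_from_bf10,
    itt_analysis,
    savage_dickey_bf,
    select_window,
    screen_covariates,
)

COVARIATES = ("sex", "summer", "dos", "dos2", "site", "motion", "t2flair")


class TestSelectWindow:
    def test_one_month_window(self, null_cohort):
        sub = select_window(null_cohort, 1)
        assert set(sub["mdob"].unique()) == {-1, 0}
        assert (sub["rosla"] == (sub["mdob"] >= 0)).all()

    def test_five_month_window(self, null_cohort):
        sub = select_window(null_cohort, 5)
        assert set(sub["mdob"].unique()) == set(range(-5, 5))
        assert sub["mdob"].nunique() == 10

    def test_out_of_range_window(self, window_cohort):
        with pytest.raises(ValueError):
            select_window(window_cohort.loc[window_cohort.mdob < 0], 1)
        with pytest.raises(ValueError):
            select_window(window_cohort, 0)


class TestAutoscalePrior:
    def test_direct_formula(self):
        y = np.array([0.0, 2.0, 4.0])  # sd 2
        x = np.array([0.0, 0.5, 1.0])  # sd 0.5
        assert autoscale_prior(PriorSpec(1.0), y, x) == pytest.approx(4.0)

    def test_strong_prior_multiplier(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(2000)
        x = rng.standard_normal(2000)
        got = autoscale_prior(PriorSpec(0.5), y, x)
        assert got == pytest.approx(0.5 * y.std(ddof=1) / x.std(ddof=1))

    def test_balanced_binary_predictor(self):
        y = np.array([-1.0, 1.0] * 500)  # sd ~ 1
        x = np.array([0.0, 1.0] * 500)  # sd ~ 0.5
        assert autoscale_prior(PriorSpec(1.0), y, x) == pytest.approx(2.0, rel=1e-3)

    def test_constant_predictor(self):
        with pytest.raises(ValueError):
            autoscale_prior(PriorSpec(1.0), np.ones(10), np.arange(10.0))


class TestFitBayesLinear:
    def test_flat_prior_limit_matches_ols(self, window_cohort):
        sub = select_window(window_cohort, 5)
        post = fit_bayes_linear(
            sub, "SA", "rosla", covariates=("sex",),
            prior=PriorSpec(100.0), method="analytic",
        )
        used = sub.dropna(subset=["SA", "sex"])
        X = np.column_stack([np.ones(len(used)), used["rosla"], used["sex"]])
        beta = np.linalg.lstsq(X, used["SA"].to_numpy(), rcond=None)[0]
        assert post.focal_mean == pytest.approx(beta[1], rel=0.01, abs=0.005)

    def test_gibbs_matches_conjugate_oracle(self, window_cohort):
        """With the residual scale fixed, the Gibbs posterior of the focal
        coefficient matches the closed-form normal conjugate posterior."""
        cfg = CohortConfig(months_range=(-5, 4), effect_delta=0.5, seed=23)
        tab = generate_cohort(cfg)
        model = LocalRandomization(tab, "SA", focal="rosla", covariates=("sex", "motion"), omega=5)
        analytic = model.fit(prior=PriorSpec(1.0), method="analytic")
        # 120k retained draws keep the Monte-Carlo error of the posterior SD
        # (~1/sqrt(2 n)) well below the 0.5% agreement contract
        sampled = model.fit(
            prior=PriorSpec(1.0), method="gibbs", iterations=240_000, chains=4,
            seed=9, sigma=analytic.sigma,
        )
        assert sampled.focal_mean == pytest.approx(analytic.focal_mean, rel=0.005)
        assert sampled.focal_sd == pytest.approx(analytic.focal_sd, rel=0.005)
        assert float(sampled.rhat.max()) < 1.05

    def test_chain_seed_self_consistency(self, window_cohort):
        model = LocalRandomization(window_cohort, "SA", focal="rosla", omega=5)
        a = model.fit(method="gibbs", iterations=20_000, seed=1)
        b = model.fit(method="gibbs", iterations=20_000, seed=2)
        mcse = a.focal_sd / np.sqrt(a.draws.shape[0] * a.draws.shape[1] / 10)
        assert abs(a.focal_mean - b.focal_mean) < 3 * mcse + 1e-6

    def test_degenerate_design_raises(self, window_cohort):
        sub = select_window(window_cohort, 5).copy()
        sub["SA"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            fit_bayes_linear(sub, "SA", "rosla")


class TestSavageDickey:
    def test_closed_form_normal_ratio(self):
        """Prior N(0,1), posterior N(1, 0.5^2): bf01 = phi(0;1,.5)/phi(0;0,1)."""
        post = _manual_posterior(mean=1.0, sd=0.5, prior_sd=1.0)
        bf = savage_dickey_bf(post)
        expected_bf01 = stats.norm.pdf(0, 1.0, 0.5) / stats.norm.pdf(0, 0.0, 1.0)
        assert bf.bf01 == pytest.approx(expected_bf01, rel=1e-10)
        assert bf.bf10 == pytest.approx(1 / expected_bf01, rel=1e-10)
        assert bf.bf10 * bf.bf01 == pytest.approx(1.0, abs=1e-12)

    def test_no_information_gives_unit_bf(self):
        post = _manual_posterior(mean=0.0, sd=1.0, prior_sd=1.0)
        bf = savage_dickey_bf(post)
        assert bf.bf10 == pytest.approx(1.0, abs=1e-12)

    def test_prior_width_ordering_on_null_data(self, window_cohort):
        """For a posterior concentrated near 0, wider priors give more
        evidence for the null."""
        model = LocalRandomization(window_cohort, "wFA", focal="rosla", covariates=("sex",), omega=5)
        bf01 = {
            s: model.fit(prior=PriorSpec(s), method="analytic").bayes_factor().bf01
            for s in (0.5, 1.0, 1.5)
        }
        assert bf01[1.5] > bf01[1.0] > bf01[0.5]


def _manual_posterior(mean, sd, prior_sd):
    import pandas as pd

    return BayesLinearResults(
        focal="theta", names=["theta"],
        mean=pd.Series({"theta": mean}), sd=pd.Series({"theta": sd}),
        prior_sd=pd.Series({"theta": prior_sd}),
        prior_mean=pd.Series({"theta": 0.0}),
        method="analytic", nobs=0, sigma=1.0,
    )


class TestGradeEvidence:
    @pytest.mark.parametrize(
        "bf10,label",
        [
            (1 / 18.21, "strong evidence for the null"),
            (1.0, "no evidence"),
            (41.7, "very strong evidence for the alternative"),
            (2.0, "anecdotal evidence for the alternative"),
            (1 / 5.0, "moderate evidence for the null"),
            (150.0, "extreme evidence for the alternative"),
        ],
    )
    def test_bands(self, bf10, label):
        assert grade_evidence_from_bf10(bf10) == label

    def test_wrapper_accepts_bfresult(self, window_cohort):
        model = LocalRandomization(window_cohort, "SA", omega=5)
        bf = model.fit(method="analytic").bayes_factor()
        assert grade_evidence(bf) == bf.grade


class TestAnalyses:
    def test_summer_excluded_at_narrow_windows(self, null_cohort):
        for omega in (1, 5):
            results = itt_analysis(
                null_cohort, "SA", omega, priors=(1.0,), covariates=COVARIATES,
                method="analytic",
            )
            dropped = dict(results[0]["posterior"].dropped_covariates)
            assert "summer" in dropped

    def test_itt_returns_one_result_per_prior(self, window_cohort):
        results = itt_analysis(
            window_cohort, "SA", 5, priors=(0.5, 1.0, 1.5), covariates=("sex",),
            method="analytic",
        )
        assert [r["prior"].scale_multiplier for r in results] == [0.5, 1.0, 1.5]
        for r in results:
            assert r["bf"].bf01 * r["bf"].bf10 == pytest.approx(1.0, abs=1e-12)

    def test_association_uses_eduyears(self, window_cohort):
        results = association_analysis(
            window_cohort, "SA", 5, priors=(1.0,), covariates=("sex",),
            method="analytic",
        )
        assert results[0]["posterior"].focal == "eduyears"

    def test_association_degenerate_eduyears(self, window_cohort):
        flat = window_cohort.copy()
        flat["eduyears"] = 12.0
        with pytest.raises(ValueError, match="variance"):
            association_analysis(flat, "SA", 5, priors=(1.0,), method="analytic")

    def test_null_consistency_bf01_grows_with_window_n(self):
        """Median evidence for the null strengthens as the window grows from
        the 1-month to the 5-month design."""
        med = {}
        for omega, n_label in ((1, 230), (5, 1200)):
            bf01 = []
            for seed in range(40):
                cfg = CohortConfig(months_range=(-5, 4), n_per_month=120, seed=3000 + seed)
                tab = generate_cohort(cfg)
                res = itt_analysis(tab, "SA", omega, priors=(1.0,), method="analytic")
                bf01.append(res[0]["bf"].bf01)
            med[omega] = float(np.median(bf01))
        assert med[5] > med[1] > 1.0


class TestScreening:
    def test_site_level_absent_in_window_dropped(self, window_cohort):
        sub = select_window(window_cohort, 5).copy()
        sub.loc[sub["site"] == "site3", "site"] = "site1"
        block, dropped = screen_covariates(sub, ["site"])
        assert "site_site3" not in block.columns

    def test_planted_separated_covariate_flagged(self, window_cohort):
        sub = select_window(window_cohort, 5).copy()
        sub["leak"] = sub["rosla"].astype(float)
        _, dropped = screen_covariates(sub, ["leak"])
        assert dropped and "assignment" in dropped[0][1] or "running" in dropped[0][1]
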