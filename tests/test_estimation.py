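"""Joint cost/QALY fit, response logit, and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ccbt_cea.estimation import (
    FitResult,
    ModelSpec,
    SeparationWarning,
    build_analysis_frame,
    fit_joint_cost_qaly,
    fit_response_logit,
    pool_rubin,
    pool_scalar,
)
from ccbt_cea import GeneratorConfig, ImputationConfig
from ccbt_cea.mice_pmm import run_mice
from ccbt_cea.synthetic_trial import generate_trial, induce_missingness


def _simulate_frame(rng, n=300, corr=0.0, beta_c=700.0, beta_q=0.02):
    treat = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(47, 13, n)
    female = (rng.random(n) < 0.8).astype(float)
    u0 = rng.normal(0.49, 0.11, n)
    cov = np.array([[200.0**2, corr * 200.0 * 0.05], [corr * 200.0 * 0.05, 0.05**2]])
    eps = rng.multivariate_normal([0, 0], cov, size=n)
    cost = 50 + beta_c * treat + 0.5 * age + eps[:, 0]
    qaly = 0.1 + beta_q * treat + 0.5 * u0 + eps[:, 1]
    return pd.DataFrame(
        {
            "treatment": treat,
            "age": age,
            "female": female,
            "baseline_utility": u0,
            "cost": cost,
            "qaly": qaly,
        }
    )


class TestJointFit:
    def test_equivalent_to_separate_ols_at_zero_correlation(self, rng):
        """With residual correlation fixed at 0, the joint system is exactly
        two independent least-squares fits (statsmodels OLS as oracle)."""
        frame = _simulate_frame(rng)
        fit = fit_joint_cost_qaly(frame, residual_corr_fixed=0.0)
        X = sm.add_constant(
            frame[["treatment", "age", "female", "baseline_utility"]].to_numpy()
        )
        for outcome, prefix in (("cost", "cost:"), ("qaly", "qaly:")):
            ols = sm.OLS(frame[outcome].to_numpy(), X).fit()
            mine = fit.params[[i for i in fit.params.index if i.startswith(prefix)]]
            np.testing.assert_allclose(mine.to_numpy(), ols.params, atol=1e-6)
            block = fit.cov.loc[mine.index, mine.index].to_numpy()
            np.testing.assert_allclose(block, ols.cov_params(), rtol=1e-8)
        # cross-equation block vanishes when the correlation is fixed at 0
        cross = fit.cov.loc["cost:treatment", "qaly:treatment"]
        assert cross == 0.0
        assert fit.residual_correlation == 0.0

    def test_recovers_residual_correlation(self, rng):
        ests = [
            fit_joint_cost_qaly(_simulate_frame(rng, n=400, corr=0.5)).residual_correlation
            for _ in range(30)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 3 * se

    def test_constant_treatment_column_rejected(self, rng):
        frame = _simulate_frame(rng)
        frame["treatment"] = 1.0
        with pytest.raises(ValueError, match="treatment|intercept"):
            fit_joint_cost_qaly(frame)

    def test_cross_covariance_follows_residual_covariance(self, rng):
        frame = _simulate_frame(rng, n=500, corr=0.6)
        fit = fit_joint_cost_qaly(frame)
        assert fit.residual_correlation > 0.3
        assert fit.cov.loc["cost:treatment", "qaly:treatment"] > 0


class TestResponseLogit:
    def test_two_by_two_closed_form_odds_ratio(self):
        """60/100 treated vs 30/100 control responders: OR = (60x70)/(40x30)."""
        frame = pd.DataFrame(
            {
                "treatment": [1.0] * 100 + [0.0] * 100,
                "response_post": [1.0] * 60 + [0.0] * 40 + [1.0] * 30 + [0.0] * 70,
            }
        )
        fit = fit_response_logit(frame, "post", covariates=("treatment",))
        assert fit.extras["odds_ratio"] == pytest.approx(3.5, rel=1e-6)

    def test_all_responders_hits_separation_path(self, rng):
        frame = _simulate_frame(rng, n=80)
        frame["baseline_phq9"] = rng.integers(10, 27, len(frame)).astype(float)
        frame["response_post"] = 1.0
        with pytest.warns(SeparationWarning):
            fit = fit_response_logit(frame, "post")
        assert fit.separation

    def test_odds_ratio_recovery(self, rng):
        """True conditional OR 2.8 at n=175: mean estimate over 50 replicates
        within 3 Monte-Carlo SEs (on the log-odds scale)."""
        true_log_or = np.log(2.8)
        ests = []
        for _ in range(50):
            n = 175
            treat = np.concatenate([np.ones(95), np.zeros(80)])
            age = rng.normal(47, 13, n)
            female = (rng.random(n) < 0.8).astype(float)
            phq = rng.integers(10, 27, n).astype(float)
            lp = -0.66 + true_log_or * treat
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            frame = pd.DataFrame(
                {
                    "treatment": treat,
                    "age": age,
                    "female": female,
                    "baseline_phq9": phq,
                    "response_post": y,
                }
            )
            ests.append(np.log(fit_response_logit(frame, "post").extras["odds_ratio"]))
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - true_log_or) < 3 * se

    def test_risk_difference_matches_rates_without_covariates(self):
        frame = pd.DataFrame(
            {
                "treatment": [1.0] * 100 + [0.0] * 100,
                "response_post": [1.0] * 60 + [0.0] * 40 + [1.0] * 30 + [0.0] * 70,
            }
        )
        fit = fit_response_logit(frame, "post", covariates=("treatment",))
        assert fit.extras["risk_difference"] == pytest.approx(0.30, abs=1e-6)


def _toy_fit(estimate: float, variance: float, n_used=175) -> FitResult:
    return FitResult(
        params=pd.Series([estimate], index=["b"]),
        cov=pd.DataFrame([[variance]], index=["b"], columns=["b"]),
        n_used=n_used,
    )


class TestRubinPooling:
    def test_identical_fits_collapse(self):
        fits = [_toy_fit(1.7, 0.4)] * 5
        pooled = pool_rubin(fits, n_params=1)
        row = pooled.table.loc["b"]
        assert row["estimate"] == 1.7
        assert row["between_var"] == 0.0
        assert row["total_var"] == pytest.approx(0.4)

    def test_hand_formula_m2(self):
        """m=2, estimates {1, 2}, variances {0.5, 0.5}:
        pooled 1.5, W 0.5, B 0.5, T = 0.5 + 1.5x0.5 = 1.25."""
        pooled = pool_rubin([_toy_fit(1.0, 0.5), _toy_fit(2.0, 0.5)], n_params=1)
        row = pooled.table.loc["b"]
        assert row["estimate"] == pytest.approx(1.5)
        assert row["within_var"] == pytest.approx(0.5)
        assert row["between_var"] == pytest.approx(0.5)
        assert row["total_var"] == pytest.approx(1.25)
        assert row["ci_lo"] < 1.5 < row["ci_hi"]

    def test_permutation_invariance(self):
        fits = [_toy_fit(e, v) for e, v in [(1.0, 0.2), (1.4, 0.3), (0.8, 0.25)]]
        a = pool_rubin(fits, n_params=1).table
        b = pool_rubin(fits[::-1], n_params=1).table
        pd.testing.assert_frame_equal(a, b)

    def test_total_never_below_within(self, rng):
        fits = [_toy_fit(rng.normal(), rng.uniform(0.1, 1.0)) for _ in range(8)]
        row = pool_rubin(fits, n_params=1).table.loc["b"]
        assert row["total_var"] >= row["within_var"]

    def test_mismatched_names_rejected(self):
        other = FitResult(
            params=pd.Series([1.0], index=["c"]),
            cov=pd.DataFrame([[0.1]], index=["c"], columns=["c"]),
            n_used=100,
        )
        with pytest.raises(ValueError, match="names"):
            pool_rubin([_toy_fit(1.0, 0.1), other])

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            pool_rubin([_toy_fit(1.0, 0.1)])

    def test_pool_scalar_matches_vector_path(self):
        out = pool_scalar([1.0, 2.0], [0.5, 0.5], n_used=175, n_params=1)
        assert out["estimate"] == pytest.approx(1.5)
        assert out["total_var"] == pytest.approx(1.25)


def test_ci_widens_with_missingness():
    """More follow-up missingness inflates between-imputation variance, so
    the pooled CI for the QALY treatment effect is (weakly) wider."""
    widths = {}
    for rate in (0.05, 0.35):
        cfg = GeneratorConfig(
            seed=21, missing_rate={"post": rate, "fu3": rate, "fu6": rate}
        )
        masked = induce_missingness(generate_trial(cfg), cfg)
        stack = run_mice(masked, ImputationConfig(m=15, n_cycles=5, seed=4))
        fits = [
            fit_joint_cost_qaly(build_analysis_frame(stack.complete(j)))
            for j in range(stack.m)
        ]
        row = pool_rubin(fits, n_params=5).table.loc["qaly:treatment"]
        widths[rate] = row["ci_hi"] - row["ci_lo"]
    assert widths[0.35] >= widths[0.05]


def test_model_spec_invariants():
    with pytest.raises(ValueError):
        ModelSpec("qaly", "gaussian-identity", ("treatment", "age"))
    with pytest.raises(ValueError):
        ModelSpec("response_post", "binomial-logit", ("treatment", "age"))


def test_recovery_pipeline_on_trial_frames(trial_complete):
    """End-to-end frame construction from generated data yields plausible
    adjusted effects on a single complete replicate."""
    frame = build_analysis_frame(trial_complete)
    fit = fit_joint_cost_qaly(frame)
    assert 550 < fit.params["cost:treatment"] < 900
    assert -0.02 < fit.params["qaly:treatment"] < 0.06
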