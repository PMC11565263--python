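"""Decision analysis: CE distributions, ICERs, CEACs, extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from ccbt_cea.cea import (
    CEDistribution,
    ceac,
    compute_icer,
    extrapolate_icer,
    extrapolation_table,
    icer_ci,
    response_icer,
    simulate_ce_distribution,
    simulate_ce_mixture,
)


def _dist(delta_cost, delta_effect):
    dc = np.asarray(delta_cost, float)
    de = np.asarray(delta_effect, float)
    return CEDistribution(
        delta_cost=dc,
        delta_effect=de,
        seed=None,
        source_mean=np.array([dc.mean(), de.mean()]),
        source_cov=np.cov(np.vstack([dc, de])),
    )


class TestSimulate:
    def test_empirical_sds_match_inputs(self):
        cov = np.diag([120.0**2, 0.01**2])
        d = simulate_ce_distribution([700.0, 0.02], cov, n_draws=100_000, seed=0)
        assert d.delta_cost.std() == pytest.approx(120.0, rel=0.02)
        assert d.delta_effect.std() == pytest.approx(0.01, rel=0.02)
        assert abs(np.corrcoef(d.delta_cost, d.delta_effect)[0, 1]) < 0.02

    def test_seed_determinism(self):
        cov = [[100.0, 0.1], [0.1, 0.001]]
        a = simulate_ce_distribution([1.0, 0.5], cov, 500, seed=9)
        b = simulate_ce_distribution([1.0, 0.5], cov, 500, seed=9)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_effect, b.delta_effect)

    def test_non_psd_rejected_with_remedy(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="nearest PSD"):
            simulate_ce_distribution([0, 0], bad, 100)

    def test_mixture_sampler_centers_on_mixture_mean(self):
        means = [[700, 0.02], [720, 0.022], [710, 0.018]]
        covs = [np.diag([25.0**2, 0.005**2])] * 3
        d = simulate_ce_mixture(means, covs, n_draws=50_000, seed=2)
        assert d.delta_cost.mean() == pytest.approx(710, abs=1.0)
        assert d.delta_effect.mean() == pytest.approx(0.02, abs=0.001)


class TestIcer:
    def test_arithmetic(self):
        assert compute_icer(100.0, 0.01)["icer"] == pytest.approx(10_000)

    def test_pooled_coefficient_ratio(self):
        """Ratio of the reported treatment coefficients: 714.64 / 0.0209."""
        out = compute_icer(714.64, 0.0209)
        assert out["icer"] == pytest.approx(34_193.3, abs=0.5)
        assert out["quadrant"] == "NE"

    def test_dominance_flagging(self):
        assert "dominant" in compute_icer(-50.0, 0.01)["quadrant"]
        assert "dominated" in compute_icer(50.0, -0.01)["quadrant"]

    def test_zero_effect_undefined(self):
        with pytest.raises(ZeroDivisionError):
            compute_icer(100.0, 0.0)


class TestIcerCI:
    def test_degenerate_distribution_zero_width(self):
        d = _dist(np.full(100, 500.0), np.full(100, 0.02))
        out = icer_ci(d)
        assert out["lo"] == out["hi"] == pytest.approx(25_000)

    def test_matches_brute_force_resampling_oracle(self):
        """Percentile CI agrees with an independently generated resample of
        the same distribution, within Monte-Carlo error of the quantiles."""
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        n = 200_000
        mk = lambda r: _dist(  # noqa: E731
            r.normal(700, 100, n), r.normal(0.02, 0.004, n)
        )
        a, b = icer_ci(mk(rng1)), icer_ci(mk(rng2))
        assert a["lo"] == pytest.approx(b["lo"], rel=0.02)
        assert a["hi"] == pytest.approx(b["hi"], rel=0.02)

    def test_interval_nesting(self, rng):
        d = _dist(rng.normal(700, 100, 5000), rng.normal(0.02, 0.005, 5000))
        wide, narrow = icer_ci(d, 0.95), icer_ci(d, 0.90)
        assert wide["lo"] <= narrow["lo"] <= narrow["hi"] <= wide["hi"]

    def test_refuses_when_effect_mostly_non_positive(self, rng):
        d = _dist(rng.normal(700, 100, 1000), rng.normal(-0.02, 0.005, 1000))
        with pytest.raises(ValueError, match="non-positive"):
            icer_ci(d)

    def test_excluded_fraction_reported(self, rng):
        d = _dist(rng.normal(700, 100, 20_000), rng.normal(0.01, 0.01, 20_000))
        out = icer_ci(d)
        assert 0.0 < out["fraction_excluded"] < 0.5


class TestCeac:
    def test_half_probability_at_symmetric_threshold(self, rng):
        # NMB at lambda* = 35000 is symmetric about 0 by construction.
        d = _dist(rng.normal(700, 50, 40_000), rng.normal(0.02, 0.002, 40_000))
        curve = ceac(d, [35_000.0])
        assert curve.probability[0] == pytest.approx(0.5, abs=0.02)

    def test_monotone_when_all_effects_positive(self, rng):
        d = _dist(rng.normal(700, 200, 5000), rng.uniform(0.001, 0.05, 5000))
        curve = ceac(d, np.arange(0, 150_001, 1000.0))
        assert (np.diff(curve.probability) >= 0).all()

    def test_zero_wtp_with_positive_costs(self, rng):
        d = _dist(rng.uniform(10, 100, 1000), rng.normal(0.02, 0.01, 1000))
        assert ceac(d, [0.0]).probability[0] == 0.0

    def test_bounds_and_limit(self, rng):
        d = _dist(rng.normal(700, 300, 10_000), rng.normal(0.01, 0.02, 10_000))
        curve = ceac(d, np.arange(0, 100_001, 5000.0))
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()
        limit = ceac(d, [1e12]).probability[0]
        assert limit == pytest.approx((d.delta_effect > 0).mean(), abs=1e-12)

    def test_nmb_rule_equals_plane_quadrant_rule(self, rng):
        d = _dist(rng.normal(100, 400, 3000), rng.normal(0.005, 0.02, 3000))
        lam = 20_000.0
        nmb_ce = ceac(d, [lam]).probability[0]
        dc, de = d.delta_cost, d.delta_effect
        quadrant_ce = np.where(
            de > 0,
            np.where(dc <= 0, True, dc / de < lam),
            np.where(dc >= 0, False, dc / de > lam),
        )
        # draws with de == 0 are cost-effective iff dc < 0
        quadrant_ce = np.where(de == 0, dc < 0, quadrant_ce)
        assert nmb_ce == pytest.approx(quadrant_ce.mean(), abs=1e-12)

    def test_empty_grid_rejected(self, rng):
        d = _dist(rng.normal(size=10), rng.normal(size=10))
        with pytest.raises(ValueError):
            ceac(d, [])


class TestResponseIcer:
    def test_figure_level_arithmetic(self):
        out = response_icer(714.64, 0.21)
        assert out["icer_per_responder"] == pytest.approx(3403.0, abs=0.5)
        assert out["extra_responders_per_100"] == pytest.approx(21.0)

    def test_unit_probability(self):
        assert response_icer(100.0, 1.0)["icer_per_responder"] == 100.0

    def test_observed_rate_difference(self):
        """12-week rates 0.5821 - 0.3396 = 0.2425 with the cost coefficient."""
        out = response_icer(714.64, 0.5821 - 0.3396)
        assert out["icer_per_responder"] == pytest.approx(2947.0, abs=1.0)

    def test_zero_difference_undefined(self):
        with pytest.raises(ValueError):
            response_icer(100.0, 0.0)


class TestExtrapolation:
    def test_zero_gap_returns_trial_icer(self):
        base = 714.64 / 0.0209
        for h in (12, 60):
            out = extrapolate_icer(0.0209, 0.0, 714.64, h, "stable")
            assert out["icer"] == pytest.approx(base)

    def test_worked_example_stable_12_months(self):
        """End-of-trial utility gap 0.047 held stable for a year:
        714.64 / (0.0209 + 0.047) ~= 10,524."""
        out = extrapolate_icer(0.0209, 0.047, 714.64, 12, "stable")
        assert out["icer"] == pytest.approx(10_524, abs=2)

    @given(
        gap=st_.floats(0.001, 0.2),
        cost=st_.floats(100.0, 2000.0),
        dq=st_.floats(0.001, 0.1),
    )
    @settings(deadline=None, max_examples=60)
    def test_stable_dominates_waning_and_decreases_in_horizon(self, gap, cost, dq):
        horizons = [12, 24, 36, 48, 60]
        stable = [extrapolate_icer(dq, gap, cost, h, "stable")["icer"] for h in horizons]
        waning = [
            extrapolate_icer(dq, gap, cost, h, "linear_waning")["icer"] for h in horizons
        ]
        assert all(s <= w for s, w in zip(stable, waning))
        assert all(b <= a + 1e-9 for a, b in zip(stable, stable[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(waning, waning[1:]))

    def test_table_covers_both_scenarios(self):
        table = extrapolation_table(0.0209, 0.047, 714.64)
        assert len(table) == 10
        assert set(table["durability"]) == {"stable", "linear_waning"}

    def test_errors(self):
        with pytest.raises(ValueError):
            extrapolate_icer(0.02, 0.05, 700.0, -6, "stable")
        with pytest.raises(ValueError):
            extrapolate_icer(0.02, 0.05, 700.0, 12, "exponential")
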