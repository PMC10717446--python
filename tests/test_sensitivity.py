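"""Pleiotropy-robust estimators: Egger, SIMEX, weighted median, Steiger,
multivariable MR."""

import math
from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm

from cannamr import (
    SimulationConfig,
    egger_simex,
    harmonize_pair,
    i2_gx,
    ivw_regression,
    mr_egger,
    mvmr,
    simulate_two_sample,
    steiger_filter,
    wald_ratios,
    weighted_median,
)
from cannamr.estimators import WaldEstimate
from cannamr.sensitivity import EstimationError, weighted_median_point
from cannamr.sumstats import ConfigurationError, InputError

from conftest import make_instrument


def _pair_instruments(**kwargs):
    pair = simulate_two_sample(SimulationConfig(**kwargs))
    return harmonize_pair(pair.exposure_stats, pair.outcome_stats, pair.covariate_stats or None).instruments


class TestEgger:
    def test_no_directional_pleiotropy_gives_null_intercept(self, sim_instruments):
        est = mr_egger(sim_instruments, n_boot=2000, seed=0)
        assert abs(est.intercept) < 3 * est.intercept_se

    def test_recovers_planted_pleiotropy_and_slope(self):
        ins = _pair_instruments(
            seed=21, theta=0.2, pleiotropy_mean=0.01, pleiotropy_sd=0.003
        )
        est = mr_egger(ins, n_boot=2000, seed=1)
        assert est.intercept == pytest.approx(0.01, abs=3 * est.intercept_se)
        assert est.theta == pytest.approx(0.2, abs=3 * est.se)

    def test_point_estimates_match_statsmodels_wls(self, sim_instruments):
        x = np.abs([i.beta_exposure for i in sim_instruments])
        y = np.sign([i.beta_exposure for i in sim_instruments]) * np.array(
            [i.beta_outcome for i in sim_instruments]
        )
        w = np.array([1 / i.se_outcome**2 for i in sim_instruments])
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        est = mr_egger(sim_instruments, n_boot=0)
        assert est.theta == pytest.approx(fit.params[1], abs=1e-12)
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-12)

    def test_zero_intercept_constraint_recovers_regression_ivw(self, sim_instruments):
        """Forcing the Egger intercept to zero is exactly the regression-form
        IVW fit (checked through the no-intercept WLS)."""
        x = np.abs([i.beta_exposure for i in sim_instruments])
        y = np.sign([i.beta_exposure for i in sim_instruments]) * np.array(
            [i.beta_outcome for i in sim_instruments]
        )
        w = np.array([1 / i.se_outcome**2 for i in sim_instruments])
        constrained = sm.WLS(y, x, weights=w).fit()
        assert ivw_regression(sim_instruments).theta == pytest.approx(
            constrained.params[0], abs=1e-12
        )

    def test_orientation_invariance(self, sim_instruments):
        """Flipping the reported allele of any SNP leaves the fit unchanged."""
        flipped = list(sim_instruments)
        for j in (0, 5, 30):
            i = flipped[j]
            flipped[j] = replace(
                i, beta_exposure=-i.beta_exposure, beta_outcome=-i.beta_outcome
            )
        a, b = mr_egger(sim_instruments, n_boot=0), mr_egger(flipped, n_boot=0)
        assert a.theta == pytest.approx(b.theta, abs=1e-14)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-14)

    def test_bootstrap_deterministic_given_seed(self, sim_instruments):
        a = mr_egger(sim_instruments, n_boot=500, seed=42)
        b = mr_egger(sim_instruments, n_boot=500, seed=42)
        assert (a.se, a.intercept_se) == (b.se, b.intercept_se)

    def test_needs_three_instruments(self):
        with pytest.raises(InputError):
            mr_egger([make_instrument(), make_instrument(rsid="rs2")])


class TestI2Gx:
    def test_zero_when_exposure_effects_identical(self):
        ins = [make_instrument(rsid=f"rs{i}", bx=0.1, sx=0.02) for i in range(5)]
        assert i2_gx(ins) == 0.0

    def test_approaches_100_when_measurement_error_vanishes(self):
        ins = [
            make_instrument(rsid=f"rs{i}", bx=0.05 + 0.01 * i, sx=1e-6)
            for i in range(5)
        ]
        assert i2_gx(ins) > 99.9

    def test_decreases_with_noisier_exposure_effects(self):
        precise = [make_instrument(rsid=f"rs{i}", bx=0.05 + 0.01 * i, sx=0.005) for i in range(6)]
        noisy = [replace(i, se_exposure=0.05) for i in precise]
        assert i2_gx(noisy) < i2_gx(precise)


class TestSimex:
    def test_equals_plain_egger_without_measurement_error(self, sim_instruments):
        exact = [replace(i, se_exposure=1e-12) for i in sim_instruments]
        simex = egger_simex(exact, n_sim=50, seed=0, n_boot=0)
        plain = mr_egger(exact, n_boot=0)
        assert simex.theta == pytest.approx(plain.theta, abs=1e-6)

    def test_small_correction_when_nome_nearly_holds(self):
        ins = _pair_instruments(seed=31, theta=0.2, n_exposure=10**7)
        assert i2_gx(ins) > 95
        simex = egger_simex(ins, n_sim=200, seed=0, n_boot=0)
        plain = mr_egger(ins, n_boot=0)
        assert abs(simex.theta - plain.theta) < 0.1 * abs(plain.theta)

    def test_corrects_attenuation_with_weak_instruments(self):
        """With noisy exposure effects the SIMEX slope should sit closer to
        the true effect than the naive Egger slope, most of the time."""
        wins = 0
        n_rep = 60
        for r in range(n_rep):
            ins = _pair_instruments(seed=1000 + r, theta=0.3, n_exposure=6000)
            simex = egger_simex(ins, n_sim=100, seed=r, n_boot=0)
            plain = mr_egger(ins, n_boot=0)
            wins += abs(simex.theta - 0.3) < abs(plain.theta - 0.3)
        assert wins / n_rep >= 0.7

    def test_grid_must_contain_zero(self, sim_instruments):
        with pytest.raises(ConfigurationError):
            egger_simex(sim_instruments, lambdas=(0.5, 1.0, 1.5))

    def test_deterministic_given_seed(self, sim_instruments):
        a = egger_simex(sim_instruments, n_sim=50, seed=9, n_boot=10)
        b = egger_simex(sim_instruments, n_sim=50, seed=9, n_boot=10)
        assert (a.theta, a.se) == (b.theta, b.se)


def _wald(ratios, ses):
    return [WaldEstimate(f"rs{i}", r, s) for i, (r, s) in enumerate(zip(ratios, ses))]


class TestWeightedMedian:
    def test_plain_median_under_equal_weights(self):
        est = weighted_median(_wald([0.1, 0.2, 0.3], [0.1, 0.1, 0.1]), n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.2)

    def test_percentile_construction_hand_case(self):
        # weights 1/se² normalize to 0.25, 0.5, 0.25 -> percentiles
        # 0.125, 0.5, 0.875 -> the median interpolates exactly at ratio 2
        ses = [1.0, 1.0 / math.sqrt(2), 1.0]
        est = weighted_median(_wald([1.0, 2.0, 10.0], ses), n_boot=100, seed=0)
        assert est.theta == pytest.approx(2.0)

    def test_point_function_interpolates(self):
        ratios = np.array([1.0, 2.0, 4.0])
        w = np.array([1.0, 1.0, 2.0])  # percentiles 0.125, 0.375, 0.75
        expected = 2.0 + (0.5 - 0.375) / (0.75 - 0.375) * 2.0
        assert weighted_median_point(ratios, w) == pytest.approx(expected)

    def test_bounded_by_extreme_ratios(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ratios = rng.normal(0, 1, 7)
            ses = rng.uniform(0.05, 0.5, 7)
            est = weighted_median(_wald(ratios, ses), n_boot=50, seed=0)
            assert ratios.min() <= est.theta <= ratios.max()

    def test_robust_to_thirty_percent_invalid_instruments(self):
        ins = _pair_instruments(
            seed=41, theta=0.2, pleiotropy_mean=0.05, invalid_fraction=0.3
        )
        est = weighted_median(wald_ratios(ins), n_boot=2000, seed=0)
        assert est.theta == pytest.approx(0.2, abs=3 * est.se)

    def test_needs_three_estimates(self):
        with pytest.raises(InputError):
            weighted_median(_wald([0.1, 0.2], [0.1, 0.1]))


class TestSteiger:
    def test_direction_flag_definition(self):
        ins = make_instrument(bx=0.1, sx=0.01, by=0.001, sy=0.01)
        res = steiger_filter([ins], n_exposure=10_000, n_outcome=10_000)
        assert res.results[0].correct_direction
        assert res.results[0].r2_exposure > res.results[0].r2_outcome

    def test_equal_correlations_are_indeterminate(self):
        ins = make_instrument(bx=0.1, sx=0.02, by=0.1, sy=0.02)
        res = steiger_filter([ins], n_exposure=50_000, n_outcome=50_000)
        assert res.results[0].z_p == pytest.approx(1.0)

    def test_r2_mapping_monotone_and_bounded(self):
        from cannamr.sensitivity import _z_to_r2

        zs = [0.0, 0.5, 1.0, 2.0, 5.0, 50.0]
        r2s = [_z_to_r2(z, 1000) for z in zs]
        assert r2s == sorted(r2s)
        assert all(0 <= r < 1 for r in r2s)

    def test_simulated_forward_causation_detected(self, sim_instruments):
        res = steiger_filter(sim_instruments)
        assert res.overall_correct
        assert res.overall_p < 0.001
        # the weakest instruments can misclassify by chance; the bulk must not
        assert sum(r.correct_direction for r in res.results) > len(res.results) * 0.8


class TestMvmr:
    def test_zero_covariate_effects_reduce_to_regression_ivw(self, sim_instruments):
        ins = [replace(i, beta_covariate=0.0, se_covariate=0.01) for i in sim_instruments]
        est = mvmr(ins, n_boot=500, seed=0)
        assert est.theta == pytest.approx(ivw_regression(sim_instruments).theta, abs=1e-12)

    def test_recovers_dual_effects(self):
        ins = _pair_instruments(
            seed=51, theta=0.2, covariate_theta=0.3, covariate_r2=0.02, covariate_cor=0.5
        )
        est = mvmr(ins, n_boot=2000, seed=0)
        assert est.theta == pytest.approx(0.2, abs=3 * est.se)
        assert est.covariate_theta == pytest.approx(0.3, abs=3 * est.covariate_se)

    def test_outcome_through_covariate_only(self):
        ins = _pair_instruments(
            seed=61, theta=0.0, covariate_theta=0.3, covariate_r2=0.02, covariate_cor=0.5
        )
        est = mvmr(ins, n_boot=2000, seed=0)
        assert abs(est.theta) < 3 * est.se

    def test_drops_and_counts_missing_covariate_rows(self, sim_instruments):
        ins = [replace(i, beta_covariate=0.01, se_covariate=0.01) for i in sim_instruments]
        for j in range(8):
            ins[j] = replace(ins[j], beta_covariate=None, se_covariate=None)
        est = mvmr(ins, n_boot=200, seed=0)
        assert est.n_snps == len(ins) - 8

    def test_collinear_design_rejected(self, sim_instruments):
        ins = [
            replace(i, beta_covariate=2.0 * i.beta_exposure, se_covariate=i.se_exposure)
            for i in sim_instruments
        ]
        with pytest.raises(EstimationError):
            mvmr(ins, n_boot=100, seed=0)
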