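"""Parameter identification: exactness on noise-free data, noise robustness."""

import math

import numpy as np
import pytest

from duotank import (
    DOTrace,
    GassingOutKLa,
    PiecewiseConstant,
    PowerLawKLa,
    RecircParams,
    RecirculationModel,
    SaturationLaw,
    SaturationModel,
    estimate_kla,
    fit_power_law,
    fit_recirc_lambdas,
    fit_saturation,
    generate_synthetic_trace,
    goodness_of_fit,
)
from duotank.identify import IdentificationError


class TestGassingOut:
    def test_exact_on_noise_free_exponential(self):
        trace = generate_synthetic_trace("gassing_out", kla=0.02, cstar=7.58,
                                         duration=300.0)
        kla, report = estimate_kla(trace, cstar=7.58)
        assert kla == pytest.approx(0.02, rel=1e-9)
        assert report.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_samples_reduce_to_two_point_formula(self):
        cstar, kla_true = 7.58, 0.015
        t = np.array([40.0, 180.0])
        c = cstar * (1.0 - np.exp(-kla_true * t))
        trace = DOTrace(time=t, value=c)
        kla, _ = estimate_kla(trace, cstar)
        expected = -(math.log(cstar - c[1]) - math.log(cstar - c[0])) / (t[1] - t[0])
        assert kla == pytest.approx(expected, rel=1e-12)
        assert kla == pytest.approx(kla_true, rel=1e-12)

    def test_constant_zero_trace_gives_zero_kla(self):
        trace = DOTrace(time=np.arange(10.0), value=np.zeros(10))
        kla, _ = estimate_kla(trace, cstar=7.58)
        assert kla == pytest.approx(0.0, abs=1e-15)

    def test_sample_at_saturation_is_domain_error(self):
        trace = DOTrace(time=np.arange(5.0), value=np.array([0, 1, 2, 7.6, 3.0]))
        with pytest.raises(IdentificationError, match="sample 3"):
            estimate_kla(trace, cstar=7.58)

    def test_invariant_to_time_translation(self):
        base = generate_synthetic_trace("gassing_out", kla=0.008, cstar=12.0,
                                        duration=400.0)
        shifted = DOTrace(time=base.time + 1234.5, value=base.value)
        k0, _ = estimate_kla(base, 12.0)
        k1, _ = estimate_kla(shifted, 12.0)
        assert k1 == pytest.approx(k0, rel=1e-12)

    def test_model_results_interface(self):
        trace = generate_synthetic_trace("gassing_out", kla=0.02, cstar=7.58)
        res = GassingOutKLa(trace, cstar=7.58).fit()
        assert res.params["kla"] == pytest.approx(0.02, rel=1e-9)
        assert "kla" in res.summary()
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)


class TestPowerLawFit:
    def test_exact_recovery_and_dimensionless_consistency(self, dimfit):
        phis = np.linspace(0.05, 1.0, 12)
        klas = 2.5302 * phis ** 1.9139
        law, dfit, report = fit_power_law(phis, klas, dimfit)
        assert law.a == pytest.approx(2.5302, rel=1e-9)
        assert law.m == pytest.approx(1.9139, rel=1e-9)
        assert dfit.n2 == pytest.approx(2.0 * law.m, rel=1e-12)
        # a <-> n1 algebraic map in the same unit system
        assert dfit.n1 == pytest.approx(
            law.a ** 2 * dimfit.dB / (dimfit.g * dimfit.rho ** 2), rel=1e-9
        )

    def test_noisy_recovery_within_five_percent(self, rng):
        phis = np.linspace(0.05, 1.0, 20)
        klas = 2.5302 * phis ** 1.9139 * (1.0 + 0.01 * rng.standard_normal(20))
        law, _, _ = fit_power_law(phis, klas)
        assert law.a == pytest.approx(2.5302, rel=0.05)
        assert law.m == pytest.approx(1.9139, rel=0.05)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(IdentificationError):
            fit_power_law([0.0, 0.5], [0.1, 0.2])
        with pytest.raises(IdentificationError):
            fit_power_law([0.2, 0.5], [-0.1, 0.2])

    def test_single_phi_rejected(self):
        with pytest.raises(IdentificationError):
            fit_power_law([0.5, 0.5], [0.1, 0.1])

    def test_model_interface(self):
        phis = np.linspace(0.1, 1.0, 8)
        res = PowerLawKLa(phis, 1.7 * phis ** 2.2).fit()
        assert res.law.m == pytest.approx(2.2, rel=1e-9)


class TestSaturationFit:
    def test_exact_points_recover_c(self):
        phis = np.array([0.05, 0.2, 0.5, 1.0])
        law, _ = fit_saturation(phis, 36.1053 * phis)
        assert law.c == pytest.approx(36.1053, rel=1e-12)

    def test_single_pure_oxygen_pair(self):
        law, _ = fit_saturation([1.0, 1.0], [36.1053, 36.1053])
        assert law.c == pytest.approx(36.1053, rel=1e-12)

    def test_replicate_means_with_noise_within_two_percent(self):
        phis, csats = generate_synthetic_trace(
            "saturation_points", noise_sd=0.1, seed=7,
            phis=(0.2, 0.4, 0.6, 0.8, 1.0), replicates=5,
        )
        law, _ = fit_saturation(phis, csats)
        assert law.c == pytest.approx(36.1053, rel=0.02)

    def test_thermo_mode_recovers_constants(self):
        P, P_H2O = 101325.0, 6274.0
        phis = np.linspace(0.05, 1.0, 10)
        truth = 32e3 * np.exp(0.0022 * np.log(phis * (P - P_H2O)) - 4.6525)
        law, report = fit_saturation(phis, truth, mode="thermo", P=P, P_H2O=P_H2O)
        assert law.d1 == pytest.approx(0.0022, rel=1e-6)
        assert law.d2 == pytest.approx(4.6525, rel=1e-6)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(IdentificationError):
            fit_saturation([0.3, 0.3, 0.3], [10.0, 10.1, 9.9], mode="thermo")
        with pytest.raises(IdentificationError):
            fit_saturation([0.0, 0.0], [0.0, 0.0], mode="linear")

    def test_model_interface(self):
        phis = np.array([0.2, 0.5, 1.0])
        res = SaturationModel(phis, 30.0 * phis).fit()
        assert res.law.c == pytest.approx(30.0, rel=1e-12)


def _lambda_traces(lam1, lam2, noise_sd=0.0, seed=0, duration=600.0, dt=5.0):
    rp = RecircParams(lambda1=lam1, lambda2=lam2)
    return generate_synthetic_trace(
        "dual_tank", noise_sd=noise_sd, seed=seed, rp=rp,
        duration=duration, dt=dt, phi=0.5,
    )


class TestLambdaFit:
    def test_noise_free_recovery_within_one_percent(self, rp, sat):
        traces = _lambda_traces(0.0069233, 0.0004899)
        lam1, lam2, report = fit_recirc_lambdas(
            traces["J"], traces["Y"], rp, sat, PiecewiseConstant.constant(0.5)
        )
        assert lam1 == pytest.approx(0.0069233, rel=0.01)
        assert lam2 == pytest.approx(0.0004899, rel=0.01)
        assert report.rmse < 1e-6

    def test_noisy_recovery_within_ten_percent(self, rp, sat):
        traces = _lambda_traces(0.0069233, 0.0004899, noise_sd=0.02, seed=3)
        lam1, lam2, _ = fit_recirc_lambdas(
            traces["J"], traces["Y"], rp, sat, PiecewiseConstant.constant(0.5)
        )
        assert lam1 == pytest.approx(0.0069233, rel=0.10)
        assert lam2 == pytest.approx(0.0004899, rel=0.10)

    def test_flat_traces_unidentifiable(self, rp, sat):
        t = np.arange(0.0, 100.0, 5.0)
        flat_j = DOTrace(time=t, value=np.full_like(t, 7.2), zone="J")
        flat_y = DOTrace(time=t, value=np.full_like(t, 7.2), zone="Y")
        with pytest.raises(IdentificationError, match="flat"):
            fit_recirc_lambdas(flat_j, flat_y, rp, sat,
                               PiecewiseConstant.constant(0.2))

    def test_bias_shrinks_with_trace_length(self, rp, sat):
        durations = (150.0, 600.0, 2400.0)
        errors = []
        for duration in durations:
            ests = []
            for seed in (11, 12, 13):
                traces = _lambda_traces(0.0069233, 0.0004899, noise_sd=0.05,
                                        seed=seed, duration=duration, dt=5.0)
                lam1, _, _ = fit_recirc_lambdas(
                    traces["J"], traces["Y"], rp, sat,
                    PiecewiseConstant.constant(0.5),
                )
                ests.append(lam1)
            errors.append(abs(np.mean(ests) - 0.0069233))
        assert errors[2] < errors[0]

    def test_model_interface(self, rp, sat):
        traces = _lambda_traces(0.005, 0.001)
        res = RecirculationModel(traces["J"], traces["Y"], rp, sat,
                                 PiecewiseConstant.constant(0.5)).fit()
        assert res.lambdas[0] == pytest.approx(0.005, rel=0.01)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        rmse, r2 = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0
        assert r2 == 1.0

    def test_constant_offset(self):
        obs = np.array([1.0, 2.0, 3.0]) + 0.1
        rmse, _ = goodness_of_fit([1.0, 2.0, 3.0], obs)
        assert rmse == pytest.approx(0.1, rel=1e-12)

    def test_hand_case(self):
        rmse, r2 = goodness_of_fit([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert rmse == pytest.approx(math.sqrt(1.0 / 3.0), rel=1e-12)
        assert r2 == pytest.approx(0.5, rel=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            _, r2 = goodness_of_fit([1.0, 1.1], [1.0, 1.0])
        assert math.isnan(r2)
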