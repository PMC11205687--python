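import numpy as np
import pytest
from scipy.integrate import quad

from enthalpics.calvet import (
    CalibrationWarning,
    CalvetRun,
    CpPolynomial,
    calibration_constant,
    correct_to_reference_T,
    cp_integral,
    summarize_calvet,
    vaporization_enthalpy,
)
from enthalpics.synthetic import (
    SYNTHETIC_CP_FURFURYLAMINE,
    SYNTHETIC_CP_METHYLFURFURYLAMINE,
    SyntheticCalvetConfig,
    generate_calvet_runs,
)


class TestCpIntegral:
    def test_constant_cp_closed_form(self):
        p = CpPolynomial((100.0,), scale_factor=1.0)
        assert cp_integral(p, 298.15, 344.5) == pytest.approx(4.635)

    def test_quadratic_against_quadrature(self):
        p = CpPolynomial((20.0, 0.3, -2e-4), scale_factor=0.965)
        lo, hi = 298.15, 400.0
        oracle, _ = quad(lambda T: p.cp(T), lo, hi)
        assert p.integral(lo, hi) == pytest.approx(oracle / 1000.0, abs=1e-9)

    def test_degenerate_interval(self):
        assert SYNTHETIC_CP_FURFURYLAMINE.integral(320.0, 320.0) == 0.0

    def test_additive_over_adjacent_intervals(self):
        p = SYNTHETIC_CP_METHYLFURFURYLAMINE
        whole = p.integral(298.15, 339.9)
        split = p.integral(298.15, 320.0) + p.integral(320.0, 339.9)
        assert whole == pytest.approx(split, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SYNTHETIC_CP_FURFURYLAMINE.integral(100.0, 300.0)


class TestCalibrationConstant:
    def _runs(self, value, n=4):
        return [CalvetRun(5.0, 344.5, value) for _ in range(n)]

    def test_unbiased_instrument(self):
        assert calibration_constant(self._runs(51.0), 51.0) == pytest.approx(1.0)

    def test_two_percent_bias(self):
        k = calibration_constant(self._runs(51.0 * 1.02), 51.0)
        assert k == pytest.approx(1 / 1.02, rel=1e-9)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            calibration_constant(self._runs(51.0, n=1), 51.0)

    def test_large_bias_warns(self):
        with pytest.warns(CalibrationWarning):
            calibration_constant(self._runs(51.0 * 1.10), 51.0)


class TestCorrectionToReferenceT:
    def test_known_corrections(self):
        v = correct_to_reference_T(54.5, SYNTHETIC_CP_FURFURYLAMINE, 344.5)
        assert v == pytest.approx(49.1, abs=0.05)
        v2 = correct_to_reference_T(59.3, SYNTHETIC_CP_METHYLFURFURYLAMINE, 339.9)
        assert v2 == pytest.approx(53.3, abs=0.05)

    def test_linear_in_observed(self):
        p = SYNTHETIC_CP_FURFURYLAMINE
        a = correct_to_reference_T(50.0, p, 344.5)
        b = correct_to_reference_T(60.0, p, 344.5)
        assert b - a == pytest.approx(10.0)

    def test_oven_below_reference_rejected(self):
        with pytest.raises(ValueError):
            correct_to_reference_T(54.5, SYNTHETIC_CP_FURFURYLAMINE, 290.0)


class TestSummaries:
    def test_mean_and_sdom(self):
        rng = np.random.default_rng(42)
        values = 54.5 + rng.normal(0, 0.98, size=6)
        runs = [CalvetRun(5.0, 344.5, v) for v in values]
        s = summarize_calvet(runs)
        assert s.at_oven.value == pytest.approx(values.mean())
        assert s.at_oven.u == pytest.approx(
            values.std(ddof=1) / np.sqrt(6)
        )

    def test_identical_runs_zero_sdom(self):
        runs = [CalvetRun(5.0, 344.5, 54.5)] * 3
        assert summarize_calvet(runs).at_oven.u == 0.0

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            summarize_calvet([CalvetRun(5.0, 344.5, 54.5)])

    def test_final_uncertainty_doubles_and_includes_calibration(self):
        runs = [CalvetRun(5.0, 344.5, v) for v in (54.1, 54.9)]
        s = summarize_calvet(runs, u_calibration=0.3)
        q = vaporization_enthalpy(s, SYNTHETIC_CP_FURFURYLAMINE)
        assert q.u == pytest.approx(2 * np.hypot(s.at_oven.u, 0.3))


class TestRoundTrips:
    def test_noise_free_exact(self):
        cfg = SyntheticCalvetConfig(seed=9, noise_sd=0.0, true_dvapH=49.1)
        runs = generate_calvet_runs(cfg)
        s = summarize_calvet(runs)
        q = vaporization_enthalpy(s, cfg.cp)
        assert q.value == pytest.approx(49.1, abs=1e-10)
        assert q.u == 0.0

    def test_bias_removed_by_calibration(self):
        ref_cfg = SyntheticCalvetConfig(
            seed=10, noise_sd=0.0, true_dvapH=51.42, bias=1.02,
            cp=CpPolynomial((0.0,)),
        )
        ref_runs = generate_calvet_runs(ref_cfg)
        k = calibration_constant(ref_runs, 51.42)
        cfg = SyntheticCalvetConfig(seed=11, noise_sd=0.0, bias=1.02)
        runs = generate_calvet_runs(cfg)
        s = summarize_calvet(runs, k=k)
        q = vaporization_enthalpy(s, cfg.cp)
        # the multiplicative bias also scales the heating term; a 2 %
        # bias on ~54.5 is removed to well under the run scatter
        assert q.value == pytest.approx(cfg.true_dvapH, abs=0.05)

    def test_noisy_recovery_unbiased(self):
        """Noisy runs recover the truth to well within the run scatter
        when averaged over a long series."""
        cfg = SyntheticCalvetConfig(seed=12, noise_sd=0.98, n_runs=100)
        runs = generate_calvet_runs(cfg)
        q = vaporization_enthalpy(summarize_calvet(runs), cfg.cp)
        assert q.value == pytest.approx(cfg.true_dvapH, abs=3 * 0.98 / 10)
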