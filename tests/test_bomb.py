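import numpy as np
import pytest

from enthalpics.bomb import (
    BombExperiment,
    Corrections,
    IncompleteRecordError,
    InconsistentRecordError,
    MELINEX,
    COTTON_FUSE,
    TemperatureTrace,
    calibrate,
    energy_ipb,
    ignition_energy,
    massic_energy,
    reduce_trace,
    sample_mass_from_co2,
)
from enthalpics.formula import parse_formula
from enthalpics.synthetic import (
    SyntheticBombConfig,
    generate_bomb_experiments,
    generate_calibration_runs,
    synthetic_trace,
)

FUEL = parse_formula("C5H7NO")


class TestIgnitionEnergy:
    def test_no_discharge(self):
        assert ignition_energy(1400e-6, 40.0, 40.0) == 0.0

    def test_discharge(self):
        assert ignition_energy(1400e-6, 40.0, 20.0) == pytest.approx(0.84)

    def test_voltage_rise_rejected(self):
        with pytest.raises(InconsistentRecordError):
            ignition_energy(1400e-6, 20.0, 40.0)

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ValueError):
            ignition_energy(0.0, 40.0, 20.0)


class TestEnergyIPB:
    def test_zero_rise_zero_ignition(self):
        exp = BombExperiment(m_sample=0.5, dT_ad=0.0, du_ign=0.0)
        assert energy_ipb(exp, 15907.1) == 0.0

    def test_direct_evaluation(self):
        exp = BombExperiment(
            m_sample=0.5, dT_ad=1.2000, du_ign=0.8, eps_f=16.0,
            delta_m_h2o=0.0,
        )
        assert energy_ipb(exp, 15907.1) == pytest.approx(-19106.92, abs=1e-6)

    def test_linear_in_temperature_rise(self):
        e1 = BombExperiment(m_sample=0.5, dT_ad=0.6, du_ign=0.0, eps_f=16.0)
        e2 = BombExperiment(m_sample=0.5, dT_ad=1.2, du_ign=0.0, eps_f=16.0)
        assert energy_ipb(e2, 15907.1) == pytest.approx(
            2 * energy_ipb(e1, 15907.1)
        )


class TestTraceReduction:
    def test_closed_form_recovery(self):
        """A noise-free Newtonian trace with known ΔT and cooling
        constant 1.5e-3 min⁻¹ is recovered to 1e-4 K."""
        cfg = SyntheticBombConfig(seed=0, temperature_noise=0.0, massic_noise=0.0)
        for dT_true in (0.6, 1.2000):
            red = reduce_trace(synthetic_trace(dT_true, cfg))
            assert red.dT_ad == pytest.approx(dT_true, abs=1e-4)
            assert red.cooling_constant * 60.0 == pytest.approx(
                cfg.cooling_constant, rel=1e-3
            )

    def test_zero_heat_exchange_gives_plain_difference(self):
        t = np.arange(30) * 10.0
        T = np.concatenate([np.full(10, 298.15), np.linspace(298.15, 299.35, 10),
                            np.full(10, 299.35)])
        trace = TemperatureTrace(t, T, ignition_index=9, main_end_index=20)
        red = reduce_trace(trace)
        assert red.dT_ad == pytest.approx(299.35 - 298.15, abs=1e-12)

    def test_doubling_energy_doubles_rise(self):
        cfg = SyntheticBombConfig(seed=0, temperature_noise=0.0, massic_noise=0.0)
        r1 = reduce_trace(synthetic_trace(0.5, cfg))
        r2 = reduce_trace(synthetic_trace(1.0, cfg))
        assert r2.dT_ad == pytest.approx(2 * r1.dT_ad, rel=1e-4)

    def test_dickinson_agrees_roughly(self):
        cfg = SyntheticBombConfig(seed=0, temperature_noise=0.0, massic_noise=0.0)
        red = reduce_trace(synthetic_trace(1.2, cfg), method="dickinson")
        assert red.dT_ad == pytest.approx(1.2, abs=5e-3)

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError):
            TemperatureTrace(
                np.arange(10.0), np.full(10, 298.0),
                ignition_index=8, main_end_index=3,
            )


class TestSampleMassFromCO2:
    def test_pure_inversion(self):
        m = sample_mass_from_co2(2.2657722128978453, FUEL)
        assert m == pytest.approx(1.0, rel=1e-12)

    def test_aux_contributions_subtracted(self):
        co2 = (
            2.2657722128978453
            + 0.003 * COTTON_FUSE.co2_per_gram()
            + 0.05 * MELINEX.co2_per_gram()
        )
        m = sample_mass_from_co2(co2, FUEL, m_fuse=0.003, m_melinex_dry=0.05)
        assert m == pytest.approx(1.0, rel=1e-10)

    def test_fuse_only_run(self):
        co2 = 0.003 * COTTON_FUSE.co2_per_gram()
        assert sample_mass_from_co2(co2, FUEL, m_fuse=0.003) == pytest.approx(0.0, abs=1e-12)

    def test_deficit_rejected(self):
        with pytest.raises(InconsistentRecordError):
            sample_mass_from_co2(0.001, FUEL, m_fuse=0.01)


class TestMassicEnergy:
    def test_noise_free_round_trip(self, exact_calibration):
        """Synthetic runs built from a declared Δc u° reduce back to it
        within 0.05 %."""
        cfg = SyntheticBombConfig(seed=11, temperature_noise=0.0, massic_noise=0.0)
        experiments, truths = generate_bomb_experiments(cfg)
        for exp, truth in zip(experiments, truths):
            res = massic_energy(exp, FUEL, exact_calibration)
            assert res.value == pytest.approx(truth, rel=5e-4)
            assert not res.warnings

    def test_corrections_all_off_degenerates(self, exact_calibration):
        exp = BombExperiment(
            m_sample=0.5, m_fuse=0.003, m_melinex=0.05, dT_ad=1.0,
            du_ign=0.8, n_hno3=5e-5,
        )
        off = Corrections(fuse=False, melinex=False, hno3=False,
                          standard_state=False)
        res = massic_energy(exp, FUEL, exact_calibration, corrections=off)
        du_ipb = energy_ipb(exp, exact_calibration.eps_cal.value)
        assert res.value == pytest.approx(du_ipb / 0.5)

    def test_hno3_contribution(self, exact_calibration):
        base = BombExperiment(m_sample=0.5, dT_ad=1.0, n_hno3=0.0)
        acid = BombExperiment(m_sample=0.5, dT_ad=1.0, n_hno3=1e-3)
        r0 = massic_energy(base, FUEL, exact_calibration)
        r1 = massic_energy(acid, FUEL, exact_calibration)
        # 1 mmol of HNO3 adds 59.7 J to the subtracted corrections
        assert (r1.value - r0.value) * 0.5 == pytest.approx(59.7)

    def test_mass_recovered_from_co2(self, exact_calibration):
        cfg = SyntheticBombConfig(seed=2, temperature_noise=0.0, massic_noise=0.0)
        experiments, truths = generate_bomb_experiments(cfg)
        exp = experiments[0]
        weighed = exp.m_sample
        exp.m_sample = None  # force the CO2 route
        res = massic_energy(exp, FUEL, exact_calibration)
        assert res.m_sample == pytest.approx(weighed, rel=1e-9)
        assert res.value == pytest.approx(truths[0], rel=5e-4)

    def test_poor_co2_recovery_flagged(self, exact_calibration):
        exp = BombExperiment(m_sample=0.5, dT_ad=1.0, m_co2=0.5 * 2.2658 * 1.05)
        res = massic_energy(exp, FUEL, exact_calibration)
        assert res.warnings

    def test_missing_rise_and_trace_rejected(self, exact_calibration):
        with pytest.raises(IncompleteRecordError):
            massic_energy(BombExperiment(m_sample=0.5), FUEL, exact_calibration)


class TestCalibrate:
    def test_noise_free_recovery(self):
        runs = generate_calibration_runs(seed=3, eps_cal_true=15907.1)
        result = calibrate(runs)
        assert result.eps_cal.value == pytest.approx(15907.1, abs=1e-6)
        assert result.eps_cal.u == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_stated_noise(self):
        runs = generate_calibration_runs(
            seed=4, eps_cal_true=15907.1, n_runs=8, dT_noise=1e-4
        )
        result = calibrate(runs)
        # 1e-4 K on a ~1.2 K rise is ~1e-4 relative on eps_cal
        assert result.eps_cal.value == pytest.approx(15907.1, rel=1e-3)
        assert result.eps_cal.u > 0

    def test_single_run_refused(self):
        runs = generate_calibration_runs(seed=5, n_runs=1)
        with pytest.raises(ValueError):
            calibrate(runs)
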