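"""Kinetic, thermal, ITC and SEC model fits with parameter-recovery checks."""

import numpy as np
import pytest

from filaquant import binding as B
from filaquant.simulate import AssaySimConfig, generate_assay_dataset


class TestCalibration:
    def test_exact_line(self):
        x = np.array([0.0, 5, 10, 20, 40])
        cal = B.calibrate_h2s(x, 3.0 * x + 7.0)
        assert cal.slope == pytest.approx(3.0)
        assert cal.intercept == pytest.approx(7.0)
        # line inversion maps responses back to concentrations
        np.testing.assert_allclose(cal.invert(cal.predict(x)), x, atol=1e-12)
        assert cal.invert(0.0) == pytest.approx(-7.0 / 3.0)

    def test_noisy_slope_within_10pct(self, rng):
        x = np.linspace(0, 50, 8)
        y = 2.0 * x + 1.0
        cal = B.calibrate_h2s(x, y + rng.normal(0, 0.05 * y.max(), y.shape))
        assert cal.slope == pytest.approx(2.0, rel=0.10)

    def test_singular_design(self):
        with pytest.raises(ValueError):
            B.calibrate_h2s([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMichaelisMenten:
    def test_noiseless_exact(self):
        s = np.array([1, 5, 10, 20, 40, 80.0])
        fit = B.fit_michaelis_menten(s, B.michaelis_menten(s, 10.0, 20.0))
        assert fit.vmax == pytest.approx(10.0, abs=1e-6)
        assert fit.km == pytest.approx(20.0, abs=1e-5)

    def test_half_max_at_km(self):
        assert B.michaelis_menten(20.0, 10.0, 20.0) == pytest.approx(5.0)

    def test_saturation_limit(self):
        cfg = AssaySimConfig(
            "michaelis_menten", B.MMParams(10.0, 0.3),
            np.array([0.1, 1.0, 300.0]), noise_sd=0.0,
        )
        df = generate_assay_dataset(cfg)
        assert df["response"].iloc[-1] == pytest.approx(10.0, rel=1e-3)

    def test_km_recovery_at_homocysteine_scale(self):
        s = np.array([0.05, 0.1, 0.2, 0.3, 0.6, 1.2, 2.5, 5.0])
        cfg = AssaySimConfig(
            "michaelis_menten", B.MMParams(10.0, 0.3), s,
            noise_sd=0.03 * 10.0, replicates=4, seed=0,
        )
        df = generate_assay_dataset(cfg)
        fit = B.fit_michaelis_menten(df["x"], df["response"])
        assert fit.km == pytest.approx(0.3, rel=0.15)


class TestHillActivation:
    def test_midpoint_identity(self):
        cfg = AssaySimConfig(
            "hill_activation",
            B.HillActivationParams(1.0, 2.0, 30.0, 3.0),
            np.array([0.0, 10.0, 30.0, 100.0, 1000.0]),
            noise_sd=0.0,
        )
        df = generate_assay_dataset(cfg)
        at_kact = df.loc[df["x"] == 30.0, "response"].iloc[0]
        assert at_kact == pytest.approx(1.5)  # midway between basal and max

    def test_hyperbolic_limit_recovers_n_of_one(self):
        s = np.array([0.0, 5, 10, 20, 40, 80, 160, 500.0])
        v = B.hill_activation(s, 1.0, 2.0, 30.0, 1.0)
        fit = B.fit_hill_activation(s, v)
        assert fit.n_hill == pytest.approx(1.0, abs=0.05)

    def test_hill_n1_equals_mm_with_zero_basal(self):
        s = np.linspace(1, 200, 40)
        hill = B.hill_activation(s, 1e-12, 10.0, 30.0, 1.0)
        mm = B.michaelis_menten(s, 10.0, 30.0)
        np.testing.assert_allclose(hill, mm, rtol=1e-9)

    def test_requires_zero_level(self):
        with pytest.raises(ValueError):
            B.fit_hill_activation([1, 2, 3, 4, 5.0], [1, 1, 1, 2, 2.0])


class TestThermalSigmoid:
    def test_noiseless_tm_exact(self):
        t = np.linspace(37, 62, 11)
        cfg = AssaySimConfig(
            "thermal_sigmoid", B.ThermalParams(1.0, 3.0, 49.5, 1.5), t,
            noise_sd=0.0,
        )
        df = generate_assay_dataset(cfg)
        fit = B.fit_thermal_sigmoid(df["x"], df["response"])
        assert fit.tm == pytest.approx(49.5, abs=1e-6)

    def test_inflection_is_plateau_mean(self):
        assert B.thermal_sigmoid(49.5, 1.0, 3.0, 49.5, 1.5) == pytest.approx(2.0)

    def test_tm_recovery_under_noise(self):
        t = np.linspace(37, 62, 11)
        for seed in range(20):
            cfg = AssaySimConfig(
                "thermal_sigmoid", B.ThermalParams(1.0, 3.0, 49.5, 1.5), t,
                noise_sd=0.05 * 3.0, replicates=4, seed=seed,
            )
            df = generate_assay_dataset(cfg)
            fit = B.fit_thermal_sigmoid(df["x"], df["response"])
            assert fit.tm == pytest.approx(49.5, abs=0.5)

    def test_monotone_data_without_inflection_errors(self):
        t = np.linspace(37, 62, 11)
        with pytest.raises((ValueError, RuntimeError)):
            B.fit_thermal_sigmoid(t, 0.01 * t + 1.0)


def _truth_design(cell_uM=60.0):
    des = B.ITCExperiment.standard_schedule(cell_conc_uM=cell_uM)
    sites = (
        B.ITCSiteClass(n=0.5, k=1 / 160e-9, dh=2.0),
        B.ITCSiteClass(n=0.5, k=1 / 600e-9, dh=-8.0),
    )
    return des, B.ITCTwoSetsParams(sites=sites)


class TestITCForwardModel:
    def test_zero_enthalpy_zero_heats(self):
        des, _ = _truth_design()
        params = B.ITCTwoSetsParams(
            sites=(B.ITCSiteClass(0.5, 1e7, 0.0), B.ITCSiteClass(0.5, 1e6, 0.0))
        )
        np.testing.assert_allclose(B.itc_model_heats(params, des), 0.0)

    def test_stoichiometric_titration_breakpoint(self):
        # one very tight site class: cumulative heat is two straight lines
        # meeting at molar ratio N1
        des = B.ITCExperiment.standard_schedule(cell_conc_uM=40.0)
        params = B.ITCTwoSetsParams(
            sites=(B.ITCSiteClass(0.5, 1e12, -10.0), B.ITCSiteClass(0.0, 1e6, 0.0))
        )
        heats = B.itc_model_heats(params, des)
        # molar ratio injected per injection (ignoring dilution, early phase)
        early = heats[1:10]
        assert np.ptp(early) / np.abs(early).max() < 0.02  # constant slope
        assert abs(heats[-1]) < 0.02 * abs(early.mean())  # saturated tail

    def test_total_heat_conservation(self):
        # integrated heat over a (near-instantly) saturating titration equals
        # V0 * M0 * sum(N_i dH_i): the dilution correction restores expelled
        # heat content, and with saturation in the first injection no site
        # is expelled unfilled
        des = B.ITCExperiment.standard_schedule(
            cell_conc_uM=40.0, syringe_conc_uM=50000.0
        )
        params = B.ITCTwoSetsParams(
            sites=(B.ITCSiteClass(0.5, 1e12, -5.0), B.ITCSiteClass(0.5, 1e11, -3.0))
        )
        total = B.itc_model_heats(params, des).sum()  # µcal
        expected = 200e-6 * 40e-6 * (0.5 * -5.0 + 0.5 * -3.0) * 1e9
        assert total == pytest.approx(expected, rel=0.01)

    def test_mass_balance(self):
        des, params = _truth_design()
        assert B.itc_mass_balance(params, des).max() < 1e-10


class TestITCFit:
    def test_noiseless_exact_recovery(self):
        des, truth = _truth_design()
        heats = B.itc_model_heats(truth, des)
        des.heats_ucal = heats
        fit = B.fit_itc_two_sets(des, blank_heats=[0.0])
        assert fit.sites[0].kd == pytest.approx(160e-9, rel=1e-4)
        assert fit.sites[1].kd == pytest.approx(600e-9, rel=1e-4)
        assert fit.sites[0].dh == pytest.approx(2.0, abs=1e-3)
        assert fit.sites[1].dh == pytest.approx(-8.0, abs=1e-3)
        # local optimality: fitted RSS no worse than RSS at the truth
        assert fit.rss <= 1e-9

    def test_thermodynamic_identity(self):
        des, truth = _truth_design()
        des.heats_ucal = B.itc_model_heats(truth, des)
        fit = B.fit_itc_two_sets(des, blank_heats=[0.0], share_n=True)
        for s in fit.sites:
            assert s.dg(fit.temperature_C) == pytest.approx(
                s.dh + s.minus_tds(fit.temperature_C), abs=1e-9
            )

    def test_requires_heats_and_enough_injections(self):
        des, truth = _truth_design()
        with pytest.raises(ValueError):
            B.fit_itc_two_sets(des)
        short = B.ITCExperiment(
            cell_volume_ul=200, cell_conc_uM=60, syringe_conc_uM=500,
            injection_volumes_ul=[0.8] * 5, heats_ucal=np.zeros(5),
        )
        with pytest.raises(ValueError):
            B.fit_itc_two_sets(short)


class TestSEC:
    def _calibration(self):
        # perfect log-linear law: log10(MW) = 6 - 3 * Kav
        v0, vt = 8.0, 20.0
        kavs = [0.15, 0.35, 0.55, 0.75]
        standards = [
            (10 ** (6 - 3 * k), v0 + k * (vt - v0)) for k in kavs
        ]
        return B.SECCalibration(v0_ml=v0, vt_ml=vt, standards=standards)

    def test_kav_definition(self):
        cal = self._calibration()
        assert cal.kav(8.0) == pytest.approx(0.0)
        assert cal.kav(20.0) == pytest.approx(1.0)

    def test_standard_maps_to_itself(self):
        cal = self._calibration()
        mw, ve = cal.standards[1]
        assert B.sec_mw_estimate(cal, ve)["mw"] == pytest.approx(mw, rel=1e-9)

    def test_midcurve_recovery_within_1pct(self):
        cal = self._calibration()
        kav = 0.45
        ve = 8.0 + kav * 12.0
        assert B.sec_mw_estimate(cal, ve)["mw"] == pytest.approx(
            10 ** (6 - 3 * kav), rel=0.01
        )

    def test_void_volume_flagged(self):
        cal = self._calibration()
        res = B.sec_mw_estimate(cal, 7.5)
        assert res["void"] and res["mw"] is None

    def test_extrapolation_flagged(self):
        cal = self._calibration()
        assert B.sec_mw_estimate(cal, 19.5)["extrapolated"]

    def test_invalid_standard_rejected(self):
        with pytest.raises(ValueError):
            B.SECCalibration(v0_ml=8.0, vt_ml=20.0, standards=[(1e5, 7.0)])


class TestAssaySimulator:
    def test_unknown_model_lists_supported(self):
        with pytest.raises(ValueError, match="michaelis_menten"):
            AssaySimConfig("weird", None, np.array([1.0, 2.0]))

    def test_noiseless_matches_forward_model(self):
        s = np.array([0.0, 10, 30, 100, 1000.0])
        truth = B.HillActivationParams(1.0, 2.0, 30.0, 3.0)
        df = generate_assay_dataset(
            AssaySimConfig("hill_activation", truth, s, noise_sd=0.0, replicates=2)
        )
        expected = B.hill_activation(s, 1.0, 2.0, 30.0, 3.0)
        for rep in (0, 1):
            np.testing.assert_array_equal(
                df.loc[df["replicate"] == rep, "response"].to_numpy(), expected
            )

    def test_seed_determinism(self):
        s = np.array([0.0, 10, 30.0])
        truth = B.HillActivationParams(1.0, 2.0, 30.0, 3.0)
        cfg = AssaySimConfig("hill_activation", truth, s, noise_sd=0.1, seed=5)
        a = generate_assay_dataset(cfg)
        b = generate_assay_dataset(cfg)
        assert a.equals(b)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            AssaySimConfig(
                "michaelis_menten", B.MMParams(1, 1), np.array([2.0, 1.0])
            )
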