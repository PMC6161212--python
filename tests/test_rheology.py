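"""Master-curve construction, Carreau–Yasuda and WLF fitting."""

import numpy as np
import pytest

import meltflow as mf
from meltflow.errors import FitError, OverlapError
from meltflow.synthetic import SaosSpec, make_saos_dataset


@pytest.fixture(scope="module")
def clean_sweeps():
    return make_saos_dataset(SaosSpec(noise_sigma=0.0))


class TestMasterCurve:
    def test_single_sweep_is_identity(self, polymer_truth):
        sweeps = make_saos_dataset(SaosSpec(noise_sigma=0.0, temperatures=(150.0,)))
        m = mf.build_master_curve(sweeps, t_ref=150.0)
        assert m.shift_factors == {150.0: 1.0}
        np.testing.assert_allclose(np.sort(m.omega_reduced), np.sort(sweeps[0].omega))
        np.testing.assert_allclose(np.sort(m.eta_star), np.sort(sweeps[0].eta_star))

    def test_noise_free_shift_recovery(self, clean_sweeps, polymer_truth):
        _, wlf = polymer_truth
        m = mf.build_master_curve(clean_sweeps, t_ref=150.0)
        for t, a in m.shift_factors.items():
            assert np.log10(a) == pytest.approx(wlf.log_at(t), abs=1e-3)

    def test_shift_factors_decrease_with_temperature(self, clean_sweeps):
        m = mf.build_master_curve(clean_sweeps, t_ref=150.0)
        temps = sorted(m.shift_factors)
        factors = [m.shift_factors[t] for t in temps]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_re_referencing_identity(self, clean_sweeps):
        m150 = mf.build_master_curve(clean_sweeps, t_ref=150.0)
        m160 = mf.build_master_curve(clean_sweeps, t_ref=160.0)
        for t in m150.shift_factors:
            expected = m150.shift_factors[t] / m150.shift_factors[160.0]
            assert np.log10(m160.shift_factors[t]) == pytest.approx(
                np.log10(expected), abs=2e-3
            )

    def test_master_residual_bounded_by_injected_noise(self):
        sigma = 0.02
        sweeps = make_saos_dataset(SaosSpec(noise_sigma=sigma, seed=3))
        m = mf.build_master_curve(sweeps, t_ref=150.0)
        cy = mf.fit_carreau_yasuda(m)
        # RMS log-residual of the merged curve stays at the noise floor
        assert cy.rms_log_residual <= 1.5 * sigma

    def test_t_ref_must_match_a_sweep(self, clean_sweeps):
        with pytest.raises(ValueError, match="t_ref"):
            mf.build_master_curve(clean_sweeps, t_ref=155.0)

    def test_disjoint_viscosity_ranges_raise_overlap_error(self):
        s1 = mf.FrequencySweep(150.0, np.geomspace(60, 1, 9),
                               np.geomspace(9000, 9900, 9))
        s2 = mf.FrequencySweep(190.0, np.geomspace(60, 1, 9),
                               np.geomspace(10, 90, 9))
        with pytest.raises(OverlapError, match="190"):
            mf.build_master_curve([s1, s2], t_ref=150.0)


class TestCarreauYasuda:
    def test_noise_free_refit_is_exact(self):
        truth = mf.FlowCurveFit(eta0=1e4, lam=1.0, a=2.0, n=0.3, t_ref=150.0)
        rates = np.geomspace(1e-3, 1e3, 25)
        res = mf.fit_carreau_yasuda((rates, mf.eval_viscosity(truth, rates)), t_ref=150.0)
        assert res.fit.eta0 == pytest.approx(1e4, rel=1e-6)
        assert res.fit.lam == pytest.approx(1.0, rel=1e-6)
        assert res.fit.a == pytest.approx(2.0, rel=1e-6)
        assert res.fit.n == pytest.approx(0.3, rel=1e-6)

    def test_zero_rate_limit_is_plateau(self):
        fit = mf.FlowCurveFit(eta0=1000.0, lam=2.0, a=1.5, n=0.4, t_ref=150.0)
        assert mf.eval_viscosity(fit, 0.0) == 1000.0

    def test_newtonian_ground_truth_stays_flat(self):
        truth = mf.FlowCurveFit(eta0=500.0, lam=1.0, a=2.0, n=1.0, t_ref=150.0)
        rates = np.geomspace(1e-2, 1e2, 12)
        with pytest.warns(UserWarning):  # no thinning to resolve
            res = mf.fit_carreau_yasuda((rates, mf.eval_viscosity(truth, rates)),
                                        t_ref=150.0)
        np.testing.assert_allclose(
            mf.eval_viscosity(res.fit, rates), 500.0, rtol=1e-6
        )

    def test_hand_evaluated_point(self):
        fit = mf.FlowCurveFit(eta0=1000.0, lam=1.0, a=2.0, n=0.5, t_ref=150.0)
        assert mf.eval_viscosity(fit, 1.0) == pytest.approx(1000.0 * 2 ** -0.25,
                                                            rel=1e-12)

    def test_negative_rate_rejected(self):
        fit = mf.FlowCurveFit(eta0=1000.0, lam=1.0, a=2.0, n=0.5, t_ref=150.0)
        with pytest.raises(ValueError):
            mf.eval_viscosity(fit, -1.0)

    def test_viscosity_non_increasing_in_rate(self):
        fit = mf.FlowCurveFit(eta0=1e4, lam=0.5, a=1.3, n=0.2, t_ref=150.0)
        eta = mf.eval_viscosity(fit, np.geomspace(1e-3, 1e4, 60))
        assert np.all(np.diff(eta) <= 1e-12)


class TestWLF:
    def test_reference_shift_is_unity(self):
        wlf = mf.WLFParams(c1=8.0, c2=120.0, t0=150.0)
        assert wlf.a_t(150.0) == 1.0

    def test_noise_free_refit(self):
        truth = mf.WLFParams(c1=8.0, c2=120.0, t0=150.0)
        temps = [120.0, 130.0, 140.0, 160.0, 170.0, 180.0]
        shifts = {t: float(truth.a_t(t)) for t in temps} | {150.0: 1.0}
        res = mf.fit_wlf(shifts, t0=150.0)
        assert res.params.c1 == pytest.approx(8.0, rel=1e-4)
        assert res.params.c2 == pytest.approx(120.0, rel=1e-4)

    def test_positive_constants_imply_decreasing_shifts(self):
        wlf = mf.WLFParams(c1=8.0, c2=120.0, t0=150.0)
        t = np.linspace(150.0, 200.0, 11)
        assert np.all(np.diff(wlf.log_at(t)) < 0)

    def test_too_few_temperatures_raise(self):
        with pytest.raises(FitError):
            mf.fit_wlf({150.0: 1.0, 160.0: 0.5, 170.0: 0.3}, t0=150.0)


class TestRoundTrip:
    def test_full_pipeline_recovers_all_parameters(self, polymer_truth):
        """TTS + CY + WLF on clean synthetic sweeps reproduces the generating
        six parameters to well under a percent."""
        cy_true, wlf_true = polymer_truth
        m = mf.build_master_curve(make_saos_dataset(SaosSpec(noise_sigma=0.0)), 150.0)
        cy = mf.fit_carreau_yasuda(m).fit
        wlf = mf.fit_wlf(m.shift_factors, t0=150.0).params
        assert cy.eta0 == pytest.approx(cy_true.eta0, rel=5e-3)
        assert cy.lam == pytest.approx(cy_true.lam, rel=5e-3)
        assert cy.a == pytest.approx(cy_true.a, rel=5e-3)
        assert cy.n == pytest.approx(cy_true.n, rel=5e-3)
        assert wlf.c1 == pytest.approx(wlf_true.c1, rel=2e-2)
        assert wlf.c2 == pytest.approx(wlf_true.c2, rel=2e-2)

    def test_off_reference_evaluation_matches_generator(self, polymer_truth):
        cy, wlf = polymer_truth
        sweeps = make_saos_dataset(SaosSpec(noise_sigma=0.0))
        for sw in sweeps:
            eta = mf.eval_viscosity_at(cy, wlf, sw.omega, sw.temperature)
            np.testing.assert_allclose(eta, sw.eta_star, rtol=1e-12)


def test_read_saos_csv_accepts_moduli(tmp_path):
    # |eta*| = sqrt(G'^2 + G''^2)/omega
    p = tmp_path / "saos.csv"
    p.write_text(
        "temperature_C,omega_rad_s,g_prime_Pa,g_double_prime_Pa\n"
        "150,10,300,400\n150,1,30,40\n"
    )
    sweeps = mf.read_saos_csv(p)
    assert len(sweeps) == 1
    np.testing.assert_allclose(sweeps[0].eta_star, [50.0, 50.0])
    np.testing.assert_allclose(sweeps[0].omega, [10.0, 1.0])
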