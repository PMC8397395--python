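"""Flory-Huggins liquidus: conversions, root solving and chi estimation."""

import numpy as np
import pytest

from asdsol import (
    ChiModel,
    ComponentConstants,
    DomainError,
    FHModel,
    NoSolutionError,
    SolubilityPoint,
    fit_fh_chi_constant,
    fit_fh_chi_temperature,
    liquidus_residual,
    liquidus_temperature,
    solubility_wtpct,
    solve_liquidus_phi,
    volfrac_to_wt,
    volume_ratio,
    wt_to_volfrac,
)
from asdsol.exceptions import ValidationError
from asdsol.synthetic import NoiseModel, SyntheticConfig, generate_fh_solubility_points


def scan_phi_oracle(temperature, model, n=100_000):
    """Brute-force sign-change scan over phi (independent of brentq path)."""
    phi = np.logspace(-6, 0, n)
    phi[-1] = 1.0 - 1e-12
    res = liquidus_residual(np.full_like(phi, temperature), phi, model)
    idx = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    assert idx.size > 0
    i = idx[-1]
    # Linear interpolation of the sign change (no shared code with solver).
    f0, f1 = res[i], res[i + 1]
    return phi[i] + (phi[i + 1] - phi[i]) * (-f0) / (f1 - f0)


class TestConversions:
    def test_volume_ratio_identical_components(self):
        c = ComponentConstants(tm0=400.0, dhfus=3e4, d_drug=1.2, d_poly=1.2,
                               mw_drug=300.0, mw_poly=300.0)
        assert volume_ratio(c) == pytest.approx(1.0, rel=1e-12)

    def test_volume_ratio_reference_system(self, constants):
        # (46000/1.20) / (308.3/1.41)
        assert volume_ratio(constants) == pytest.approx(175.3, abs=0.1)

    def test_volume_ratio_linear_in_polymer_mass(self, constants):
        doubled = ComponentConstants(tm0=constants.tm0, dhfus=constants.dhfus,
                                     d_drug=constants.d_drug, d_poly=constants.d_poly,
                                     mw_drug=constants.mw_drug,
                                     mw_poly=2 * constants.mw_poly)
        assert volume_ratio(doubled) == pytest.approx(2 * volume_ratio(constants), rel=1e-12)

    def test_wt_vol_roundtrip(self, constants):
        wt = np.linspace(0.0, 100.0, 21)
        np.testing.assert_allclose(
            volfrac_to_wt(wt_to_volfrac(wt, constants), constants), wt, atol=1e-12
        )

    def test_boundaries_and_equal_densities(self, constants):
        assert wt_to_volfrac(0.0, constants) == 0.0
        assert wt_to_volfrac(100.0, constants) == 1.0
        c = ComponentConstants(tm0=400.0, dhfus=3e4, d_drug=1.3, d_poly=1.3,
                               mw_drug=300.0, mw_poly=5e4)
        assert wt_to_volfrac(37.0, c) == pytest.approx(0.37, rel=1e-12)


class TestLiquidus:
    def test_pure_drug_anchor_for_any_chi(self, constants):
        for chi in (-2.0, 0.0, 1.5):
            model = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=chi))
            assert liquidus_residual(constants.tm0, 1.0, model) == pytest.approx(0.0, abs=1e-15)
            assert liquidus_temperature(1.0, model) == pytest.approx(constants.tm0, rel=1e-12)

    def test_phi_zero_rejected(self, fh_model_const):
        with pytest.raises(DomainError):
            liquidus_residual(350.0, 0.0, fh_model_const)

    def test_residual_affine_in_inverse_temperature(self, fh_model_const):
        # At fixed phi the residual is affine (hence strictly monotone) in 1/T.
        phi = 0.4
        inv_t = np.linspace(1.0 / 420.0, 1.0 / 280.0, 50)
        res = np.array([liquidus_residual(1.0 / it, phi, fh_model_const) for it in inv_t])
        slopes = np.diff(res) / np.diff(inv_t)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    @pytest.mark.parametrize("kind", ["constant", "linear_in_invT"])
    def test_closed_form_temperature_zeroes_residual(self, constants, kind):
        chi_model = (
            ChiModel(kind="constant", chi=-1.2)
            if kind == "constant"
            else ChiModel(kind="linear_in_invT", a_chi=6.7, b_chi=-3000.0)
        )
        model = FHModel(constants=constants, chi_model=chi_model)
        for phi in (0.1, 0.4, 0.8, 1.0):
            t = liquidus_temperature(phi, model)
            assert liquidus_residual(t, phi, model) == pytest.approx(0.0, abs=1e-12)

    def test_root_matches_scan_oracle(self, fh_model_ab):
        for t in (298.0, 340.0, 390.0):
            phi = solve_liquidus_phi(t, fh_model_ab)
            assert phi == pytest.approx(scan_phi_oracle(t, fh_model_ab), rel=1e-4)
            assert liquidus_residual(t, phi, fh_model_ab) == pytest.approx(0.0, abs=1e-12)

    def test_phi_approaches_one_below_melting(self, fh_model_const):
        # Near the anchor dphi/dT scales with the volume ratio m, so the
        # approach to phi = 1 is slow: ~m * (dHfus/R) * dT / Tm0^2.
        tm0 = fh_model_const.constants.tm0
        assert solve_liquidus_phi(tm0 - 1e-4, fh_model_const) == pytest.approx(1.0, abs=1e-3)
        assert solve_liquidus_phi(tm0 - 1e-3, fh_model_const) == pytest.approx(1.0, abs=1e-2)

    def test_above_melting_rejected(self, fh_model_const):
        with pytest.raises(DomainError):
            solve_liquidus_phi(430.0, fh_model_const)

    def test_no_root_reports_scan(self, constants):
        # A huge positive chi pushes the liquidus away: no root at low T.
        model = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=60.0))
        with pytest.raises(NoSolutionError) as excinfo:
            solve_liquidus_phi(250.0, model)
        assert excinfo.value.scan_summary["n_scan"] > 0


class TestFits:
    def _points(self, model, temps=(368, 373, 378, 383, 388, 393, 398), sd=0.0, seed=0):
        cfg = SyntheticConfig(seed=seed, noise=NoiseModel(solubility_wt_sd=sd))
        return generate_fh_solubility_points(model, np.asarray(temps, float), cfg)

    def test_constant_chi_roundtrip(self, constants):
        truth = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=-1.25))
        fit = fit_fh_chi_constant(self._points(truth), constants)
        assert fit.chi_model.chi == pytest.approx(-1.25, rel=1e-6)

    def test_single_point_on_known_liquidus(self, constants):
        truth = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=-0.9))
        wt = solubility_wtpct(380.0, truth)
        fit = fit_fh_chi_constant(
            [SolubilityPoint(temperature=380.0, wtpct_drug=wt),
             SolubilityPoint(temperature=380.0, wtpct_drug=wt)],
            constants,
        )
        assert fit.chi_model.chi == pytest.approx(-0.9, rel=1e-8)

    def test_chi_temperature_roundtrip(self, constants, fh_model_ab):
        fit = fit_fh_chi_temperature(self._points(fh_model_ab), constants)
        assert fit.chi_model.a_chi == pytest.approx(6.7, rel=1e-4)
        assert fit.chi_model.b_chi == pytest.approx(-3000.0, rel=1e-4)

    def test_fixed_b_self_consistency(self, constants, fh_model_ab):
        points = self._points(fh_model_ab)
        free = fit_fh_chi_temperature(points, constants)
        fixed = fit_fh_chi_temperature(points, constants, fixed_b_chi=free.chi_model.b_chi)
        assert fixed.chi_model.a_chi == pytest.approx(free.chi_model.a_chi, rel=1e-6)
        assert fixed.fit_report["b_chi_fixed"] is True

    def test_b_fixed_to_zero_degenerates_to_constant_chi(self, constants):
        truth = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=-1.1))
        points = self._points(truth)
        const_fit = fit_fh_chi_constant(points, constants)
        zero_b = fit_fh_chi_temperature(points, constants, fixed_b_chi=0.0)
        assert zero_b.chi_model.a_chi == pytest.approx(const_fit.chi_model.chi, rel=1e-8)

    def test_fitted_liquidus_keeps_pure_drug_anchor(self, constants, fh_model_ab):
        fit = fit_fh_chi_temperature(self._points(fh_model_ab), constants)
        assert liquidus_temperature(1.0, fit) == pytest.approx(constants.tm0, rel=1e-12)

    def test_predicted_solubility_increases_with_temperature(self, constants, fh_model_ab):
        fit = fit_fh_chi_temperature(self._points(fh_model_ab), constants)
        temps = np.linspace(368.0, 398.0, 7)
        wt = [solubility_wtpct(t, fit) for t in temps]
        assert np.all(np.diff(wt) > 0)

    def test_r_squared_reported(self, constants, fh_model_ab):
        fit = fit_fh_chi_temperature(self._points(fh_model_ab, sd=0.3, seed=7), constants)
        assert 0.9 < fit.fit_report["r_squared"] <= 1.0

    def test_collinear_temperatures_rejected(self, constants, fh_model_ab):
        wt = solubility_wtpct(380.0, fh_model_ab)
        points = [SolubilityPoint(temperature=380.0, wtpct_drug=wt + d) for d in (0, 0.5, 1.0)]
        from asdsol.exceptions import FitError

        with pytest.raises(FitError):
            fit_fh_chi_temperature(points, constants)

    def test_too_few_points_rejected(self, constants):
        with pytest.raises(ValidationError):
            fit_fh_chi_constant([SolubilityPoint(temperature=380.0, wtpct_drug=30.0)], constants)
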