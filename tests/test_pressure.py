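"""Pressure transpositions, combined fitting and isochronal pairing."""

import numpy as np
import pytest

from asdsol import (
    ChiModel,
    CompositionTgPoint,
    FHModel,
    GordonTaylorParams,
    PressureCondition,
    SolubilityPoint,
    VFTFit,
    combined_fh_fit,
    estimate_delta_tg,
    fit_fh_chi_constant,
    fit_fh_chi_temperature,
    isochronal_solubility_pairs,
    transpose_solubility_points,
    transpose_tg_curve,
)
from asdsol.datasets import tg_composition_points
from asdsol.exceptions import ValidationError
from asdsol.synthetic import NoiseModel, SyntheticConfig, generate_fh_solubility_points

GT = GordonTaylorParams(tg_drug=291.0, tg_poly=376.0, k=0.7)
COND = PressureCondition(pressure=50.0, tm0_at_p=435.0, delta_tg=12.0)


class TestTgCurveTransposition:
    def test_zero_shift_is_identity(self):
        curve = transpose_tg_curve(GT, PressureCondition(50.0, 435.0, 0.0))
        for w in (0.0, 0.3, 1.0):
            assert curve.predict(w) == GT.predict(w)

    def test_pure_drug_shifts_by_12K(self):
        curve = transpose_tg_curve(GT, COND)
        assert curve.predict(0.0) == pytest.approx(291.0 + 12.0, rel=1e-12)

    def test_inversion_shift_equivariance(self):
        curve = transpose_tg_curve(GT, COND)
        for tg in (310.0, 330.0, 350.0):
            assert curve.invert(tg + 12.0) == pytest.approx(GT.invert(tg), abs=1e-12)


class TestDeltaTgEstimate:
    def test_exact_constant_offset(self):
        ambient = [CompositionTgPoint(w_drug=w, tg=t) for w, t in
                   [(0.8, 302.0), (0.6, 320.0), (0.45, 334.0)]]
        pressurized = [CompositionTgPoint(w_drug=p.w_drug, tg=p.tg + 12.0, pressure=50.0)
                       for p in ambient]
        est = estimate_delta_tg(ambient, pressurized)
        assert est.delta_tg == pytest.approx(12.0, abs=1e-12)
        assert est.spread == 0.0
        assert est.is_constant

    def test_published_pairs_give_12K(self):
        est = estimate_delta_tg(
            tg_composition_points("bds"), tg_composition_points("50mpa")
        )
        assert est.delta_tg == pytest.approx(12.0, abs=1e-9)
        assert est.spread == pytest.approx(0.0, abs=1e-9)

    def test_nonconstant_offsets_flagged(self):
        ambient = [CompositionTgPoint(w_drug=w, tg=t) for w, t in
                   [(0.8, 302.0), (0.6, 320.0)]]
        pressurized = [
            CompositionTgPoint(w_drug=0.8, tg=312.0, pressure=50.0),
            CompositionTgPoint(w_drug=0.6, tg=336.0, pressure=50.0),
        ]
        est = estimate_delta_tg(ambient, pressurized)
        assert est.delta_tg == pytest.approx(13.0)
        assert est.spread == pytest.approx(6.0)
        assert not est.is_constant

    def test_no_matches_rejected(self):
        with pytest.raises(ValidationError):
            estimate_delta_tg(
                [CompositionTgPoint(w_drug=0.8, tg=302.0)],
                [CompositionTgPoint(w_drug=0.5, tg=330.0, pressure=50.0)],
            )


class TestSolubilityTransposition:
    def test_equal_melting_points_identity(self):
        points = [SolubilityPoint(temperature=398.0, wtpct_drug=36.0, pressure=50.0)]
        shifted = transpose_solubility_points(points, 421.0, 421.0)
        assert shifted[0].temperature == 398.0

    def test_melting_point_difference_shift(self):
        points = [SolubilityPoint(temperature=398.0, wtpct_drug=36.0, pressure=50.0)]
        shifted = transpose_solubility_points(points, 421.0, 435.0)
        assert shifted[0].temperature == pytest.approx(384.0, rel=1e-12)
        assert shifted[0].wtpct_drug == 36.0

    def test_double_shift_is_identity(self):
        points = [SolubilityPoint(temperature=t, wtpct_drug=w, pressure=50.0)
                  for t, w in [(368.0, 29.0), (398.0, 36.0)]]
        back = transpose_solubility_points(
            transpose_solubility_points(points, 421.0, 435.0), 435.0, 421.0
        )
        for orig, rt in zip(points, back):
            assert rt.temperature == pytest.approx(orig.temperature, abs=1e-12)

    def test_compositions_preserved_and_shift_constant(self):
        points = [SolubilityPoint(temperature=t, wtpct_drug=w, pressure=50.0)
                  for t, w in [(368.0, 29.0), (378.0, 31.0), (398.0, 36.0)]]
        shifted = transpose_solubility_points(points, 421.0, 435.0)
        shifts = [s.temperature - p.temperature for s, p in zip(shifted, points)]
        assert np.ptp(shifts) == 0.0
        assert [s.wtpct_drug for s in shifted] == [p.wtpct_drug for p in points]


class TestCombinedFit:
    def test_empty_pressure_set_equals_ambient_fit(self, constants):
        truth = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=-1.2))
        cfg = SyntheticConfig(seed=0, noise=NoiseModel(solubility_wt_sd=0.0))
        ambient = generate_fh_solubility_points(truth, np.arange(368.0, 399.0, 5.0), cfg)
        alone = fit_fh_chi_constant(ambient, constants)
        combined = combined_fh_fit(ambient, [], COND, constants, mode="chi_constant")
        assert combined.chi_model.chi == pytest.approx(alone.chi_model.chi, rel=1e-12)

    def test_recovers_generating_model_from_two_pressures(self, constants, fh_model_ab):
        # High-pressure points generated on the vertically shifted liquidus
        # must, after transposition, refit to the generating parameters.
        cfg = SyntheticConfig(seed=0, noise=NoiseModel(solubility_wt_sd=0.0))
        ambient = generate_fh_solubility_points(fh_model_ab, np.arange(368.0, 399.0, 5.0), cfg)
        shift = COND.tm0_at_p - constants.tm0
        hp_truth_temps = np.array([368.0, 378.0, 388.0, 398.0])
        hp = [
            SolubilityPoint(temperature=t, wtpct_drug=p.wtpct_drug, pressure=50.0)
            for t, p in zip(
                hp_truth_temps,
                generate_fh_solubility_points(fh_model_ab, hp_truth_temps - shift, cfg),
            )
        ]
        fit = combined_fh_fit(ambient, hp, COND, constants, mode="chi_temperature")
        assert fit.chi_model.a_chi == pytest.approx(6.7, rel=1e-5)
        assert fit.chi_model.b_chi == pytest.approx(-3000.0, rel=1e-5)

    def test_fixed_b_mode_requires_value(self, constants):
        with pytest.raises(ValidationError):
            combined_fh_fit(
                [SolubilityPoint(temperature=380.0, wtpct_drug=30.0)] * 2,
                [], COND, constants, mode="fixed_b",
            )


class TestIsochronalPairs:
    AMBIENT_FIT = VFTFit(tau_inf=1e-14, b_vft=2000.0, t0=250.0)
    HP_FIT = VFTFit(tau_inf=1e-14, b_vft=2000.0, t0=262.0)

    def _solubilities(self):
        return {
            0.1: [SolubilityPoint(temperature=t, wtpct_drug=w)
                  for t, w in [(368.0, 32.0), (383.0, 37.0), (398.0, 49.0)]],
            50.0: [SolubilityPoint(temperature=t, wtpct_drug=w, pressure=50.0)
                   for t, w in [(368.0, 29.0), (398.0, 36.0)]],
        }

    def test_identical_fits_identical_temperatures(self):
        records = isochronal_solubility_pairs(
            {0.1: self.AMBIENT_FIT, 50.0: self.AMBIENT_FIT},
            self._solubilities(), [1e-6],
        )
        temps = [e["temperature_K"] for e in records[0].entries]
        assert temps[0] == pytest.approx(temps[1], rel=1e-12)

    def test_equal_tau_preserves_constructed_solubility(self):
        # Construction: HP curve is the ambient curve shifted +12 K and the
        # HP solubility at T+12 equals the ambient solubility at T, so the
        # isochronal pairing reads out equal solubility at both pressures.
        tau_star = self.AMBIENT_FIT.tau(383.0)
        ambient_points = [SolubilityPoint(temperature=383.0, wtpct_drug=37.0)]
        hp_points = [SolubilityPoint(temperature=395.0, wtpct_drug=37.0, pressure=50.0)]
        records = isochronal_solubility_pairs(
            {0.1: self.AMBIENT_FIT, 50.0: self.HP_FIT},
            {0.1: ambient_points, 50.0: hp_points}, [tau_star],
        )
        wts = [e["wtpct_drug"] for e in records[0].entries]
        assert wts[0] == pytest.approx(wts[1], abs=1e-9)

    def test_larger_tau_lower_temperature_everywhere(self):
        records = isochronal_solubility_pairs(
            {0.1: self.AMBIENT_FIT, 50.0: self.HP_FIT},
            self._solubilities(), [1e-6, 1e-3, 1.0],
        )
        for i in range(2):
            for j in range(2):
                assert (records[i + 1].entries[j]["temperature_K"]
                        < records[i].entries[j]["temperature_K"])

    def test_out_of_range_tau_flagged_not_fatal(self):
        records = isochronal_solubility_pairs(
            {0.1: self.AMBIENT_FIT, 50.0: self.HP_FIT},
            self._solubilities(), [1e3],
        )
        entry = records[0].entries[0]
        assert not entry["in_range"] and entry["wtpct_drug"] is None

    def test_interpolation_flagged(self):
        tau_star = self.AMBIENT_FIT.tau(375.0)
        records = isochronal_solubility_pairs(
            {0.1: self.AMBIENT_FIT, 50.0: self.HP_FIT},
            self._solubilities(), [tau_star],
        )
        amb = records[0].entries[0]
        assert amb["interpolated"] and 32.0 < amb["wtpct_drug"] < 37.0

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            isochronal_solubility_pairs({0.1: self.AMBIENT_FIT}, {}, [1e-6])
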