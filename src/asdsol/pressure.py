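"""Elevated-pressure operations of the solubility protocol.

Moderate hydrostatic pressure raises both the glass transition of the
amorphous mixture and the melting point of the crystalline drug, while
the shape of the composition-Tg curve and the liquidus are, to a good
approximation, preserved.  This module implements the two vertical
transpositions built on that observation:

* the ambient composition-Tg curve is shifted up by a constant
  delta_Tg (estimated from compositions measured at both pressures) and
  inverted at pressure with the shifted curve;
* high-pressure solubility points are shifted down by the difference of
  the pure-drug melting points and pooled with ambient points for a
  combined Flory-Huggins fit (constant chi, chi(T) = A + B/T, or A-only
  with B fixed at the ambient value).

It also pairs (T, P) conditions that share the same alpha-relaxation
time (isochronal conditions) with the solubility measured there, the
comparison used to argue that equal relaxation times preserve the
solubility level across pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .flory import (
    ComponentConstants,
    FHModel,
    SolubilityPoint,
    fit_fh_chi_constant,
    fit_fh_chi_temperature,
)
from .mixing import CompositionTgPoint, GordonTaylorParams, gt_invert, gt_predict
from .vft import VFTFit, isochrone_temperature

__all__ = [
    "PressureCondition",
    "ShiftedTgCurve",
    "DeltaTgEstimate",
    "IsochronalRecord",
    "transpose_tg_curve",
    "estimate_delta_tg",
    "transpose_solubility_points",
    "combined_fh_fit",
    "isochronal_solubility_pairs",
]


@dataclass
class PressureCondition:
    """An elevated-pressure condition relative to ambient."""

    pressure: float  # MPa
    tm0_at_p: float  # K, pure-drug melting point at this pressure
    delta_tg: float  # K, constant Tg offset versus ambient

    def __post_init__(self):
        if not np.isfinite(self.delta_tg):
            raise ValidationError("delta_tg must be finite")


@dataclass
class ShiftedTgCurve:
    """The ambient Gordon-Taylor curve displaced vertically by delta_tg.

    A vertically shifted Gordon-Taylor curve is not itself of
    Gordon-Taylor form, so the shift is kept explicit: prediction adds
    delta_tg, inversion subtracts it before inverting the ambient curve.
    """

    base: GordonTaylorParams
    delta_tg: float  # K

    def predict(self, w_poly):
        return gt_predict(self.base, w_poly) + self.delta_tg

    def invert(self, tg_observed: float) -> float:
        return gt_invert(self.base, tg_observed - self.delta_tg)


def transpose_tg_curve(ambient: GordonTaylorParams, condition: PressureCondition) -> ShiftedTgCurve:
    """Composition-Tg mapping at pressure: the ambient curve + delta_tg."""
    return ShiftedTgCurve(base=ambient, delta_tg=condition.delta_tg)


@dataclass
class DeltaTgEstimate:
    """Constant Tg offset between pressures with a constancy diagnostic."""

    delta_tg: float  # K, least-squares (mean) offset
    spread: float  # K, max - min of per-composition offsets
    offsets: dict = field(default_factory=dict)  # w_drug -> offset (K)

    @property
    def is_constant(self) -> bool:
        return self.spread < 1.0


def estimate_delta_tg(
    ambient_points, pressure_points, match_tol: float = 1e-6
) -> DeltaTgEstimate:
    """Least-squares constant offset between Tg's matched by composition.

    The least-squares constant shift is the mean of the per-composition
    offsets; their spread (max - min) is reported so a genuinely
    non-constant pressure effect is visible rather than silently
    averaged away.
    """
    ambient = {round(p.w_drug, 9): p for p in ambient_points}
    offsets = {}
    for hp in pressure_points:
        for w, ap in ambient.items():
            if abs(hp.w_drug - ap.w_drug) <= match_tol:
                offsets[ap.w_drug] = hp.tg - ap.tg
    if not offsets:
        raise ValidationError("no compositions measured at both pressures")
    values = np.array(list(offsets.values()))
    return DeltaTgEstimate(
        delta_tg=float(values.mean()),
        spread=float(np.ptp(values)),
        offsets=offsets,
    )


def transpose_solubility_points(
    points, tm0_ambient: float, tm0_at_p: float
) -> list[SolubilityPoint]:
    """Shift high-pressure solubility points to the ambient reference.

    Each temperature moves by (tm0_ambient - tm0_at_p), the difference
    of the pure-drug melting points; compositions are unchanged.
    """
    shift = tm0_ambient - tm0_at_p
    return [
        SolubilityPoint(
            temperature=p.temperature + shift,
            wtpct_drug=p.wtpct_drug,
            pressure=0.1,
        )
        for p in points
    ]


def combined_fh_fit(
    ambient_points,
    pressure_points,
    condition: PressureCondition,
    constants: ComponentConstants,
    mode: str = "chi_temperature",
    fixed_b_chi: float | None = None,
) -> FHModel:
    """Pooled Flory-Huggins fit of ambient + transposed pressure points.

    ``mode`` selects the chi model: ``chi_constant``, ``chi_temperature``
    or ``fixed_b`` (A fitted with B held at ``fixed_b_chi``, typically
    the ambient-only fitted value).  The pressure points are first
    transposed to the ambient reference via the melting-point
    difference; ``constants`` are the ambient ones.
    """
    pooled = list(ambient_points) + transpose_solubility_points(
        pressure_points, constants.tm0, condition.tm0_at_p
    )
    if not pooled:
        raise ValidationError("empty pooled data set")
    if mode == "chi_constant":
        return fit_fh_chi_constant(pooled, constants)
    if mode == "chi_temperature":
        return fit_fh_chi_temperature(pooled, constants)
    if mode == "fixed_b":
        if fixed_b_chi is None:
            raise ValidationError("fixed_b mode requires fixed_b_chi")
        return fit_fh_chi_temperature(pooled, constants, fixed_b_chi=fixed_b_chi)
    raise ValidationError(f"unknown mode {mode!r}")


@dataclass
class IsochronalRecord:
    """Solubility at the (T, P) states sharing one relaxation time."""

    tau_s: float
    entries: list = field(default_factory=list)
    # each entry: {pressure_MPa, temperature_K, wtpct_drug or None,
    #              interpolated: bool, in_range: bool}


def isochronal_solubility_pairs(
    fits_by_condition: dict,
    solubilities_by_condition: dict,
    tau_targets,
) -> list[IsochronalRecord]:
    """Tabulate isochronal (T, P) states and the solubility measured there.

    For each target tau, the temperature at each pressure comes from the
    corresponding VFT fit; the solubility at that temperature is taken
    from the measured points of that pressure, linearly interpolated in
    T when the temperature falls between annealing points.  Temperatures
    outside the measured range are flagged (``in_range`` False,
    solubility None) rather than extrapolated.
    """
    if len(fits_by_condition) < 2:
        raise ValidationError("need fits for at least 2 pressure conditions")
    records = []
    for tau in tau_targets:
        record = IsochronalRecord(tau_s=float(tau))
        for pressure, fit in sorted(fits_by_condition.items()):
            temperature = isochrone_temperature(fit, tau)
            entry = {
                "pressure_MPa": float(pressure),
                "temperature_K": float(temperature),
                "wtpct_drug": None,
                "interpolated": False,
                "in_range": False,
            }
            points = sorted(
                solubilities_by_condition.get(pressure, []), key=lambda p: p.temperature
            )
            if points:
                t_arr = np.array([p.temperature for p in points])
                w_arr = np.array([p.wtpct_drug for p in points])
                if t_arr[0] <= temperature <= t_arr[-1]:
                    entry["in_range"] = True
                    exact = np.isclose(t_arr, temperature, atol=1e-9)
                    if np.any(exact):
                        entry["wtpct_drug"] = float(w_arr[exact][0])
                    else:
                        entry["wtpct_drug"] = float(np.interp(temperature, t_arr, w_arr))
                        entry["interpolated"] = True
            record.entries.append(entry)
        records.append(record)
    return records
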