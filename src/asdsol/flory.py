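"""Flory-Huggins solid-liquid line for drug solubility in a polymer.

Melting-point depression of a crystalline drug dissolved in a polymer is
described by the Flory-Huggins lattice model.  A composition with drug
volume fraction phi melts at the temperature Tm satisfying

    (1/Tm - 1/Tm0) + (R/dHfus) * [ ln(phi) + (1 - 1/m)(1 - phi)
                                   + chi(T) (1 - phi)^2 ] = 0

with Tm0 and dHfus the melting point and fusion enthalpy of the pure
drug, m the polymer/drug molar-volume ratio

    m = (Mw_poly / d_poly) / (Mw_drug / d_drug),

and chi the interaction parameter, modeled either as a constant
(approach I) or as chi(T) = A + B/T (approach II; A and B carry the
entropic and enthalpic contributions).  Annealing experiments give
points (T, wt%) on this liquidus: the equilibrium drug content at the
annealing temperature.  Fitting chi (or A, B) to those points and
solving the liquidus at a lower temperature extrapolates the solubility
limit to storage conditions.

Because the relation is affine in 1/T for both chi models, the liquidus
temperature at fixed phi has a closed form, and the fits minimize
unweighted temperature residuals (predicted liquidus T at each point's
composition minus the observed annealing T) by Levenberg-Marquardt.
The pure-drug anchor (phi = 1 melts at Tm0) holds for every chi by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, FitError, NoSolutionError, ValidationError

__all__ = [
    "GAS_CONSTANT",
    "ComponentConstants",
    "ChiModel",
    "SolubilityPoint",
    "FHModel",
    "volume_ratio",
    "wt_to_volfrac",
    "volfrac_to_wt",
    "liquidus_residual",
    "liquidus_temperature",
    "solve_liquidus_phi",
    "solubility_wtpct",
    "fit_fh_chi_constant",
    "fit_fh_chi_temperature",
]

#: Molar gas constant R in J/(mol K).
GAS_CONSTANT = 8.314


@dataclass
class ComponentConstants:
    """Pure-component constants of the drug-polymer pair at one pressure."""

    tm0: float  # K, pure-drug melting point at the working pressure
    dhfus: float  # J/mol, enthalpy of fusion of the pure drug
    d_drug: float  # g/cm^3, true density
    d_poly: float  # g/cm^3
    mw_drug: float  # g/mol
    mw_poly: float  # g/mol
    r_gas: float = GAS_CONSTANT  # J/(mol K)

    def __post_init__(self):
        for name in ("tm0", "dhfus", "d_drug", "d_poly", "mw_drug", "mw_poly", "r_gas"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class ChiModel:
    """Interaction-parameter model: constant chi or chi(T) = A + B/T."""

    kind: str  # {"constant", "linear_in_invT"}
    chi: float | None = None
    a_chi: float | None = None  # dimensionless A
    b_chi: float | None = None  # K (enthalpic B; unrelated to the VFT B)
    uncertainties: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "constant":
            if self.chi is None:
                raise ValidationError("constant ChiModel needs chi")
        elif self.kind == "linear_in_invT":
            if self.a_chi is None or self.b_chi is None:
                raise ValidationError("linear_in_invT ChiModel needs a_chi and b_chi")
        else:
            raise ValidationError(f"unknown ChiModel kind {self.kind!r}")

    def chi_at(self, temperature):
        """Evaluate chi at temperature T (K)."""
        if self.kind == "constant":
            return self.chi if np.ndim(temperature) == 0 else np.full_like(
                np.asarray(temperature, dtype=float), self.chi
            )
        return self.a_chi + self.b_chi / np.asarray(temperature, dtype=float)


@dataclass
class SolubilityPoint:
    """One solubility-limit datum: annealing T is the liquidus Tm of the
    equilibrium composition reached during annealing."""

    temperature: float  # K
    wtpct_drug: float  # weight percent drug
    pressure: float = 0.1  # MPa

    def __post_init__(self):
        if not 0.0 < self.wtpct_drug < 100.0:
            raise ValidationError(
                f"wtpct_drug must be in (0, 100), got {self.wtpct_drug}"
            )
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive")


def volume_ratio(constants: ComponentConstants) -> float:
    """Polymer/drug molar-volume ratio m = (Mw2/d2) / (Mw1/d1)."""
    return (constants.mw_poly / constants.d_poly) / (constants.mw_drug / constants.d_drug)


def wt_to_volfrac(wtpct_drug, constants: ComponentConstants):
    """Drug weight percent -> volume fraction phi (amorphous true densities)."""
    w = np.asarray(wtpct_drug, dtype=float) / 100.0
    if np.any(w < 0) or np.any(w > 1):
        raise ValidationError("wtpct_drug must be in [0, 100]")
    phi = (w / constants.d_drug) / (w / constants.d_drug + (1.0 - w) / constants.d_poly)
    return float(phi) if np.ndim(wtpct_drug) == 0 else phi


def volfrac_to_wt(phi, constants: ComponentConstants):
    """Volume fraction phi -> drug weight percent; exact inverse of
    :func:`wt_to_volfrac`."""
    p = np.asarray(phi, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("phi must be in [0, 1]")
    w = (p * constants.d_drug) / (p * constants.d_drug + (1.0 - p) * constants.d_poly)
    out = 100.0 * w
    return float(out) if np.ndim(phi) == 0 else out


@dataclass
class FHModel:
    """A parameterized Flory-Huggins liquidus: constants + chi model."""

    constants: ComponentConstants
    chi_model: ChiModel
    m: float = None  # derived volume ratio
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m is None:
            self.m = volume_ratio(self.constants)

    def liquidus_temperature(self, phi):
        return liquidus_temperature(phi, self)

    def solubility_wtpct(self, temperature):
        return solubility_wtpct(temperature, self)


def _mixing_term(phi, m, chi):
    return np.log(phi) + (1.0 - 1.0 / m) * (1.0 - phi) + chi * (1.0 - phi) ** 2


def liquidus_residual(temperature, phi, model: FHModel):
    """Residual of the melting-point-depression relation; zero on the liquidus."""
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(phi, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("phi must be in (0, 1] (ln phi diverges at 0)")
    if np.any(t <= 0):
        raise DomainError("temperature must be positive")
    c = model.constants
    chi = model.chi_model.chi_at(t)
    out = (1.0 / t - 1.0 / c.tm0) + (c.r_gas / c.dhfus) * _mixing_term(p, model.m, chi)
    if np.ndim(temperature) == 0 and np.ndim(phi) == 0:
        return float(out)
    return out


def liquidus_temperature(phi, model: FHModel):
    """Melting temperature of the composition with drug volume fraction phi.

    Closed form: the liquidus relation is affine in 1/T for both chi
    models.  For chi(T) = A + B/T the B term is collected on the 1/T
    side.  Raises :class:`DomainError` when the composition has no
    physical melting point under the model (non-positive 1/T).
    """
    p = np.asarray(phi, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("phi must be in (0, 1]")
    c = model.constants
    r_over_h = c.r_gas / c.dhfus
    if model.chi_model.kind == "constant":
        inv_t = 1.0 / c.tm0 - r_over_h * _mixing_term(p, model.m, model.chi_model.chi)
    else:
        base = 1.0 / c.tm0 - r_over_h * _mixing_term(p, model.m, model.chi_model.a_chi)
        coef = 1.0 + r_over_h * model.chi_model.b_chi * (1.0 - p) ** 2
        inv_t = base / coef
    if np.any(inv_t <= 0):
        raise DomainError("no physical liquidus temperature for this composition")
    out = 1.0 / inv_t
    return float(out) if np.ndim(phi) == 0 else out


def solve_liquidus_phi(
    temperature: float, model: FHModel, n_scan: int = 10_000, phi_min: float = 1e-8
) -> float:
    """Drug volume fraction on the liquidus at ``temperature``.

    Scans log-spaced phi in (phi_min, 1), takes the sign change closest
    to phi = 1 (the drug-rich solubility branch), and polishes it with
    Brent's method.  Raises :class:`NoSolutionError` when the residual
    never changes sign.
    """
    c = model.constants
    if temperature >= c.tm0:
        raise DomainError(
            f"T = {temperature} K must lie below the pure-drug melting point {c.tm0} K"
        )
    grid = np.logspace(math.log10(phi_min), 0.0, n_scan)
    grid[-1] = 1.0 - 1e-12
    res = liquidus_residual(np.full_like(grid, temperature), grid, model)
    sign_change = np.nonzero(np.diff(np.sign(res)) != 0)[0]
    if sign_change.size == 0:
        raise NoSolutionError(
            f"no liquidus root at T = {temperature} K",
            scan_summary={
                "phi_range": (float(grid[0]), float(grid[-1])),
                "residual_range": (float(np.min(res)), float(np.max(res))),
                "n_scan": n_scan,
            },
        )
    i = int(sign_change[-1])
    return brentq(
        lambda p: liquidus_residual(temperature, p, model),
        grid[i],
        grid[i + 1],
        xtol=1e-14,
        rtol=1e-14,
    )


def solubility_wtpct(temperature: float, model: FHModel) -> float:
    """Equilibrium drug content (wt%) at ``temperature`` from the liquidus."""
    phi = solve_liquidus_phi(temperature, model)
    return volfrac_to_wt(phi, model.constants)


def _temperature_residuals(points, model: FHModel):
    phis = np.array([wt_to_volfrac(p.wtpct_drug, model.constants) for p in points])
    t_obs = np.array([p.temperature for p in points])
    return liquidus_temperature(phis, model) - t_obs


def _fit_report(residual, params, extra=None):
    t_res = np.asarray(residual)
    report = {
        "r_squared": None,
        "residual_rms_K": float(np.sqrt(np.mean(t_res**2))),
        "n_points": int(t_res.size),
    }
    report.update(extra or {})
    return report


def _r_squared(points, model: FHModel) -> float:
    """1 - SS_res/SS_tot on the temperature residuals."""
    t_obs = np.array([p.temperature for p in points])
    res = _temperature_residuals(points, model)
    ss_tot = float(np.sum((t_obs - t_obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum(res**2)) / ss_tot


def fit_fh_chi_constant(points, constants: ComponentConstants) -> FHModel:
    """Approach I: fit a single chi to solubility points.

    Unweighted Levenberg-Marquardt on temperature residuals with a
    chi-square tolerance of 1e-9.
    """
    points = list(points)
    if len(points) < 2:
        raise ValidationError("constant-chi fitting needs at least 2 points")

    params = lmfit.Parameters()
    params.add("chi", value=0.0)

    def residual(p):
        model = FHModel(constants=constants, chi_model=ChiModel(kind="constant", chi=p["chi"].value))
        return _temperature_residuals(points, model)

    result = lmfit.minimize(residual, params, method="leastsq", ftol=1e-9, xtol=1e-9)
    if not result.success:
        raise FitError(f"constant-chi fit did not converge: {result.message}")
    chi = float(result.params["chi"].value)
    stderr = result.params["chi"].stderr
    model = FHModel(
        constants=constants,
        chi_model=ChiModel(
            kind="constant",
            chi=chi,
            uncertainties={"chi": float(stderr) if stderr is not None else None},
        ),
    )
    model.fit_report = _fit_report(result.residual, result.params)
    model.fit_report["r_squared"] = _r_squared(points, model)
    return model


def fit_fh_chi_temperature(
    points, constants: ComponentConstants, fixed_b_chi: float | None = None
) -> FHModel:
    """Approach II: fit chi(T) = A + B/T to solubility points.

    With ``fixed_b_chi`` the enthalpic B is held at the supplied value
    and only A is fitted (>= 2 points); otherwise A and B are fitted
    jointly (>= 3 points).  Same solver settings as approach I.
    """
    points = list(points)
    n_min = 2 if fixed_b_chi is not None else 3
    if len(points) < n_min:
        raise ValidationError(f"chi(T) fitting needs at least {n_min} points")
    t_obs = np.array([p.temperature for p in points])
    if fixed_b_chi is None and np.ptp(t_obs) < 1e-6:
        raise FitError("collinear input: all points at (nearly) one temperature")

    params = lmfit.Parameters()
    params.add("a_chi", value=0.0)
    params.add(
        "b_chi",
        value=fixed_b_chi if fixed_b_chi is not None else -1000.0,
        vary=fixed_b_chi is None,
    )

    def residual(p):
        model = FHModel(
            constants=constants,
            chi_model=ChiModel(
                kind="linear_in_invT", a_chi=p["a_chi"].value, b_chi=p["b_chi"].value
            ),
        )
        return _temperature_residuals(points, model)

    result = lmfit.minimize(residual, params, method="leastsq", ftol=1e-9, xtol=1e-9)
    if not result.success:
        raise FitError(f"chi(T) fit did not converge: {result.message}")
    p = result.params
    unc = {
        "a_chi": float(p["a_chi"].stderr) if p["a_chi"].stderr is not None else None,
        "b_chi": float(p["b_chi"].stderr)
        if (fixed_b_chi is None and p["b_chi"].stderr is not None)
        else None,
    }
    model = FHModel(
        constants=constants,
        chi_model=ChiModel(
            kind="linear_in_invT",
            a_chi=float(p["a_chi"].value),
            b_chi=float(p["b_chi"].value),
            uncertainties=unc,
        ),
    )
    model.fit_report = _fit_report(
        result.residual, result.params, extra={"b_chi_fixed": fixed_b_chi is not None}
    )
    model.fit_report["r_squared"] = _r_squared(points, model)
    return model
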