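"""Vogel-Fulcher-Tammann parameterization of alpha-relaxation times.

Supercooled liquids show super-Arrhenius slowing of the structural
relaxation time, described empirically by

    tau(T) = tau_inf * exp(B / (T - T0))

with attempt time tau_inf, activation-like parameter B (K) and Vogel
temperature T0.  The glass-transition temperature is defined
isochronally as the temperature where tau_alpha reaches 100 s, obtained
in closed form:

    Tg = T0 + B / ln(tau_ref / tau_inf),   tau_ref = 100 s.

For a condition where too few relaxation times could be measured to fit
the VFT law, a well-parameterized reference curve is displaced
horizontally until it passes through the one available (T, tau) anchor,
and the reference Tg is shifted by the same amount
(:func:`horizontal_shift_tg`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exceptions import DomainError, FitError, ValidationError

__all__ = [
    "RelaxationSeries",
    "VFTFit",
    "vft_tau",
    "fit_vft",
    "extrapolate_tg",
    "isochrone_temperature",
    "horizontal_shift_tg",
    "TG_TAU_REFERENCE_S",
]

#: Isochronal definition of the glass transition: Tg = T(tau_alpha = 100 s).
TG_TAU_REFERENCE_S = 100.0


@dataclass
class RelaxationSeries:
    """tau_alpha(T) for one composition at one pressure."""

    temperature: np.ndarray  # K
    tau_alpha: np.ndarray  # s
    pressure: float = 0.1  # MPa
    composition_label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.tau_alpha = np.asarray(self.tau_alpha, dtype=float)
        if self.temperature.size != self.tau_alpha.size:
            raise ValidationError("temperature and tau_alpha must have equal length")
        if np.unique(self.temperature).size != self.temperature.size:
            raise ValidationError("temperatures must be distinct")
        if np.any(self.tau_alpha <= 0):
            raise ValidationError("relaxation times must be positive")


@dataclass
class VFTFit:
    """VFT parameters with the derived isochronal Tg.

    ``covariance`` carries the parameter standard errors of the fit in
    the (log10 tau_inf, b_vft, t0) basis when available.
    """

    tau_inf: float  # s
    b_vft: float  # K
    t0: float  # K
    tg: float = None  # K, derived at tau = 100 s
    covariance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tau_inf > 0:
            raise ValidationError(f"tau_inf must be > 0, got {self.tau_inf}")
        if not self.b_vft > 0:
            raise ValidationError(f"b_vft must be > 0, got {self.b_vft}")
        if self.t0 < 0:
            raise ValidationError(f"t0 must be >= 0, got {self.t0}")
        if self.tg is None:
            self.tg = extrapolate_tg(self)

    def tau(self, temperature):
        return vft_tau(temperature, self.tau_inf, self.b_vft, self.t0)


def vft_tau(temperature, tau_inf: float, b_vft: float, t0: float):
    """Evaluate tau(T) = tau_inf * exp(B / (T - T0)); requires T > T0."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= t0):
        raise DomainError(f"temperature must exceed T0 = {t0} K")
    out = tau_inf * np.exp(b_vft / (t - t0))
    return float(out) if np.ndim(temperature) == 0 else out


def fit_vft(series: RelaxationSeries) -> VFTFit:
    """Least-squares VFT fit of log10 tau versus T.

    The objective is taken on log10 tau so that points spanning many
    decades carry comparable leverage.  At least 3 points are required;
    4+ spanning two or more decades are recommended for a stable T0.
    """
    if series.temperature.size < 3:
        raise ValidationError("VFT fitting needs at least 3 points")
    t = series.temperature
    log_tau = np.log10(series.tau_alpha)
    t_min = float(np.min(t))

    params = lmfit.Parameters()
    params.add("log10_tau_inf", value=-14.0, min=-30.0, max=math.log10(np.min(series.tau_alpha)))
    params.add("t0", value=max(t_min - 50.0, 1.0), min=0.0, max=t_min - 1e-3)
    params.add("b_vft", value=2000.0, min=1e-6)

    def residual(p):
        tau_inf = 10.0 ** p["log10_tau_inf"].value
        return (
            np.log10(tau_inf) + p["b_vft"].value / (t - p["t0"].value) / math.log(10.0)
        ) - log_tau

    result = lmfit.minimize(residual, params, method="leastsq", ftol=1e-12, xtol=1e-12)
    if not result.success:
        last = {name: p.value for name, p in result.params.items()}
        raise FitError(f"VFT fit did not converge: {result.message}", last_iterate=last)
    p = result.params
    if p["t0"].value >= t_min:
        raise FitError(f"fitted T0 = {p['t0'].value:.2f} K is not below min(T) = {t_min:.2f} K")
    cov = {
        name: (float(par.stderr) if par.stderr is not None else None)
        for name, par in p.items()
    }
    cov["residual_rms_log10"] = float(np.sqrt(np.mean(result.residual**2)))
    return VFTFit(
        tau_inf=10.0 ** p["log10_tau_inf"].value,
        b_vft=float(p["b_vft"].value),
        t0=float(p["t0"].value),
        covariance=cov,
    )


def extrapolate_tg(fit: VFTFit, tau_ref: float = TG_TAU_REFERENCE_S) -> float:
    """Glass-transition temperature Tg = T0 + B / ln(tau_ref / tau_inf)."""
    if tau_ref <= fit.tau_inf:
        raise DomainError(
            f"tau_ref = {tau_ref} s must exceed tau_inf = {fit.tau_inf} s"
        )
    return fit.t0 + fit.b_vft / math.log(tau_ref / fit.tau_inf)


def isochrone_temperature(fit: VFTFit, tau_target: float) -> float:
    """Temperature at which the fitted tau_alpha equals ``tau_target``.

    Same closed form as :func:`extrapolate_tg`; with tau_target = 100 s
    this is the fit's Tg.
    """
    return extrapolate_tg(fit, tau_ref=tau_target)


def horizontal_shift_tg(reference: VFTFit, anchor_temperature: float, anchor_tau: float) -> float:
    """Tg from a horizontally displaced reference VFT curve.

    Finds the displacement delta such that the reference curve evaluated
    at ``anchor_temperature - delta`` reproduces ``anchor_tau``, i.e.
    the shifted curve passes through the anchor, and returns
    ``reference.tg + delta``.  Used when a condition yields too few
    relaxation times for its own VFT fit.
    """
    if anchor_tau <= reference.tau_inf:
        raise DomainError(
            f"anchor_tau = {anchor_tau} s must exceed the reference tau_inf = {reference.tau_inf} s"
        )
    # The curve-level solution is exact: the reference reaches anchor_tau
    # at T* = isochrone_temperature(anchor_tau), so delta = T_anchor - T*.
    delta = anchor_temperature - isochrone_temperature(reference, anchor_tau)
    return reference.tg + delta
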