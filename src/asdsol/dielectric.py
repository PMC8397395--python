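"""Havriliak-Negami analysis of dielectric loss spectra.

The structural (alpha) relaxation of a supercooled drug-polymer mixture
shows up as a single peak in the imaginary part of the complex
permittivity, eps''(f).  Each isothermal spectrum is fitted with the
empirical Havriliak-Negami (HN) shape

    eps*(omega) = eps_inf + delta_eps / (1 + (i omega tau_HN)^a)^b

whose loss part is the negative imaginary component; ``a`` and ``b`` are
the symmetric and asymmetric broadening exponents (Debye relaxation is
a = b = 1).  An optional dc-conductivity term sigma_dc/(eps0 omega) can
be added to the loss.  The model relaxation time tau_HN is converted to
the peak relaxation time tau_alpha (the inverse angular frequency of the
loss maximum) with the analytic HN peak formula, which this module also
cross-checks numerically.

The dielectric strength delta_eps is proportional to the number of
relaxing units, so a sudden drop of delta_eps during isothermal
annealing marks the onset of recrystallization of the amorphous drug,
and a subsequent plateau marks its cessation; both are detected from a
delta_eps(t) trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exceptions import DomainError, FitError, ValidationError

__all__ = [
    "VACUUM_PERMITTIVITY",
    "LossSpectrum",
    "HNFit",
    "DeltaEpsTrace",
    "RecrystallizationEvent",
    "hn_loss",
    "tau_alpha_from_hn",
    "fit_hn",
    "detect_recrystallization",
]

#: Vacuum permittivity in F/m; enters only the dc-conductivity loss term.
VACUUM_PERMITTIVITY = 8.8541878128e-12


def _validate_hn_params(delta_eps, tau_hn, a, b):
    if not delta_eps > 0:
        raise ValidationError(f"delta_eps must be > 0, got {delta_eps}")
    if not tau_hn > 0:
        raise ValidationError(f"tau_hn must be > 0, got {tau_hn}")
    if not 0 < a <= 1:
        raise ValidationError(f"shape parameter a must be in (0, 1], got {a}")
    if not 0 < b <= 1:
        raise ValidationError(f"shape parameter b must be in (0, 1], got {b}")


@dataclass
class LossSpectrum:
    """One isothermal/isobaric dielectric loss curve eps''(f)."""

    frequency: np.ndarray  # Hz, strictly increasing
    loss: np.ndarray  # dimensionless eps''
    temperature: float  # K
    pressure: float = 0.1  # MPa
    label: str = ""

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if self.frequency.size != self.loss.size:
            raise ValidationError("frequency and loss must have equal length")
        if self.frequency.size < 8:
            raise ValidationError("a spectrum needs at least 8 points")
        if np.any(self.frequency <= 0):
            raise ValidationError("frequencies must be positive")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValidationError("frequencies must be strictly increasing")
        if np.any(self.loss <= 0):
            raise ValidationError("loss values must be positive")


@dataclass
class HNFit:
    """Havriliak-Negami parameters plus the derived peak time tau_alpha.

    ``tau_alpha`` is filled in automatically from the analytic peak
    formula when not supplied.  ``fit_quality`` summarizes the residuals
    of the fit that produced the parameters (empty for synthetic truth
    values), and ``peak_in_window`` is False when the fitted loss peak
    lies more than one decade outside the measured frequency window.
    """

    delta_eps: float
    tau_hn: float  # s
    a: float
    b: float
    eps_inf: float = 0.0
    sigma_dc: float | None = None  # S/m; None disables the dc term
    tau_alpha: float = None  # s, derived
    fit_quality: dict = field(default_factory=dict)
    peak_in_window: bool = True

    def __post_init__(self):
        _validate_hn_params(self.delta_eps, self.tau_hn, self.a, self.b)
        if self.tau_alpha is None:
            self.tau_alpha = tau_alpha_from_hn(self)


def hn_loss(params: HNFit, frequency) -> np.ndarray:
    """Model dielectric loss eps''(f) of the HN function.

    eps'' = -Im[ delta_eps / (1 + (i omega tau_HN)^a)^b ]
            + sigma_dc / (eps0 * omega)          (term optional)

    with omega = 2 pi f.
    """
    f = np.asarray(frequency, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if np.any(f <= 0):
        raise DomainError("frequency must be positive")
    omega = 2.0 * math.pi * f
    core = (1.0 + (1j * omega * params.tau_hn) ** params.a) ** params.b
    loss = -np.imag(params.delta_eps / core)
    if params.sigma_dc is not None:
        loss = loss + params.sigma_dc / (VACUUM_PERMITTIVITY * omega)
    return loss[0] if scalar else loss


def tau_alpha_from_hn(fit: HNFit | None = None, *, delta_eps=1.0, tau_hn=None, a=None, b=None) -> float:
    """Peak relaxation time tau_alpha from HN shape parameters.

    tau_alpha = tau_HN * [sin(a pi / (2 + 2b))]^(-1/a)
                       * [sin(a b pi / (2 + 2b))]^(1/a)

    so that 2 pi f_max tau_alpha = 1 at the model-loss maximum f_max.
    Reduces to tau_alpha = tau_HN in the Debye limit a = b = 1.
    """
    if fit is not None:
        tau_hn, a, b = fit.tau_hn, fit.a, fit.b
    _validate_hn_params(delta_eps, tau_hn, a, b)
    half = math.pi / (2.0 * (1.0 + b))
    return tau_hn * math.sin(a * half) ** (-1.0 / a) * math.sin(a * b * half) ** (1.0 / a)


def _default_init(spectrum: LossSpectrum) -> HNFit:
    # Peak-based heuristic: a single-peak spectrum has its maximum near
    # omega tau_HN ~ 1 and a height of roughly delta_eps / 2.
    i_max = int(np.argmax(spectrum.loss))
    f_max = spectrum.frequency[i_max]
    return HNFit(
        delta_eps=2.0 * spectrum.loss[i_max],
        tau_hn=1.0 / (2.0 * math.pi * f_max),
        a=0.9,
        b=0.7,
    )


def fit_hn(spectrum: LossSpectrum, init: HNFit | None = None, with_conductivity: bool = False) -> HNFit:
    """Least-squares HN fit of a loss spectrum.

    Residuals are taken on log10(eps''): the loss spans decades, and a
    linear objective would let the peak dominate the low-loss wings.
    Initialization defaults to the peak heuristic (tau_HN at the loss
    argmax, delta_eps twice the peak height, a = 0.9, b = 0.7).
    """
    if init is None:
        init = _default_init(spectrum)

    params = lmfit.Parameters()
    params.add("log10_delta_eps", value=math.log10(init.delta_eps))
    params.add("log10_tau_hn", value=math.log10(init.tau_hn))
    params.add("a", value=init.a, min=1e-3, max=1.0)
    params.add("b", value=init.b, min=1e-3, max=1.0)
    if with_conductivity:
        start = init.sigma_dc if init.sigma_dc else 1e-15
        params.add("log10_sigma_dc", value=math.log10(start))

    log_obs = np.log10(spectrum.loss)

    def residual(p):
        model = HNFit(
            delta_eps=10.0 ** p["log10_delta_eps"].value,
            tau_hn=10.0 ** p["log10_tau_hn"].value,
            a=p["a"].value,
            b=p["b"].value,
            sigma_dc=10.0 ** p["log10_sigma_dc"].value if with_conductivity else None,
        )
        return np.log10(hn_loss(model, spectrum.frequency)) - log_obs

    result = lmfit.minimize(residual, params, method="leastsq", ftol=1e-12, xtol=1e-12)
    if not result.success:
        last = {name: p.value for name, p in result.params.items()}
        raise FitError(f"HN fit did not converge: {result.message}", last_iterate=last)

    p = result.params
    fit = HNFit(
        delta_eps=10.0 ** p["log10_delta_eps"].value,
        tau_hn=10.0 ** p["log10_tau_hn"].value,
        a=p["a"].value,
        b=p["b"].value,
        sigma_dc=10.0 ** p["log10_sigma_dc"].value if with_conductivity else None,
        fit_quality={
            "residual_rms_log10": float(np.sqrt(np.mean(result.residual**2))),
            "redchi": float(result.redchi),
            "nfev": int(result.nfev),
            "conductivity_term": with_conductivity,
            "stderr": {
                name: (float(par.stderr) if par.stderr is not None else None)
                for name, par in result.params.items()
            },
        },
    )
    # Flag extrapolated peaks: more than one decade outside the window.
    f_peak = 1.0 / (2.0 * math.pi * fit.tau_alpha)
    lo, hi = spectrum.frequency[0], spectrum.frequency[-1]
    fit.peak_in_window = bool(lo / 10.0 <= f_peak <= hi * 10.0)
    return fit


@dataclass
class DeltaEpsTrace:
    """Dielectric strength delta_eps versus annealing time at one (T, P)."""

    time: np.ndarray  # s, strictly increasing
    delta_eps: np.ndarray
    temperature: float  # K
    pressure: float = 0.1  # MPa

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)
        if self.time.size == 0:
            raise ValidationError("empty trace")
        if self.time.size != self.delta_eps.size:
            raise ValidationError("time and delta_eps must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.delta_eps < 0):
            raise ValidationError("delta_eps must be non-negative")


@dataclass
class RecrystallizationEvent:
    """Detected onset/cessation times (s); None when the criterion is unmet."""

    onset_time: float | None
    cessation_time: float | None


def detect_recrystallization(
    trace: DeltaEpsTrace,
    drop_threshold: float = 0.1,
    plateau_window: int = 5,
    plateau_tol: float = 0.02,
) -> RecrystallizationEvent:
    """Detect recrystallization onset and cessation from delta_eps(t).

    Onset is the first time delta_eps falls below
    ``(1 - drop_threshold)`` times the initial baseline (the first
    point).  Cessation is the start of the first run of
    ``plateau_window`` consecutive points after onset whose relative
    range is below ``plateau_tol``.  Either may be None: a constant
    trace has no onset, and a decay still in progress at the end of the
    record has an onset but no cessation.
    """
    if trace.time.size < plateau_window + 2:
        raise ValidationError(
            f"need at least plateau_window + 2 = {plateau_window + 2} points, got {trace.time.size}"
        )
    baseline = trace.delta_eps[0]
    below = trace.delta_eps < (1.0 - drop_threshold) * baseline
    if not np.any(below):
        return RecrystallizationEvent(None, None)
    i_onset = int(np.argmax(below))
    onset_time = float(trace.time[i_onset])

    for i in range(i_onset, trace.time.size - plateau_window + 1):
        window = trace.delta_eps[i : i + plateau_window]
        center = np.mean(window)
        if center <= 0:
            rel_range = 0.0 if np.ptp(window) == 0 else np.inf
        else:
            rel_range = np.ptp(window) / center
        if rel_range < plateau_tol:
            return RecrystallizationEvent(onset_time, float(trace.time[i]))
    return RecrystallizationEvent(onset_time, None)
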