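"""Gordon-Taylor mixing rule for the glass transition of binary blends.

For a miscible drug (component 1) + polymer (component 2) blend the
glass-transition temperature follows

    Tg(W2) = (W1 Tg1 + K W2 Tg2) / (W1 + K W2),   W1 + W2 = 1,

where K is either fitted to measured composition-Tg points or computed
from the heat-capacity increments at Tg as K = dCp2 / dCp1.  For K > 0
the curve is strictly monotone in composition, so a measured Tg maps
back to a unique composition: this inversion is the step that converts
the Tg of an annealed, partially recrystallized dispersion into the
equilibrium drug content (the solubility limit at the annealing
temperature).

Calorimetric Tg values are read off heat-flow traces as the midpoint of
the sigmoidal heat-capacity step (:func:`tg_from_thermogram`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exceptions import DetectionError, DomainError, FitError, ValidationError

__all__ = [
    "CompositionTgPoint",
    "GordonTaylorParams",
    "Thermogram",
    "gt_predict",
    "fit_gordon_taylor",
    "gt_invert",
    "tg_from_thermogram",
]


@dataclass
class CompositionTgPoint:
    """A measured (composition, Tg) pair; ``w_drug`` is the drug weight fraction."""

    w_drug: float
    tg: float  # K
    pressure: float = 0.1  # MPa
    method: str = "DSC"  # {DSC, BDS}

    def __post_init__(self):
        if not 0.0 <= self.w_drug <= 1.0:
            raise ValidationError(f"w_drug must be in [0, 1], got {self.w_drug}")

    @property
    def w_poly(self) -> float:
        return 1.0 - self.w_drug


@dataclass
class GordonTaylorParams:
    """Gordon-Taylor parameterization of Tg versus composition.

    ``source`` records whether K was fitted or derived from
    heat-capacity increments; the dCp convention used here is
    K = dCp2 / dCp1 (polymer over drug), stated explicitly because
    conventions differ across the literature.
    """

    tg_drug: float  # K (Tg1)
    tg_poly: float  # K (Tg2)
    k: float  # dimensionless
    source: str = "fitted"
    delta_cp_drug: float | None = None  # J/(g K)
    delta_cp_poly: float | None = None  # J/(g K)
    fit_quality: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.k > 0:
            raise ValidationError(f"K must be > 0, got {self.k}")

    @classmethod
    def from_delta_cp(cls, tg_drug, tg_poly, delta_cp_drug, delta_cp_poly):
        """K from heat-capacity increments, K = dCp_poly / dCp_drug."""
        if delta_cp_drug <= 0 or delta_cp_poly <= 0:
            raise ValidationError("heat-capacity increments must be positive")
        return cls(
            tg_drug=tg_drug,
            tg_poly=tg_poly,
            k=delta_cp_poly / delta_cp_drug,
            source="from_delta_cp",
            delta_cp_drug=delta_cp_drug,
            delta_cp_poly=delta_cp_poly,
        )

    def predict(self, w_poly):
        return gt_predict(self, w_poly)

    def invert(self, tg_observed):
        return gt_invert(self, tg_observed)


def gt_predict(params: GordonTaylorParams, w_poly) -> float | np.ndarray:
    """Blend Tg from the Gordon-Taylor rule at polymer weight fraction ``w_poly``."""
    w2 = np.asarray(w_poly, dtype=float)
    if np.any(w2 < 0) or np.any(w2 > 1):
        raise ValidationError("w_poly must be in [0, 1]")
    w1 = 1.0 - w2
    tg = (w1 * params.tg_drug + params.k * w2 * params.tg_poly) / (w1 + params.k * w2)
    return float(tg) if np.ndim(w_poly) == 0 else tg


def fit_gordon_taylor(points, fix_endpoints: bool = True) -> GordonTaylorParams:
    """Least-squares Gordon-Taylor fit to composition-Tg points.

    With ``fix_endpoints`` the pure-component Tg's are anchored to the
    measured w = 0 / w = 1 points (which must be present) and only K is
    free; otherwise Tg1, Tg2 and K are all fitted (needs >= 3 distinct
    compositions).
    """
    points = list(points)
    w_poly = np.array([p.w_poly for p in points])
    tg = np.array([p.tg for p in points])
    if np.unique(w_poly).size < 2:
        raise FitError("degenerate input: all points share one composition")

    params = lmfit.Parameters()
    params.add("k", value=1.0, min=1e-6)
    if fix_endpoints:
        pure_drug = [p.tg for p in points if p.w_poly == 0.0]
        pure_poly = [p.tg for p in points if p.w_poly == 1.0]
        if not pure_drug or not pure_poly:
            raise ValidationError(
                "fix_endpoints requires measured pure-drug and pure-polymer points"
            )
        params.add("tg_drug", value=float(np.mean(pure_drug)), vary=False)
        params.add("tg_poly", value=float(np.mean(pure_poly)), vary=False)
    else:
        if np.unique(w_poly).size < 3:
            raise ValidationError("free-endpoint fitting needs >= 3 distinct compositions")
        params.add("tg_drug", value=float(np.min(tg)))
        params.add("tg_poly", value=float(np.max(tg)))

    def residual(p):
        model = GordonTaylorParams(
            tg_drug=p["tg_drug"].value, tg_poly=p["tg_poly"].value, k=p["k"].value
        )
        return gt_predict(model, w_poly) - tg

    result = lmfit.minimize(residual, params, method="leastsq", ftol=1e-12, xtol=1e-12)
    if not result.success:
        raise FitError(f"Gordon-Taylor fit did not converge: {result.message}")
    p = result.params
    return GordonTaylorParams(
        tg_drug=float(p["tg_drug"].value),
        tg_poly=float(p["tg_poly"].value),
        k=float(p["k"].value),
        source="fitted",
        fit_quality={
            "residual_rms_K": float(np.sqrt(np.mean(result.residual**2))),
            "k_stderr": float(p["k"].stderr) if p["k"].stderr is not None else None,
            "endpoints_fixed": fix_endpoints,
        },
    )


def gt_invert(params: GordonTaylorParams, tg_observed: float) -> float:
    """Drug weight fraction whose Gordon-Taylor Tg equals ``tg_observed``.

    Closed-form inversion of the mixing rule,

        W1 = K (Tg - Tg2) / [(Tg1 - Tg) + K (Tg - Tg2)],

    unique for K > 0 since the curve is strictly monotone.
    """
    lo, hi = sorted((params.tg_drug, params.tg_poly))
    if not lo <= tg_observed <= hi:
        raise DomainError(
            f"tg = {tg_observed} K outside the curve range [{lo}, {hi}] K"
        )
    if params.tg_drug == params.tg_poly:
        raise DomainError("pure-component Tg values coincide; inversion is undefined")
    num = params.k * (tg_observed - params.tg_poly)
    den = (params.tg_drug - tg_observed) + num
    if den == 0.0:
        # Only possible at tg == tg_drug == tg_poly, excluded above.
        raise DomainError("degenerate inversion")
    return num / den


@dataclass
class Thermogram:
    """A heat-flow-like trace versus temperature (arbitrary signal units)."""

    temperature: np.ndarray  # K, strictly increasing
    signal: np.ndarray
    scan_rate: float = 10.0  # K/min

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.size != self.signal.size:
            raise ValidationError("temperature and signal must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


def tg_from_thermogram(trace: Thermogram) -> float:
    """Glass transition as the midpoint of the heat-capacity step.

    Fits signal(T) = baseline(T) + h * logistic((T - Tg)/w) with a
    shared linear baseline and returns the logistic center, i.e. the
    temperature at half step height.  Raises :class:`DetectionError`
    when no step rises above the residual noise (h < 5 sigma).
    """
    t = trace.temperature
    y = trace.signal
    if t.size < 10:
        raise ValidationError("thermogram too short for step detection")

    span = float(np.ptp(y))
    t_range = float(t[-1] - t[0])
    # Center init: steepest point of a lightly smoothed trace.
    kernel = np.ones(max(3, t.size // 50)) / max(3, t.size // 50)
    smooth = np.convolve(y, kernel, mode="same")
    i_step = int(np.argmax(np.abs(np.gradient(smooth, t))))

    params = lmfit.Parameters()
    params.add("c0", value=float(y[0]))
    params.add("c1", value=0.0)
    params.add("h", value=span if span > 0 else 1e-12)
    params.add("tg", value=float(t[i_step]), min=float(t[0]), max=float(t[-1]))
    params.add("w", value=max(t_range / 50.0, 0.1), min=1e-3, max=t_range)

    def model(p):
        z = (t - p["tg"].value) / p["w"].value
        return p["c0"].value + p["c1"].value * (t - t[0]) + p["h"].value / (1.0 + np.exp(-z))

    result = lmfit.minimize(lambda p: model(p) - y, params, method="leastsq")
    if not result.success:
        raise FitError(f"step fit did not converge: {result.message}")
    h = result.params["h"].value
    noise = float(np.std(result.residual))
    if h <= 0 or h < 5.0 * noise:
        raise DetectionError(
            f"no heat-capacity step above the noise floor (h = {h:.3g}, noise = {noise:.3g})"
        )
    return float(result.params["tg"].value)
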