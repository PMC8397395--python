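"""Synthetic-data generators for every input the pipeline consumes.

No measured spectra are shipped with the package, so each analysis
stage is exercised on data generated from the same models the stages
fit: HN-shaped loss peaks, VFT-distributed relaxation times,
Gordon-Taylor composition-Tg curves, Flory-Huggins liquidus points,
sigmoidal heat-capacity steps and logistic dielectric-strength decays.
All generators draw from a PRNG seeded by :class:`SyntheticConfig`, so
a fixed seed reproduces every data set bit for bit.

Noise models (all sds configurable, zero disables):

* eps'' noise is multiplicative lognormal - the loss spans decades and
  additive noise would distort the low-loss wings; multiplicative noise
  also preserves positivity;
* tau noise is additive in log10 (relaxation times span 8+ decades);
* Tg and solubility noise are additive Gaussian in K and wt%.

Defaults (1% on eps'', 0.05 decades on tau, 0.5 K on Tg, 0.5 wt% on
solubility points) represent a well-run broadband-dielectric/DSC study;
the measured-noise levels of any given instrument are not knowable from
the models, so these are documented assumptions, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dielectric import DeltaEpsTrace, HNFit, LossSpectrum, hn_loss
from .exceptions import DomainError, ValidationError
from .flory import FHModel, SolubilityPoint, solubility_wtpct
from .mixing import CompositionTgPoint, GordonTaylorParams, Thermogram, gt_predict
from .vft import RelaxationSeries, VFTFit, vft_tau

__all__ = [
    "NoiseModel",
    "SyntheticConfig",
    "default_frequency_grid",
    "generate_hn_spectrum",
    "generate_vft_series",
    "generate_gt_curve",
    "generate_fh_solubility_points",
    "generate_recrystallization_trace",
    "generate_thermogram",
]


def default_frequency_grid() -> np.ndarray:
    """10 points per decade from 1e-1 to 1e6 Hz (the spectrometer range)."""
    return np.logspace(-1.0, 6.0, 71)


@dataclass
class NoiseModel:
    """Standard deviations of the measurement noise on each data kind."""

    eps_rel_sd: float = 0.01  # multiplicative lognormal sd on eps''
    tau_log10_sd: float = 0.05  # additive sd on log10(tau/s)
    tg_sd: float = 0.5  # K
    solubility_wt_sd: float = 0.5  # wt%
    signal_sd: float = 0.002  # thermogram signal units

    def __post_init__(self):
        for name in ("eps_rel_sd", "tau_log10_sd", "tg_sd", "solubility_wt_sd", "signal_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls):
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SyntheticConfig:
    """Seed, frequency grid and noise model shared by all generators."""

    seed: int = 0
    frequency_grid: np.ndarray = field(default_factory=default_frequency_grid)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self):
        self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        if np.any(self.frequency_grid <= 0):
            raise ValidationError("frequency grid values must be positive")
        if np.any(np.diff(self.frequency_grid) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A fresh Generator; ``stream`` decorrelates draws within one config."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def generate_hn_spectrum(
    params: HNFit,
    config: SyntheticConfig,
    temperature: float = 300.0,
    pressure: float = 0.1,
    label: str = "",
) -> LossSpectrum:
    """An HN loss spectrum on the config grid with multiplicative noise."""
    clean = hn_loss(params, config.frequency_grid)
    sd = config.noise.eps_rel_sd
    if sd > 0:
        noise = config.rng(stream=1).normal(0.0, sd, size=clean.size)
        clean = clean * np.exp(noise)
    return LossSpectrum(
        frequency=config.frequency_grid.copy(),
        loss=clean,
        temperature=temperature,
        pressure=pressure,
        label=label,
    )


def generate_vft_series(
    params: VFTFit,
    temperatures,
    config: SyntheticConfig,
    pressure: float = 0.1,
    composition_label: str = "",
) -> RelaxationSeries:
    """tau(T) from the VFT law with optional log10-domain noise."""
    t = np.asarray(temperatures, dtype=float)
    if np.any(t <= params.t0):
        raise DomainError(f"all temperatures must exceed T0 = {params.t0} K")
    log_tau = np.log10(vft_tau(t, params.tau_inf, params.b_vft, params.t0))
    sd = config.noise.tau_log10_sd
    if sd > 0:
        log_tau = log_tau + config.rng(stream=2).normal(0.0, sd, size=t.size)
    return RelaxationSeries(
        temperature=t,
        tau_alpha=10.0**log_tau,
        pressure=pressure,
        composition_label=composition_label,
    )


def generate_gt_curve(
    tg_drug: float,
    tg_poly: float,
    k_gt: float,
    fractions,
    config: SyntheticConfig,
    pressure: float = 0.1,
    method: str = "DSC",
) -> list[CompositionTgPoint]:
    """Composition-Tg points on a Gordon-Taylor curve with Tg noise.

    ``fractions`` are polymer weight fractions W2 (W2 = 0 is the pure
    drug).  Endpoint values are exact up to the added noise.
    """
    w_poly = np.asarray(fractions, dtype=float)
    if np.any(w_poly < 0) or np.any(w_poly > 1):
        raise ValidationError("fractions must be in [0, 1]")
    gt = GordonTaylorParams(tg_drug=tg_drug, tg_poly=tg_poly, k=k_gt)
    tg = np.asarray(gt_predict(gt, w_poly), dtype=float).reshape(w_poly.shape)
    sd = config.noise.tg_sd
    if sd > 0:
        tg = tg + config.rng(stream=3).normal(0.0, sd, size=w_poly.size)
    return [
        CompositionTgPoint(w_drug=1.0 - w2, tg=float(t), pressure=pressure, method=method)
        for w2, t in zip(w_poly, tg)
    ]


def generate_fh_solubility_points(
    model: FHModel, temperatures, config: SyntheticConfig, pressure: float = 0.1
) -> list[SolubilityPoint]:
    """Equilibrium wt% per temperature from the liquidus, plus noise.

    Noisy values are clipped to the open interval (0, 100) so every
    point remains a valid composition.
    """
    t = np.asarray(temperatures, dtype=float)
    tm0 = model.constants.tm0
    if np.any(t >= tm0):
        raise DomainError(f"temperatures must lie below Tm0 = {tm0} K")
    wt = np.array([solubility_wtpct(float(ti), model) for ti in t])
    sd = config.noise.solubility_wt_sd
    if sd > 0:
        wt = wt + config.rng(stream=4).normal(0.0, sd, size=t.size)
    wt = np.clip(wt, 1e-6, 100.0 - 1e-6)
    return [
        SolubilityPoint(temperature=float(ti), wtpct_drug=float(w), pressure=pressure)
        for ti, w in zip(t, wt)
    ]


def generate_recrystallization_trace(
    initial_delta_eps: float,
    final_delta_eps: float,
    rate: float,
    times,
    config: SyntheticConfig,
    temperature: float = 370.0,
    pressure: float = 0.1,
) -> DeltaEpsTrace:
    """A logistic decay of delta_eps(t) from initial to final plateau.

    The decay midpoint sits at t = 5/rate so the trace starts within
    ~1% of ``initial_delta_eps`` at t = 0; ``rate`` (1/s) sets the
    steepness.  Only a smooth monotone drop is needed to exercise
    onset/cessation detection - no crystallization kinetics are implied.
    """
    if not initial_delta_eps > final_delta_eps >= 0:
        raise ValidationError("need initial_delta_eps > final_delta_eps >= 0")
    if not rate > 0:
        raise ValidationError("rate must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    t_mid = 5.0 / rate
    decay = 1.0 / (1.0 + np.exp(rate * (t - t_mid)))
    trace = final_delta_eps + (initial_delta_eps - final_delta_eps) * decay
    sd = config.noise.eps_rel_sd
    if sd > 0:
        trace = trace * np.exp(config.rng(stream=5).normal(0.0, sd, size=t.size))
    return DeltaEpsTrace(time=t, delta_eps=trace, temperature=temperature, pressure=pressure)


def generate_thermogram(
    tg: float,
    step_height: float,
    width: float,
    temperatures,
    config: SyntheticConfig,
    scan_rate: float = 10.0,
) -> Thermogram:
    """A sigmoidal heat-capacity step centered at ``tg``.

    ``width`` is the logistic scale parameter in K (the 10-90% rise
    spans about 4.4 widths).  ``step_height`` of zero produces a flat
    trace, on which downstream midpoint extraction must fail.
    """
    if not width > 0:
        raise ValidationError("width must be positive")
    t = np.asarray(temperatures, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("temperatures must be strictly increasing")
    signal = step_height / (1.0 + np.exp(-(t - tg) / width))
    sd = config.noise.signal_sd
    if sd > 0:
        signal = signal + config.rng(stream=6).normal(0.0, sd, size=t.size)
    return Thermogram(temperature=t, signal=signal, scan_rate=scan_rate)
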