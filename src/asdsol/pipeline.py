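"""End-to-end solubility-determination pipeline.

Orchestrates the four-step annealing protocol and its analysis chain:

i.   start from spectra of an annealed, initially supersaturated
     dispersion (one directory of loss spectra per annealing condition);
ii.  fit every spectrum with the HN function and collect tau_alpha(T);
iii. parameterize tau_alpha(T) with the VFT law and extrapolate to
     tau = 100 s to obtain the Tg of the annealed material (falling
     back to a horizontal shift of a reference VFT curve when a
     condition yielded fewer than three usable relaxation times);
iv.  invert the composition-Tg (Gordon-Taylor) curve at that Tg to read
     off the equilibrium drug content - one solubility point per
     annealing condition.

The collected solubility points are then fitted with the Flory-Huggins
liquidus (constant chi and chi(T) = A + B/T) per pressure, and, when an
elevated-pressure condition is present, the high-pressure points are
transposed to the ambient reference by the melting-point difference and
refitted together with the ambient points (including the fixed-B
variant).  Every stage writes its artifacts; a machine-readable summary
collects all fitted parameters.

The input layout consumed by :func:`run_solubility_pipeline` is the one
written by :func:`write_synthetic_study`:

    input_dir/
      constants.json          pure-component constants
      tg_composition.tsv      ambient composition-Tg points
      spectra/<condition>/    one .tsv loss spectrum per measurement T
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .dielectric import HNFit, LossSpectrum, fit_hn, tau_alpha_from_hn
from .exceptions import PipelineError
from .flory import (
    ChiModel,
    ComponentConstants,
    FHModel,
    SolubilityPoint,
    fit_fh_chi_constant,
    fit_fh_chi_temperature,
    solubility_wtpct,
)
from .io import read_table, write_table
from .mixing import CompositionTgPoint, GordonTaylorParams, fit_gordon_taylor, gt_predict
from .pressure import PressureCondition, combined_fh_fit, transpose_tg_curve
from .vft import RelaxationSeries, VFTFit, fit_vft, horizontal_shift_tg

__all__ = ["PipelineConfig", "PipelineReport", "run_solubility_pipeline", "write_synthetic_study"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML or JSON loadable)."""

    input_dir: str
    output_dir: str
    seed: int = 0
    tau_ref_s: float = 100.0  # isochronal Tg definition
    lm_tolerance: float = 1e-9
    ambient_pressure: float = 0.1  # MPa
    #: per elevated pressure: {"pressure": MPa, "tm0_at_p": K, "delta_tg": K}
    pressure_conditions: list = field(default_factory=list)
    min_vft_points: int = 3

    def __post_init__(self):
        if self.lm_tolerance <= 0 or self.tau_ref_s <= 0:
            raise PipelineError("config", "tolerances and tau_ref_s must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls(**data)

    def validate_paths(self):
        root = Path(self.input_dir)
        for rel in ("constants.json", "tg_composition.tsv", "spectra"):
            if not (root / rel).exists():
                raise PipelineError("config", f"missing input {root / rel}")


@dataclass
class PipelineReport:
    """Nested per-stage results; serialized to summary.json."""

    summary: dict

    def to_json(self) -> str:
        return json.dumps(self.summary, indent=2, sort_keys=True)


def _load_constants(path) -> ComponentConstants:
    raw = json.loads(Path(path).read_text())
    return ComponentConstants(
        tm0=raw["tm0_K"],
        dhfus=raw["dhfus_J_per_mol"],
        d_drug=raw["d_drug_g_per_cm3"],
        d_poly=raw["d_poly_g_per_cm3"],
        mw_drug=raw["mw_drug_g_per_mol"],
        mw_poly=raw["mw_poly_g_per_mol"],
    )


def _read_spectrum(path) -> LossSpectrum:
    df, meta = read_table(path)
    return LossSpectrum(
        frequency=df["frequency_hz"].to_numpy(),
        loss=df["eps_loss"].to_numpy(),
        temperature=float(meta["temperature_K"]),
        pressure=float(meta.get("pressure_MPa", 0.1)),
        label=str(meta.get("label", "")),
    )


def _chi_summary(model: FHModel) -> dict:
    cm = model.chi_model
    out = {
        "kind": cm.kind,
        "r_squared": model.fit_report.get("r_squared"),
        "residual_rms_K": model.fit_report.get("residual_rms_K"),
        "solubility_wtpct_298K": None,
    }
    if cm.kind == "constant":
        out["chi"] = cm.chi
    else:
        out["a_chi"] = cm.a_chi
        out["b_chi_K"] = cm.b_chi
    out["uncertainties"] = cm.uncertainties
    try:
        out["solubility_wtpct_298K"] = solubility_wtpct(298.0, model)
    except Exception:  # no root below Tm0 for this parameterization
        out["solubility_wtpct_298K"] = None
    return out


def run_solubility_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full protocol; returns the report and writes artifacts."""
    config.validate_paths()
    root = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    constants = _load_constants(root / "constants.json")
    conditions = [
        PressureCondition(
            pressure=float(c["pressure"]),
            tm0_at_p=float(c["tm0_at_p"]),
            delta_tg=float(c["delta_tg"]),
        )
        for c in config.pressure_conditions
    ]
    by_pressure = {c.pressure: c for c in conditions}

    # --- stage ii: HN fits per annealing condition -----------------------
    hn_records = []
    tau_series: dict[str, dict] = {}
    spectra_root = root / "spectra"
    for cond_dir in sorted(p for p in spectra_root.iterdir() if p.is_dir()):
        try:
            _, meta = read_table(next(iter(sorted(cond_dir.glob("*.tsv")))))
        except StopIteration:
            raise PipelineError("fit-hn", f"no spectra in {cond_dir}")
        anneal_t = float(meta["annealing_T_K"])
        pressure = float(meta.get("pressure_MPa", config.ambient_pressure))
        temps, taus = [], []
        for spec_path in sorted(cond_dir.glob("*.tsv")):
            spectrum = _read_spectrum(spec_path)
            try:
                fit = fit_hn(spectrum)
            except Exception as exc:
                raise PipelineError("fit-hn", f"{spec_path}: {exc}") from exc
            hn_records.append(
                {
                    "condition": cond_dir.name,
                    "file": spec_path.name,
                    "temperature_K": spectrum.temperature,
                    "pressure_MPa": pressure,
                    "delta_eps": fit.delta_eps,
                    "tau_hn_s": fit.tau_hn,
                    "a": fit.a,
                    "b": fit.b,
                    "tau_alpha_s": fit.tau_alpha,
                    "peak_in_window": fit.peak_in_window,
                    "residual_rms_log10": fit.fit_quality["residual_rms_log10"],
                }
            )
            if fit.peak_in_window:
                temps.append(spectrum.temperature)
                taus.append(fit.tau_alpha)
        tau_series[cond_dir.name] = {
            "annealing_T_K": anneal_t,
            "pressure_MPa": pressure,
            "temperature_K": temps,
            "tau_alpha_s": taus,
        }
    hn_df = pd.DataFrame(hn_records)
    write_table(hn_df, out / "hn_fits.tsv")

    # --- stage iii: VFT fits and Tg, with horizontal-shift fallback ------
    vft_results: dict[str, dict] = {}
    fits: dict[str, VFTFit] = {}
    for name, series in tau_series.items():
        if len(series["temperature_K"]) >= config.min_vft_points:
            try:
                fit = fit_vft(
                    RelaxationSeries(
                        temperature=np.array(series["temperature_K"]),
                        tau_alpha=np.array(series["tau_alpha_s"]),
                        pressure=series["pressure_MPa"],
                        composition_label=name,
                    )
                )
            except Exception as exc:
                raise PipelineError("fit-vft", f"{name}: {exc}") from exc
            fits[name] = fit
            vft_results[name] = {
                "method": "vft",
                "tau_inf_s": fit.tau_inf,
                "b_vft_K": fit.b_vft,
                "t0_K": fit.t0,
                "tg_K": fit.tg,
                "n_points": len(series["temperature_K"]),
            }
    for name, series in tau_series.items():
        if name in vft_results:
            continue
        if not series["temperature_K"]:
            raise PipelineError("fit-vft", f"{name}: no usable relaxation times")
        # Sparse condition: shift the best-sampled same-pressure fit.
        candidates = [
            n for n in fits if tau_series[n]["pressure_MPa"] == series["pressure_MPa"]
        ]
        if not candidates:
            raise PipelineError(
                "fit-vft", f"{name}: too few points and no same-pressure reference fit"
            )
        reference = max(candidates, key=lambda n: len(tau_series[n]["temperature_K"]))
        tg = horizontal_shift_tg(
            fits[reference],
            anchor_temperature=series["temperature_K"][0],
            anchor_tau=series["tau_alpha_s"][0],
        )
        vft_results[name] = {
            "method": "horizontal_shift",
            "reference": reference,
            "tg_K": tg,
            "n_points": len(series["temperature_K"]),
        }
    (out / "vft_fits.json").write_text(json.dumps(vft_results, indent=2, sort_keys=True))

    # --- stage iv: Gordon-Taylor inversion -> solubility points ----------
    tg_df, _ = read_table(root / "tg_composition.tsv")
    # table stores polymer wt%, points store drug weight fraction
    gt_points = [
        CompositionTgPoint(w_drug=1.0 - float(r.wtpct_poly) / 100.0, tg=float(r.tg_K))
        for r in tg_df.itertuples()
    ]
    try:
        gt = fit_gordon_taylor(gt_points, fix_endpoints=True)
    except Exception as exc:
        raise PipelineError("tg-map", str(exc)) from exc

    solubility: dict[float, list[SolubilityPoint]] = {}
    sol_records = []
    for name, series in tau_series.items():
        pressure = series["pressure_MPa"]
        tg = vft_results[name]["tg_K"]
        if pressure in by_pressure:
            curve = transpose_tg_curve(gt, by_pressure[pressure])
            w_drug = curve.invert(tg)
        else:
            w_drug = gt.invert(tg)
        point = SolubilityPoint(
            temperature=series["annealing_T_K"],
            wtpct_drug=100.0 * w_drug,
            pressure=pressure,
        )
        solubility.setdefault(pressure, []).append(point)
        sol_records.append(
            {
                "condition": name,
                "annealing_T_K": point.temperature,
                "pressure_MPa": pressure,
                "tg_K": tg,
                "wtpct_drug": point.wtpct_drug,
            }
        )
    write_table(pd.DataFrame(sol_records).sort_values(["pressure_MPa", "annealing_T_K"]),
                out / "solubility_points.tsv")

    # --- Flory-Huggins fits ----------------------------------------------
    fh_summary: dict = {}
    ambient_points = solubility.get(config.ambient_pressure, [])
    try:
        for pressure, points in sorted(solubility.items()):
            consts = constants
            if pressure in by_pressure:
                consts = ComponentConstants(
                    tm0=by_pressure[pressure].tm0_at_p,
                    dhfus=constants.dhfus,
                    d_drug=constants.d_drug,
                    d_poly=constants.d_poly,
                    mw_drug=constants.mw_drug,
                    mw_poly=constants.mw_poly,
                )
            entry = {}
            if len(points) >= 2:
                entry["chi_constant"] = _chi_summary(fit_fh_chi_constant(points, consts))
            if len(points) >= 3:
                entry["chi_temperature"] = _chi_summary(fit_fh_chi_temperature(points, consts))
            fh_summary[f"{pressure}_MPa"] = entry
        ambient_ab = fh_summary.get(f"{config.ambient_pressure}_MPa", {}).get("chi_temperature")
        for condition in conditions:
            hp_points = solubility.get(condition.pressure, [])
            if not ambient_points or not hp_points:
                continue
            combined = {
                "chi_constant": _chi_summary(
                    combined_fh_fit(ambient_points, hp_points, condition, constants,
                                    mode="chi_constant")
                ),
                "chi_temperature": _chi_summary(
                    combined_fh_fit(ambient_points, hp_points, condition, constants,
                                    mode="chi_temperature")
                ),
            }
            if ambient_ab is not None:
                combined["fixed_b"] = _chi_summary(
                    combined_fh_fit(ambient_points, hp_points, condition, constants,
                                    mode="fixed_b", fixed_b_chi=ambient_ab["b_chi_K"])
                )
            fh_summary[f"combined_{condition.pressure}_MPa"] = combined
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit-fh", str(exc)) from exc

    summary = {
        "seed": config.seed,
        "tau_ref_s": config.tau_ref_s,
        "gordon_taylor": {
            "tg_drug_K": gt.tg_drug,
            "tg_poly_K": gt.tg_poly,
            "k": gt.k,
            "residual_rms_K": gt.fit_quality.get("residual_rms_K"),
        },
        "conditions": vft_results,
        "solubility_points": sol_records,
        "flory_huggins": fh_summary,
    }
    report = PipelineReport(summary=summary)
    (out / "summary.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# Synthetic study writer (the `simulate` entry point)
# ---------------------------------------------------------------------------

def write_synthetic_study(
    path,
    seed: int = 0,
    annealing_temperatures=(368.0, 373.0, 378.0, 383.0, 388.0, 393.0, 398.0),
    hp_annealing_temperatures=(368.0, 378.0, 388.0, 398.0),
    include_pressure: bool = True,
    noise: synthetic.NoiseModel | None = None,
) -> dict:
    """Write a complete synthetic study directory consumable by the pipeline.

    The generating truth mirrors the reference drug-polymer system: a
    Flory-Huggins liquidus with chi(T) = A + B/T (A = 6.6, B = -2990 K)
    and the published component constants sets the equilibrium drug
    content at each annealing temperature; a Gordon-Taylor curve
    (294/377 K endpoints, K = 0.35) maps that composition to a Tg; a VFT
    law anchored at that Tg (tau_inf = 1e-14 s, B = 2600 K) produces
    relaxation times at measurement temperatures chosen so tau spans
    1e-6 to 1e-1 s; HN spectra (a = 0.8, b = 0.6) carry those times.
    At 50 MPa the melting point moves to 435 K and every Tg is 12 K
    higher.  Returns the generating truth for recovery checks.
    """
    root = Path(path)
    (root / "spectra").mkdir(parents=True, exist_ok=True)
    noise = noise if noise is not None else synthetic.NoiseModel()

    constants = {
        "tm0_K": 421.0,
        "tm0_50MPa_K": 435.0,
        "dhfus_J_per_mol": 32988.0,
        "d_drug_g_per_cm3": 1.41,
        "d_poly_g_per_cm3": 1.20,
        "mw_drug_g_per_mol": 308.3,
        "mw_poly_g_per_mol": 46000.0,
    }
    (root / "constants.json").write_text(json.dumps(constants, indent=2, sort_keys=True))

    consts = _load_constants(root / "constants.json")
    truth = {
        "gt": {"tg_drug": 294.0, "tg_poly": 377.0, "k": 0.35},
        "fh": {"a_chi": 6.6, "b_chi": -2990.0},
        "vft": {"tau_inf": 1e-14, "b_vft": 2600.0},
        "hn": {"a": 0.8, "b": 0.6, "delta_eps": 1.5},
        "delta_tg": 12.0,
        "tm0_at_p": constants["tm0_50MPa_K"],
        "pressure": 50.0,
    }

    # Ambient composition-Tg table (noisy like a measured curve).
    cfg = synthetic.SyntheticConfig(seed=seed, noise=noise)
    fractions = [0.0, 0.2, 0.3, 0.4, 0.55, 0.8, 1.0]
    gt_pts = synthetic.generate_gt_curve(
        truth["gt"]["tg_drug"], truth["gt"]["tg_poly"], truth["gt"]["k"], fractions, cfg
    )
    # Endpoints anchored exactly: the measured pure-component Tg's fix the curve.
    gt_pts[0].tg = truth["gt"]["tg_drug"]
    gt_pts[-1].tg = truth["gt"]["tg_poly"]
    write_table(
        pd.DataFrame(
            {"wtpct_poly": [100 * p.w_poly for p in gt_pts], "tg_K": [p.tg for p in gt_pts]}
        ),
        root / "tg_composition.tsv",
    )
    gt_truth = GordonTaylorParams(
        tg_drug=truth["gt"]["tg_drug"], tg_poly=truth["gt"]["tg_poly"], k=truth["gt"]["k"]
    )

    fh_truth = FHModel(
        constants=consts,
        chi_model=ChiModel(kind="linear_in_invT", a_chi=truth["fh"]["a_chi"],
                           b_chi=truth["fh"]["b_chi"]),
    )

    def emit_condition(anneal_t, pressure, delta_tg, tm_shift, idx):
        # Truth chain: liquidus -> composition -> Tg -> VFT -> spectra.
        # At elevated pressure the liquidus is the ambient one shifted up
        # by the melting-point difference, and every Tg is delta_tg higher.
        wt = solubility_wtpct(anneal_t - tm_shift, fh_truth)
        w_poly = 1.0 - wt / 100.0
        tg = gt_predict(gt_truth, w_poly) + delta_tg
        tau_inf, b_vft = truth["vft"]["tau_inf"], truth["vft"]["b_vft"]
        t0 = tg - b_vft / math.log(100.0 / tau_inf)
        vft = VFTFit(tau_inf=tau_inf, b_vft=b_vft, t0=t0)
        # Measurement temperatures: tau from 1e-6 to 1e-1 s (peaks inside
        # the 0.1 Hz - 1 MHz window).
        n_meas = 8
        taus = np.logspace(-6, -1, n_meas)
        meas_t = np.array([t0 + b_vft / math.log(t / tau_inf) for t in taus])
        cond = f"anneal{int(round(anneal_t))}K_{pressure:g}MPa"
        cond_dir = root / "spectra" / cond
        cond_dir.mkdir(parents=True, exist_ok=True)
        hn = truth["hn"]
        peak_factor = tau_alpha_from_hn(tau_hn=1.0, a=hn["a"], b=hn["b"])
        for j, (t_meas, tau) in enumerate(zip(meas_t, taus)):
            params = HNFit(
                delta_eps=hn["delta_eps"],
                tau_hn=tau / peak_factor,
                a=hn["a"],
                b=hn["b"],
            )
            spec_cfg = synthetic.SyntheticConfig(
                seed=int(np.random.SeedSequence([seed, idx, j]).generate_state(1)[0] % 2**31),
                noise=noise,
            )
            spectrum = synthetic.generate_hn_spectrum(
                params, spec_cfg, temperature=float(t_meas), pressure=pressure
            )
            write_table(
                pd.DataFrame({"frequency_hz": spectrum.frequency, "eps_loss": spectrum.loss}),
                cond_dir / f"spec_{j:02d}.tsv",
                metadata={
                    "temperature_K": f"{t_meas:.6f}",
                    "pressure_MPa": pressure,
                    "annealing_T_K": anneal_t,
                    "label": cond,
                },
            )
        return {"condition": cond, "true_wtpct": wt, "true_tg_K": tg}

    truth["conditions"] = []
    for i, anneal_t in enumerate(annealing_temperatures):
        truth["conditions"].append(emit_condition(anneal_t, 0.1, 0.0, 0.0, i))
    if include_pressure:
        tm_shift = constants["tm0_K"] - constants["tm0_50MPa_K"]  # negative
        for i, anneal_t in enumerate(hp_annealing_temperatures):
            truth["conditions"].append(
                emit_condition(anneal_t, truth["pressure"], truth["delta_tg"], -tm_shift, 100 + i)
            )
    (root / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
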