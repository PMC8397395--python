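# asdsol

Drug–polymer solubility limits from dielectric relaxation data.

Amorphous solid dispersions (ASDs) keep a poorly water-soluble drug
amorphous by dispersing it in a polymer matrix. The dispersion is only
physically stable if the drug loading stays below its equilibrium
solubility in the polymer — a quantity that is hard to measure at storage
temperature, where equilibration takes years. `asdsol` implements the
annealing-based inference chain that formulation scientists use to get at
it, at ambient and at elevated pressure:

1. **Spectral fitting.** Dielectric loss spectra ε″(f) of the annealed
   dispersion are fitted with the Havriliak–Negami function
   ε\*(ω) = ε∞ + Δε / (1 + (iωτ_HN)^a)^b, and the structural relaxation
   time τ_α is obtained from the analytic peak-time formula. A drop of
   the dielectric strength Δε(t) during annealing marks recrystallization
   onset; a plateau marks its cessation.
2. **Tg extrapolation.** τ_α(T) is parameterized with the
   Vogel–Fulcher–Tammann law τ(T) = τ∞·exp(B/(T−T0)) and extrapolated to
   the isochronal glass transition, Tg = T(τ_α = 100 s). When a condition
   yields too few relaxation times, a well-sampled reference VFT curve is
   shifted horizontally through the single available (T, τ) anchor.
3. **Composition from Tg.** The measured composition–Tg curve is
   parameterized with the Gordon–Taylor rule
   Tg = (W₁Tg₁ + K·W₂Tg₂)/(W₁ + K·W₂) and inverted: the Tg of the annealed
   sample gives the equilibrium drug weight fraction at the annealing
   temperature — one point on the solubility curve.
4. **Flory–Huggins extrapolation.** The solubility points (T, wt%) lie on
   the melting-point-depression liquidus
   1/Tm − 1/Tm⁰ = −(R/ΔH_fus)·[ln φ + (1 − 1/m)(1 − φ) + χ(1 − φ)²],
   with m the polymer/drug molar-volume ratio. Fitting χ (constant, or
   χ(T) = A + B/T) and solving the liquidus at 298 K extrapolates the
   solubility limit to storage conditions.
5. **Pressure transposition.** At elevated pressure the composition–Tg
   curve is shifted up by a constant ΔTg and the pure-drug melting point
   rises; high-pressure solubility points transposed down by the
   melting-point difference pool with ambient points for a combined fit.

The package ships the published study tables for nimesulide (NMS) +
Kollidon VA64 (KVA) — composition–Tg curves, annealing-derived solubility
points at 0.1 and 50 MPa, and pure-component constants — as its worked
reference data, and a synthetic-data generator that emulates every input
of the chain so the whole pipeline is testable without measured spectra.

## Worked example

```python
from asdsol import (fit_fh_chi_temperature, fit_gordon_taylor,
                    solubility_wtpct)
from asdsol.datasets import (nimesulide_kollidon_constants,
                             solubility_points, tg_composition_points)

constants = nimesulide_kollidon_constants()      # Tm0 = 421 K, etc.
points = solubility_points("bds")                # 7 annealing points

model = fit_fh_chi_temperature(points, constants)
print(f"m = {model.m:.1f}")
print(f"chi(T) = A + B/T with A = {model.chi_model.a_chi:.3f}, "
      f"B = {model.chi_model.b_chi:.0f} K")
print(f"R^2 = {model.fit_report['r_squared']:.3f}")
print(f"solubility at 298 K = {solubility_wtpct(298.0, model):.1f} wt% drug")

gt = fit_gordon_taylor(tg_composition_points("dsc"), fix_endpoints=True)
print(f"Gordon-Taylor K = {gt.k:.3f}")
print(f"Tg = 330 K -> {100 * gt.invert(330.0):.1f} wt% drug")
```

prints

```
m = 175.3
chi(T) = A + B/T with A = 6.606, B = -2992 K
R^2 = 0.983
solubility at 298 K = 13.9 wt% drug
Gordon-Taylor K = 0.706
Tg = 330 K -> 48.0 wt% drug
```

The negative enthalpic term B and χ(298 K) < 0 indicate drug–polymer
miscibility; ~14 wt% is the predicted equilibrium drug load at room
temperature, and the Gordon–Taylor inversion shows that annealing at
398 K leaves ~48 wt% drug amorphous in the matrix.

## Command line

`asdsol` exposes the same stages as subcommands:

```
asdsol simulate --out study/ --seed 1      # write a synthetic study
asdsol pipeline --input-dir study/ --out results/ --seed 1
asdsol fit-hn spectrum.tsv                 # one HN fit
asdsol fit-vft tau_table.tsv               # VFT fit + Tg
asdsol tg-map tg_table.tsv                 # Gordon-Taylor fit
asdsol invert-tg tg_table.tsv 330          # Tg -> wt% drug
asdsol fit-fh points.tsv --constants constants.json
asdsol transpose points.tsv --tm0-ambient 421 --tm0-at-p 435
```

All tabular I/O is tab-separated text with unit-bearing column names and
`# key = value` metadata headers.

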