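# Methods

## The inference chain

The package determines the equilibrium solubility of a crystalline drug
in an amorphous polymer from annealing experiments. A supersaturated
glass solution is annealed above its Tg until the excess drug has
recrystallized; the composition of the remaining amorphous phase — the
solubility limit at the annealing temperature — is read off its glass
transition. Repeating at several annealing temperatures traces the
solubility curve, which a Flory–Huggins liquidus then extrapolates to
storage temperature. Each link of the chain is a parametric model with
explicit assumptions:

* **Havriliak–Negami loss** (`dielectric`). One structural (α)
  relaxation per spectrum; ε″(ω) = −Im[Δε/(1 + (iωτ_HN)^a)^b], with
  0 < a, b ≤ 1 and an optional dc-conductivity term σ_dc/(ε₀ω), off by
  default (whether measured spectra need it depends on the sample's
  ionic impurity content; the flag is recorded in the fit metadata).
  No β-relaxations, excess wings, or multi-peak deconvolution. The peak
  relaxation time is
  τ_α = τ_HN·[sin(aπ/(2+2b))]^(−1/a)·[sin(abπ/(2+2b))]^(1/a);
  because this formula is easy to mistype and conventions vary, the test
  suite verifies it against a brute-force argmax of the model loss on a
  1000-point-per-decade grid rather than trusting it.
* **VFT dynamics** (`vft`). τ(T) = τ∞·exp(B/(T−T0)) above T0, with the
  glass transition defined isochronally at τ_α = 100 s and evaluated in
  closed form, Tg = T0 + B/ln(τ_ref/τ∞). The closed form is checked
  against bracketed root finding. For a condition with fewer than three
  usable relaxation times, the best-sampled same-pressure VFT curve is
  displaced horizontally through the single (T, τ) anchor and its Tg is
  shifted by the same amount; the displacement is computed in closed
  form through the same isochrone expression (a 1-D root search would
  return the identical value, since the VFT curve is strictly monotone).
* **Gordon–Taylor mixing** (`mixing`).
  Tg(W₂) = (W₁Tg₁ + K·W₂Tg₂)/(W₁ + K·W₂). K is a free fit parameter by
  default, with the pure-component Tg's anchored to their measured
  values; when heat-capacity increments are supplied instead, the
  convention K = ΔCp₂/ΔCp₁ (polymer over drug) is used and recorded in
  the parameter metadata, since the opposite convention also circulates
  in the literature. Inversion is closed-form and unique for K > 0;
  bisection serves as the oracle in tests. Calorimetric Tg's are the
  midpoint of a logistic step fitted with a shared linear baseline; a
  step below five times the residual noise raises a detection error.
* **Flory–Huggins liquidus** (`flory`). The melting-point-depression
  relation under *Model and conventions* below, with the volume ratio
  m = (Mw₂/d₂)/(Mw₁/d₁) from true densities and χ either constant
  (approach I) or χ(T) = A + B/T (approach II). The relation passes
  through the pure-drug anchor (φ = 1, Tm⁰) identically for every χ, so
  the anchor is never fitted as a datum.
* **Pressure transpositions** (`pressure`). A single constant ΔTg per
  pressure shifts the composition–Tg curve (per-composition deviations
  are reported as a spread diagnostic, not modeled); solubility points
  move by the difference of pure-drug melting points; ΔH_fus and
  densities are taken as pressure-independent over the 50 MPa range
  considered.

## Model and conventions for the liquidus fits

The liquidus residual is

    (1/Tm − 1/Tm⁰) + (R/ΔH_fus)·[ln φ + (1 − 1/m)(1 − φ) + χ(T)(1 − φ)²] = 0.

Because this is affine in 1/T for both χ models, the liquidus
temperature at fixed composition has a closed form, and the solubility
at fixed temperature is the largest root φ ∈ (0, 1) — the drug-rich
branch that annealing experiments sample. Root location scans 10⁴
log-spaced compositions for the sign change closest to φ = 1 and
polishes it with Brent's method (xtol 1e−14).

**Objective.** All χ fits minimize unweighted temperature residuals —
predicted liquidus T at each point's composition minus the observed
annealing T — by Levenberg–Marquardt with a χ² tolerance of 1e−9. This
matches how the data are plotted (T versus composition), keeps both χ
models on one objective, and keeps the fixed-B variant exactly nested.
Weight-percent → volume-fraction conversion uses the true densities.

**Sensitivity.** The choice of residual variable is not innocuous. On
the shipped seven-point ambient data set, minimizing temperature
residuals gives χ = −1.26 for approach I, while minimizing composition
residuals gives χ = −1.22; the approach-II parameters move by a few
percent between conventions. The reference study for this system quotes
χ = −1.17 ± 0.08, A = 6.695 ± 0.85, B = −2996 ± 324 and 14 wt% at
298 K without stating its residual convention; this package reproduces
the approach-II parameters and the 14 wt% prediction closely, while the
constant-χ value and several elevated-pressure/pooled quantities land
outside the quoted uncertainties under every convention we examined
(temperature residuals, composition residuals, point-wise χ
regression). Two further caveats compound this: the shipped tables are
rounded to integer weight percent, and the pooled-fit composition of the
reference analysis may differ from the plain union of the shipped
tables. The acceptance script reports what the package computes; it does
not tune toward the quoted values.

## Synthetic data

`synthetic` generates every input the pipeline consumes from the same
models the pipeline fits, seeded reproducibly (each generator draws from
its own seed stream, so adding one generator call never perturbs
another's noise).

* ε″ noise is multiplicative lognormal (default relative sd 1%): loss
  spans decades and additive noise would distort the low-loss wings;
  multiplicative noise preserves positivity.
* τ noise is additive in log10 (default 0.05 decades) — relaxation
  times span 8+ decades.
* Tg and solubility noise are Gaussian (defaults 0.5 K and 0.5 wt%,
  comparable to the scatter of the shipped measured tables).
* Δε(t) recrystallization traces are logistic decays; only a smooth
  monotone drop is needed to exercise onset/cessation detection, and no
  crystallization kinetics (Avrami or otherwise) are implied.
* The default frequency grid is 10 points/decade over 0.1 Hz – 1 MHz,
  the range of the broadband spectrometers these experiments use.

What the generator deliberately does not emulate: secondary relaxations
and excess wings, dc-conductivity transients, electrode polarization,
DSC melting endotherms, temperature-dependent HN shape parameters, and
non-Gaussian outliers. Passing round-trip tests therefore demonstrates
the correctness and statistical calibration of the estimators under the
stated noise models, not robustness to every artifact of real spectra;
the HN initialization heuristic in particular assumes a single resolvable
peak.

## Numerical choices

* HN and VFT fits take residuals on log10 of the data (decade-spanning
  quantities), with internal log10 parameterization of τ and Δε to keep
  positivity without constraints; shape parameters are box-bounded in
  (0, 1].
* HN initialization: τ_HN at the loss argmax, Δε twice the peak height,
  a = 0.9, b = 0.7. Fits whose peak lies more than one decade outside
  the measured window are flagged (`peak_in_window = False`) and such
  points are excluded from VFT fitting in the pipeline, as are
  crystallization-onset spectra by the same flag mechanism.
* Spectral/VFT solver tolerances are 1e−12 (these fits are cheap); the
  liquidus fits use the 1e−9 χ² tolerance that the reference study
  states for its own modeling.
* Degenerate inputs fail loudly: φ = 0 (divergent ln φ), T ≤ T0, Tg
  outside the mixing-curve range, all-equal compositions, flat
  thermograms, and empty Δε traces each raise a typed exception.

## Problem sizes in the test suite

Replicate studies use 50 seeded replicates; spectra use the 71-point
default grid (7001 points where an argmax oracle needs density); VFT
series use 8–12 temperatures spanning τ ≈ 1e−6–1e−1 s. The end-to-end
pipeline test runs eleven annealing conditions (seven ambient, four at
50 MPa) with eight spectra each. The full suite completes in well under
a minute on one core.

## Known limitations

* Only one relaxation process per spectrum; no ε′ fitting.
* No pressure-extended VFT; pressure enters only through separate
  per-pressure fits and the two vertical transpositions.
* Parameter uncertainties are asymptotic standard errors from the
  Levenberg–Marquardt covariance; they are reported but should not be
  over-interpreted for the 4-point high-pressure data set.
* The fitted-K Gordon–Taylor curve describes the shipped measured
  composition–Tg sets to ~1.3 K rms, but individual points deviate by
  up to 2.5 K, which propagates to ~2–3 wt% in inverted compositions at
  the polymer-rich end.
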