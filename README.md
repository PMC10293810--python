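# dtkin — direct-transfer kinetics of protein–polynucleotide competition

Many DNA- and RNA-binding proteins do not wait for their complex to fall
apart before exchanging ligands: a competing polynucleotide can partially
invade the occupied binding site and displace the resident ligand through a
short-lived ternary intermediate. This *direct transfer* (facilitated
dissociation) makes the apparent lifetime of a protein–ligand complex
depend on the concentration of competitors around it, with consequences for
how nucleic acid–binding proteins search chromatin and why so many
DNA-binders also bind RNA.

`dtkin` is a toolkit for measuring and modeling this behavior. It is aimed
at biophysicists analyzing fluorescence-polarization competitive-dissociation
(FPCD) plate experiments and single-molecule TIRF residence-time data, and
at anyone who wants a simulated testbed for such analyses.

## What it does

Under a chase of a preformed labeled complex with unlabeled competitor at
concentration D, the apparent off-rate follows

```
classic competition:  k_off_obs(D) = k₋₁ · D/(D + K_c)          (plateaus)
direct transfer:      k_off_obs(D) = k₋₁ · D/(D + K_c) + k_θ·D  (keeps rising)
```

where k₋₁ (s⁻¹) is the intrinsic dissociation rate, k_θ (M⁻¹s⁻¹) the
second-order transfer constant, and K_c the capture constant of the chase.
The package provides:

* **`dtkin.kinetics_core`** — mass-action ODE simulation of the competition
  scheme (simplified and partial-association/ternary variants), equilibria,
  the analytic k_off_obs(D) prediction, and the transfer-vs-classic
  pathway-flux partition k_θD/(k_θD + k₋₁).
* **`dtkin.fp_pipeline`** — the full plate chain: range normalization,
  one-phase exponential decay fits, k_off_obs extraction (initial-slope
  convention), classic-vs-transfer regression with BIC model selection,
  plus equilibrium K_d fitting (standard/Hill/depletion-quadratic) and
  FP stoichiometry breakpoints.
* **`dtkin.sm_pipeline`** — single-molecule analysis: hysteresis event
  detection on intensity traces, left-truncated exponential dwell MLE,
  photobleaching correction as a competing exponential, rate constants from
  ± competitor conditions, and two-color transfer-event classification.
* **`dtkin.synthesis_metrics`** — cross-interaction synthesis: hand-off
  proficiency HOP = log₁₀((k_θ/k₋₁)/reference), the zero-intercept
  k_θ-vs-k₋₁ trend with uncentered R², and flux-crossover concentrations.
* **`dtkin.synthetic_data`** — seed-deterministic generators for FPCD
  plates (driven by the ODE scheme, with the ~90 s dead time), binding
  isotherms, and single-molecule dwells/traces/two-color streams with
  photobleaching and hand-off events, plus a registry of literature-derived
  kinetic presets. Every generator returns its ground truth.
* **`dtkin` CLI** — `simulate`, `synth`, `fit-fpcd`, `fit-kd`, `fit-sm`,
  `synthesize`, `report`.

## Worked example

Simulate a plate from the bundled 25 °C TREX1/ssDNA self-competition preset
(k₋₁ = 7.0×10⁻³ s⁻¹, k_θ = 1500 M⁻¹s⁻¹) and run the full analysis:

```python
from dtkin.synthetic_data import generate_fpcd_dataset, get_preset
from dtkin.fp_pipeline import analyze_plate
from dtkin.synthesis_metrics import flux_crossover, hop_score

preset = get_preset("TREX1_ssDNA_25C")
plate, truth = generate_fpcd_dataset(preset, seed=7)
fits, profile, result = analyze_plate(plate, anchor_mode="plateau")

print(f"selected model : {result.selected}  (dBIC = {result.delta_bic:.1f})")
print(f"k_neg1P        : {result.k_neg1P:.2e} 1/s")
print(f"k_thetaD       : {result.k_thetaD:.3g} 1/(M s)")
print(f"HOP (ref 1e5/M): {hop_score(result.k_neg1P, result.k_thetaD, 1e5):+.2f}")
print(f"flux crossover : {flux_crossover(result.k_neg1P, result.k_thetaD)*1e6:.1f} uM")
```

prints

```
selected model : direct_transfer  (dBIC = -10.5)
k_neg1P        : 7.82e-03 1/s
k_thetaD       : 1.45e+03 1/(M s)
HOP (ref 1e5/M): +0.27
flux crossover : 5.4 uM
```

BIC prefers the transfer model by 10.5 points, and the two rate constants
come back within ~12% and ~3% of the generating values for this seed. The
positive HOP says this interaction transfers ligands faster than a
reference protein with the same intrinsic off-rate and the typical ratio
k_θ/k₋₁ = 10⁵ M⁻¹; the crossover says transfer carries half the
dissociation flux at ~5 µM competitor.

The same run from the shell:

```bash
dtkin synth fpcd --preset TREX1_ssDNA_25C --seed 7 --out out/
dtkin fit-fpcd out/fpcd_plate.csv --out out/
```

## Layout

```
src/dtkin/        library modules
tests/            pytest suite (unit, property, and end-to-end recovery)
scripts/          acceptance script
docs/methods.md   model assumptions, estimator conventions, limitations
```
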