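# Methods

## The kinetic model

A protein **E** binds a fluorescently labeled ligand **P** and an unlabeled
competitor **D** (in self-competition experiments P and D are the same
polynucleotide, distinguished only by the label). Classic competition
assumes the EP complex dissociates at an intrinsic rate k₋₁P regardless of
free competitor; the competitor matters only by capturing free protein and
preventing rebinding. Direct transfer (also called facilitated
dissociation) adds a bimolecular exchange channel

```
EP + D  →  ED + P        rate k_θD · [EP][D]
```

in which the competitor partially invades the occupied binding site and
displaces the resident ligand through a ternary intermediate too
short-lived to accumulate. Under a chase, the apparent off-rate of the
labeled complex then grows linearly with competitor instead of plateauing:

```
k_off_obs(D) = k₋₁P · k₁D·D / (k₁D·D + k₁P·P_free)  +  k_θD · D
```

The first term is the classic capture hyperbola (a dissociated protein is
captured by competitor at rate k₁D·D or rebinds the trace labeled ligand at
rate k₁P·P_free); the second is the transfer channel. For fitting we
parameterize the hyperbola with a single capture constant K_c rather than
the individual association constants, which are not identifiable from chase
data:

```
classic:          k_off_obs = k₋₁P · D / (D + K_c)
direct transfer:  k_off_obs = k₋₁P · D / (D + K_c) + k_θD · D
```

(2 and 3 free parameters respectively). The two models are compared by
BIC = n·ln(RSS/n) + p·ln(n) on a common weighted-least-squares likelihood
scale; |ΔBIC| < 2 is reported *indeterminate* and defaults to the simpler
classic model. When classic is selected, k_θD is reported as 0 and the
hand-off score as "n/a".

### Reaction schemes

`kinetics_core` integrates two mass-action ODE schemes (molar and seconds
throughout; stiff-capable solver, default LSODA with rtol 1e-8 and
atol 1e-12 M, configurable):

* **simplified** — species {E, P, D, EP, ED} with association,
  dissociation, and the two transfer steps (EP + D ⇌ ED + P).
* **complete** — adds partially associated complexes EP\*, ED\* (site
  "breathing": EP ⇌ EP\* with opening/closing rates ν_open, ν_close) and
  two symmetric ternary species D·EP\* and P·ED\*, each formed from either
  side at a common docking rate and resolving to either side with equal
  probability. This is one concrete instantiation of the partial-association
  picture; with an open-state occupancy f = ν_open/(ν_open+ν_close) and two
  parallel ternary channels, the effective transfer constant is
  k_θ = f · k_ternary_on. `complete_rates_from_effective` inverts this
  mapping, and with partial-state rates ≥100× all other first-order rates
  the complete scheme reproduces simplified EP(t) within 2% (a tested
  invariant). The symmetric topology requires k_θD = k_θP.

Equilibria are computed independently of the ODEs by bracketed root-finding
on the free-protein conservation relation; a transfer channel satisfying
detailed balance (k_θD/k_θP = K_dP/K_dD) cannot shift them, which is
exposed as a consistency check (warning by default, error in strict mode —
fitted transfer constants are generally not constrained this way).

The relative flux through the transfer versus classic pathway at competitor
effective molarity D is k_θ·D / (k_θ·D + k₋₁); it crosses 1/2 at
D = k₋₁/k_θ. With the typical ratio k_θ/k₋₁ ≈ 1e5 M⁻¹ the two pathways
carry equal flux near 10 µM competitor.

## Plate pipeline (`fp_pipeline`)

1. **Normalization.** Polarization is mapped to fraction of initial complex
   using anchors for the bound ceiling and free floor. Three anchor
   policies: exact global extrema (default), quantile anchors
   (1st/99th percentile, outlier-resistant), and *plateau* anchors — the
   mean of the lowest-competitor condition (whose complex persists) and the
   mean of the final reads of the highest-competitor condition (fully
   decayed). Extreme-value anchors on a noisy plate are biased outward by
   2–3 noise SDs, which deflates every fitted rate on the plate by the same
   factor; the averaged plateau anchors remove this correlated error and
   are what the recovery benchmarks use.
2. **Decay fitting.** Each well is fit with F(t) = A·exp(−k·t) + c by
   bounded least squares from a deterministic grid of 8 log-spaced rate
   starts (no RNG in fitting). Readings before the initiation–measurement
   dead time (default 90 s) do not exist; fits extrapolate to reaction
   initiation. The amplitude is bounded to [0, 1.3] because the normalized
   fraction lives in [0, 1] — without this, fast chases observed only after
   the dead time wander along the k–A likelihood ridge. Fits with
   amplitude < 0.2 or a window shorter than one decay time are flagged
   *partial*, reported but caveated, never silently dropped.
3. **k_off_obs convention.** Default is the initial slope of the normalized
   decay, k·A, which equals the apparent off-rate even for
   partial-dissociation curves that relax to a nonzero plateau (where the
   bare exponential rate k is inflated by rebinding). The bare-rate
   convention is selectable; the two agree when dissociation is complete.
4. **Profile regression.** Per-concentration means ± SD over replicates are
   regressed with both models; inverse-variance weighting is used when ≥3
   replicates per point are available, else unweighted; multi-start over
   capture-constant and slope scales, deterministic.

Equilibrium isotherms are fit with the standard hyperbola, the Hill form,
or the exact 1:1 binding polynomial with ligand depletion; an apparent K_d
at or below the ligand concentration (or the lowest tested protein
concentration) is flagged ligand-limited, since the true K_d could be
lower. Stoichiometry titrations in the tight-binding regime are fit with a
two-segment rising-line/plateau model; stoichiometry = ligand/breakpoint.

## Single-molecule pipeline (`sm_pipeline`)

Binding events are segmented from per-particle intensity traces by
hysteresis thresholding (enter above the high threshold, exit below the
low; defaults from median ± multiples of 1.4826·MAD), with a 2-frame
minimum dwell and censoring of events that run off the trace end. Dwell
times are fit by the left-truncated exponential MLE
k = n / Σ(tᵢ − t_min), exact by memorylessness; censored dwells are
excluded by default (matching naive PDF regression) or contribute survival
exposure via an option. Photobleaching is a competing exponential: the
observed rate is the departure rate plus k_b, so correction subtracts a
bleach rate measured from a non-dissociating control, and the attributable
fraction k_b/k_off_obs is reported. Rate constants follow from
k_off_obs(D) = k₋₁ + k_θ·D across a zero-competitor and a chase condition;
a negative implied k_θ is clamped to 0 with a warning.

Dual-color transfer events pair one channel's departure with the other
channel's arrival at the same (pre-colocalized) particle within a ternary
window (default 150 ms, matching the lifetime bound on the intermediate);
sustained double occupancy is not a transfer, and the detector is symmetric
under channel swap.

## Synthesis metrics (`synthesis_metrics`)

The hand-off proficiency (HOP) score is implemented as
log₁₀((k_θ/k₋₁)/reference). The reference defaults to the fitted
through-origin slope of the loaded record set, so a score of 0 means
average for those interactions; a fixed 1e5 M⁻¹ preset is provided for
reproducibility. This is the simplest definition consistent with a
normalized log-ratio metric; published scores computed under other
normalizations are not comparable number-for-number, and the package makes
no claim to reproduce them. The k_θ-vs-k₋₁ trend is a zero-intercept
least-squares line on linear axes (slope = Σxy/Σx²) with the uncentered
R² = 1 − RSS/Σy², the standard convention for through-origin models (a
centered alternative is available).

## Synthetic data (`synthetic_data`)

The generator bundles a registry of kinetic presets (k₋₁, k_θ, apparent
K_d, temperature) spanning the surveyed interactions — hnRNP-U/G4 RNA,
TREX1/ssDNA and dsDNA, FBF-2/PUF RNA, MS2-CP/hairpin RNA, a
streptavidin–biotin classic-competition control, and the single-molecule
TREX1 estimate — with association constants fixed by k₁ = k₋₁/K_d.

**FPCD plates.** The labeled complex (5 nM ligand, 100 nM protein) is
pre-equilibrated without competitor; competitor is added at t = 0 and the
simplified scheme integrated per concentration; bound fraction maps
linearly to polarization between 60 mP (free) and 200 mP (bound, arbitrary
but recorded); i.i.d. Gaussian noise of 2.8 mP (2% of the range) is added
per replicate; reads before the 90 s dead time are dropped. The default
chase series (0, 0.3, 0.6, 1, 2, 3, 4.5, 6 µM; 4 replicates; 10 s reads
for 1800 s) encodes three assay constraints: a zero-competitor well anchors
the bound ceiling; the lowest chase concentration sits far enough above the
protein concentration that free protein is sequestered within seconds; and
the top concentration keeps the fastest decay resolvable after the dead
time (k_off·90 s ≲ 1.5). A named carrier species can be declared to hold
total polynucleotide constant; it binds nothing and changes no rates — its
role is bookkeeping parity with carrier-control designs.

**Isotherms.** Hill-form bound fractions (n_H = 1 reduces to the standard
hyperbola) or exact depletion curves, over a 12-concentration titration in
duplicate wells with the same noise model.

**Single molecule.** Dwells are drawn from the competing-risks exponential
with rate k₋₁ + k_θ·D + k_b, each termination labeled
dissociation/transfer/bleach in the ground truth (counts always add up to
the total, a tested invariant); observed dwells are sampled directly above
the resolution limit t_min using memorylessness. Trace mode renders
two-level signals with Gaussian noise of SD 1/SNR; two-color mode emits
paired event streams where a configurable fraction of departures hand off
to the other channel within half the ternary window (two-color fixtures
use a 50 ms frame interval so the window is resolvable on the frame grid).

**What the generator does not emulate:** baseline drift and temperature
gradients across a plate, heteroscedastic or heavy-tailed polarization
noise, aggregation at high polynucleotide concentration, non-exponential
(multi-state) dissociation, fluorophore blinking, and drift or stage
registration error in the microscope. Passing recovery tests therefore
show the estimators are correct for data obeying the stated model, not
that real instruments are free of these artifacts.

## Benchmark problem sizes

The recovery benchmarks use plates of 8 concentrations × 4 replicates with
recovery medians taken over 25 simulated experiments (9 in the quicker
test-suite variant); single-molecule recovery uses 2000 events per
condition over 3 repeats; model-selection rates use 200 noisy profiles per
generating model at 5% multiplicative noise. At these sizes the
plate-pipeline medians for the 25 °C ssDNA self-competition preset land
within a few percent of the generating constants (per-experiment scatter
is ~10% for k₋₁ and ~20% for k_θ), and BIC selects the generating model in
≥95% of classic and ~100% of transfer repeats.

## Known limitations

* The initial-slope estimator extrapolates across the dead time; for
  chases faster than ~1.5/dead-time the amplitude is regularized by its
  physical bound rather than measured, and recovered rates inherit a few
  percent of bias (real assays footnote the same regime as "early partial
  dissociation curves").
* K_c is barely identifiable when every tested concentration is
  capture-saturated; it is reported with its standard error but should be
  read as a nuisance parameter.
* The complete scheme's topology is one plausible instantiation of partial
  association; only its fast-exchange limit is constrained by data.
* Two-color transfer detection assumes colocalization has already been
  established upstream; coincident independent rebinding within the ternary
  window is counted as transfer (rare at realistic arrival rates, ~0.3%
  per window at the default 0.02 s⁻¹).
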