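# Methods

`enosesim` simulates the data produced by an array of conducting-polymer
gas sensors (an "electronic nose") exposed to pulses of up to three
analytes — A (ammonia), B (propanoic acid) and C (n-butanol) — and
provides the surrounding machinery a practitioner needs to benchmark
signal-processing and pattern-recognition algorithms on such data:
scenario definition, feature extraction and a difficulty-graded
classification harness.

## Input protocol

Concentrations are expressed in volume-fraction percent (vol.%). The
dynamic ranges are A, B: 0.01–0.05 vol.% and C: 0.1–1 vol.%.
Concentrations outside these ranges are legal inputs — the saturation
region is a deliberate use case — but raise a warning at parse time.

A measurement cycle (gas pulse) is a cleaning phase of `tunit` samples of
air followed by an exposition phase of `tunit` samples at the label's
concentration, sampled once per time unit. The last cleaning sample is
tagged `airout` (the baseline), the last exposition sample `gasout` (the
steady-state value); first/interior samples of each phase are tagged
`airin`/`air` and `gasin`/`gas`. With `tunit = 1` each phase is a single
sample tagged with the `out` labels, so steady-state and step extraction
remain defined. The long-pulse protocol uses `tunit = 60`: three pulses
then place their `gasout` tags at time units 120, 240 and 360 (1-based).

## Simulation models

**Sorption.** A sensor's binding sites are occupied according to the
competitive (extended) Langmuir isotherm,

    x_j = K_j c_j / (1 + Σ_k K_k c_k),

with per-analyte affinities K_j (1/vol.%). The law is linear at low
loads, saturating at high loads, and competitive: raising any analyte's
concentration strictly lowers every other occupied analyte's sorbed
fraction. The nonlinearity slot `alpha` multiplies all affinities
elementwise (identity at 1, zero forbidden); larger `alpha` means deeper
saturation and stronger mixture penalization. The default is 2.25.

**Calibration.** The steady-state signal is affine in the sorbed
fractions, `y_ss = b0 + Σ_j b_j x_j`; the air response is the baseline
`b0` (fixed at 1.0 — signal units are arbitrary, only relative responses
matter downstream). The diversity slot `beta` re-draws each sensitivity
from `Uniform(b_j (1 ± beta · h_j))` with relative half-width `h_j = 0.1`,
so two sensors of the same type are distinct replicas unless `beta = 0`.
Default `beta = 2` (moderate diversity).

**Transient dynamics.** Signals relax toward the instantaneous steady
state with one first-order step per time unit,
`y ← y + (y_target − y)/τ`, using `τ_rise` during exposition and
`τ_decay` during cleaning, drawn per prototype from [4, 10] time units.
The residual gap after m steps is exactly `(1 − 1/τ)^m` of the initial
gap, so a 60-unit phase at τ ≤ 10 is quasi-stabilized well within 1% —
steady-state extraction at `gasout` is consistent with the transient
model. At `tunit = 1` the transient layer is bypassed (τ treated as 1).

**Noise.** Three independent injectors, each with a level where 0 is
noise-free and 1 the reference level; output variance scales with the
square of the level. Defaults are 0.1 (moderate).

* *Concentration noise* (`csd`): one zero-mean Gaussian delivery-error
  draw per pulse with covariance `csd² Σ_c`, applied only to the analytes
  present in the gas and clipped at zero.
* *Sensor noise* (`ssd`): each sensor's sensitivity vector is perturbed
  once per pulse with covariance `ssd² Σ_s` (per prototype).
* *Drift* (`dsd`, alias `dcsd`): a random walk in a fixed low-rank
  subspace of sensor space. The basis D (unit-norm orthonormal columns,
  one per drift component, `ndcomp ∈ {1,2,3}`) is realized per array
  size; the latent coordinates advance once per pulse with step variance
  `dsd² · step_sd² · ndvar_i`, and the per-sensor offsets `D z` are added
  to all samples of the pulse. Importances default to 0.86 (one
  component) or (0.86, 0.06, 0.05) (three). Because offsets are constant
  within a pulse, baseline subtraction cancels drift exactly.

Noise levels can be changed on the fly (`nsd`); each noise source
consumes its own named random substream keyed by (master seed, source,
sensor index, pulse index), so toggling one source never shifts
another's draws and serial and parallel execution are bitwise identical.

## The synthetic prototype bank

The 17 sensor prototypes are generated, not measured: real
parameter sets estimated from long-term conducting-polymer recordings
are not redistributable here, so `generate_profile_bank(seed)` builds a
bank with the same documented structure. Each type receives an A-vs-C
selectivity fraction from a fixed ladder plus a small seeded jitter —
types 1–3 are C-selective at mid-range concentrations, types 13, 14 and
17 A-selective, the rest interpolate — and a mid-range total occupancy
`Σ K_j c_j ∈ [0.4, 0.9]` at `alpha = 1`, which places the default
`alpha = 2.25` responses visibly into the saturation regime at the top
of each dynamic range. B acts as a minor interferent (10–30% of the
occupancy budget). Sensitivities are uniform in [2, 6] signal units.

Reference noise magnitudes are design choices, made once: the
concentration-noise standard deviation at level 1 is 10% of each
analyte's mid-range (gas-delivery imprecision), the coefficient-noise
standard deviation is 5% of the coefficient — inflated to 25% on the A
channel for types 13/14/17, which is what makes those types "very noisy
in response to A" — and the drift step scale is 0.1 signal units per
pulse, which accumulates over a ~200-pulse campaign to a spread
comparable to the clean signal range.

What the generator does *not* emulate: temperature/humidity covariates,
sensor aging other than subspace drift, kinetic sorption effects,
second-order transients and inter-analyte sensitivity correlations.
Passing tests therefore demonstrate correctness of the simulation
machinery and of qualitative structure (selectivity, saturation, drift
geometry), not quantitative agreement with any physical sensor.

## Scenarios, features, benchmark

A `Scenario` lists `(label, count)` pairs for a training and a
validation set, with optional seeded randomization of pulse order within
each set (training always precedes validation). Feature extraction
yields `transient` (all samples), `ss` (the `gasout` sample per pulse)
or `step` (`gasout` minus the same pulse's `airout` — the standard
drift-correction feature) tables joining concentrations, features and
annotations, exportable as CSV. Exploratory backends compute mean-centred
PCA scores with variance fractions and per-label boxplot statistics.

Scenario difficulty is a property of the gas classes alone — the
similarity of the two mixtures — independent of any sensor model:
level 1 is A 0.02 vs C 0.5, level 2 is A 0.01, C 0.6 vs A 0.03, C 0.4,
level 3 is A 0.015, C 0.55 vs A 0.025, C 0.45. The harness simulates
step features (100 pulses per class per set by default), tunes a
k-nearest-neighbours classifier over k ∈ {3, 5, 7, 9} by repeated
stratified 10-fold cross-validation with PCA preprocessing fit on
training folds only (components retained up to 95% variance, exposed as
a flag), breaks ties toward the smaller k, and reports cross-validated
training accuracy and held-out test accuracy.

## Numerical and design notes

* Cleaning precedes exposition within a pulse; this is what places
  `gasout` at 120/240/360 for three 60-unit pulses and guarantees every
  steady-state sample has a same-pulse baseline preceding it.
* Pulse boundaries of raw (unannotated) concentration matrices are
  inferred from gas→air transitions; annotated matrices carry an
  explicit `pulse` column.
* Type recycling: when fewer types than sensors are listed, types repeat
  cyclically (e.g. types (1,2,3) over 12 sensors).
* PSD covariances are factored by Cholesky with an eigendecomposition
  fallback for singular matrices; the drift basis comes from a seeded QR
  with a sign convention making it unique.
* PCA is mean-centred and unscaled by default (common sensor-array
  practice); scaling is a flag. Degenerate zero-variance input returns
  zero scores and zero variance fractions rather than NaN.
* KNN vote ties cannot occur with odd k on two classes; the tuning
  tie-break (smallest k) keeps results deterministic.
* Suite problem sizes: Monte-Carlo checks of the noise scaling laws use
  1e5 draws (±3%), drift variance shares 1e4 steps (±5%), and the
  difficulty-ordering check averages 10 seeded benchmark repetitions
  with 2 cross-validation repeats each; the headline difficulty-1 run
  uses the full 10×10 cross-validation.

## Known limitations

* The bank is synthetic; absolute signal magnitudes and error rates are
  not comparable with any laboratory dataset, and the harder benchmark
  levels (2–3) are meaningful only as an ordering, not as absolute
  accuracies.
* Drift is within-pulse constant; sub-pulse drift (which step features
  would only partially cancel) is not modelled.
* Only three analytes are supported; the models are defined for A, B, C.
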