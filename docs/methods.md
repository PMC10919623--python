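# Methods

This note documents the models, defaults, and design decisions behind
`wearsite`: what the synthetic-data generator emulates, how the metabolic
ground truth is derived, how the count baseline and the sequence
classifiers are built, and what the package's tests do and do not show.

## 1. The study design being emulated

The package targets the design of calorimetry-validated, multi-wear-site
accelerometer studies: adults and children visit a laboratory once, rest
seated for 10 minutes, then perform 7 activity bouts drawn from a
17-activity catalog — 3 from sedentary/daily-living activities, 3 from
light-or-moderate physical activities, 1 vigorous — each 5 minutes long,
extended up to 8 minutes when needed to secure at least 3 steady-state
minutes, with ~3-minute rests between bouts. Triaxial accelerometers
record at 100 Hz on the hip, the wrist, and the chest (suspended from a
lanyard); a portable metabolic cart measures VO₂ per kg throughout.

No such raw dataset is publicly available, so the generator reproduces the
*statistical structure* rather than any particular recording:

* **Demographics.** Age, BMI and resting VO₂ are drawn per group from
  normal distributions — adults 26.9 ± 8.7 y, BMI 21.8 ± 2.0,
  resting VO₂ 4.09 ± 0.98 ml/kg/min; children 12.1 ± 2.3 y, BMI
  18.3 ± 2.5, resting VO₂ 5.71 ± 1.91 — truncated *symmetrically about the
  mean* (lower bound at the group age floor), which preserves the
  configured means exactly at the cost of thinner tails. Child height
  follows a crude linear growth curve (≈4.8 cm/year past age 6); weight is
  derived from BMI and height.
* **Metabolic load.** Each bout's latent intensity is drawn as
  MET ~ Normal(μ_c, σ_c) truncated above 0, with category parameters
  (adults: living/light 1.7 ± 0.9, moderate 5.8 ± 1.9, vigorous 8.2 ± 2.3;
  children: 1.8 ± 1.0, 4.8 ± 1.5, 7.7 ± 2.1). The latent draw is stored in
  the session object and the manifest, so parameter-recovery tests compare
  pipeline output against values the pipeline never saw.

## 2. Signal model (invented, and why)

The source design reports no signal-level properties of its recordings, so
the acceleration model is the package's own. It is deliberately minimal: it
carries exactly the three cues the downstream classifiers need, and
nothing else.

    a(t) = g_site + wobble(t) + m(t) + ε(t)

* **Orientation → wear-site.** Each site has a fixed gravity unit vector
  (hip/wrist/chest mutually ≥ ~38° apart, configurable minimum 15°) plus a
  slow postural wobble (0.015 g at 0.05 Hz). This is the dominant cue for
  wear-site detection, as it is for real devices.
* **Amplitude and periodicity → intensity.** The movement component m(t)
  has RMS `amp_per_met · (MET−1)^0.8 · site_gain · (55/weight)^0.4 ·
  (18/age)^0.15` with `amp_per_met = 0.08 g` and site gains
  wrist 1.45 > hip 1.0 > chest 0.85. Locomotor activities superimpose gait
  harmonics at a step frequency `clip(1.0 + 0.28·MET, 1.2, 3.4) Hz` (3
  harmonics, wrist arm-swing at half the step rate); non-locomotor
  activities use 0.5–6 Hz band-limited noise. All movement includes a
  0.3–1.5 Hz trunk-sway/stride-modulation component (35% of RMS) — real
  locomotion has substantial energy below the step rate, and without it
  band-pass count algorithms would see almost nothing at running cadences.
  The chest adds a 0.7 Hz lanyard-swing oscillation. Sensor noise is white
  with σ = 0.01 g.
* **Anthropometric coupling → covariates.** Because the amplitude-to-MET
  map depends on weight and age, two participants at the same MET produce
  different amplitudes; knowing (age, height, weight) disambiguates, which
  is what makes covariate-augmented intensity models measurably better on
  this data — by construction, mirroring the phenomenon rather than proving
  it for real signals.

`amp_per_met` was set so hip vertical-axis counts land in conventional
counts-per-minute ranges for walking (≈2.6k cpm at MET 3, ≈5.5k at MET 6);
all constants are exposed in `SignalConfig`.

**Calorimetry.** VO₂ is emitted in 5-s bins (breath-by-breath variation is
not modeled; only steady-state averages are consumed downstream). During a
bout it rises with a first-order lag (τ = 45 s) normalized to reach the
plateau `MET_draw × resting VO₂` exactly at the end of a 120-s
on-transient, then stays flat plus noise (σ = 0.02·plateau + 0.05). A
configurable 5% of bouts never settle: their VO₂ ramps toward 1.4× the
plateau for the whole bout, so the steady-state detector excludes them.
Rest-gap recovery decays exponentially back to baseline.

## 3. Ground truth

* Resting VO₂ = mean over minutes 6–9 of the rest period. The rest
  period's own MET value is therefore exactly 1.0 — the ratio is
  definitional, which is why the package asserts it as an identity.
* Steady-state detection: the bout is steady if some suffix ≥ 180 s has
  |least-squares slope| ≤ `trend_slope_tol`, scanned longest-first. The
  published criterion is visual ("no clear trend"); the quantitative
  default 0.3 (ml/kg/min)/min is ≈3× the sampling SD of the slope
  estimator over a 3-min window at the generator's noise level, so flat
  segments pass and true drifts fail. The *returned* value averages only
  the final 180 s of the admissible window: a longest-suffix mean retains
  a small on-transient deficit (up to ~tol·window/2, measured ≈ −1% even
  at the tightened tolerance) that the slope test cannot see, whereas the
  final-window mean is unbiased once the plateau is reached.
* Boundary METs belong to the upper class (1.5 → light, 3.0 → moderate,
  6.0 → vigorous), matching the defining inequalities.
* One intensity label per bout; excluded bouts propagate no windows.

## 4. Count baseline

Counts follow the published frequency-band emulation of device counts:
resample to 30 Hz → 0.29–1.63 Hz band-pass (order 3, DC-matched initial
conditions so constant gravity contributes exactly zero) → decimate to
10 Hz → rectify → 0.068 g dead-band → 2.13 g saturation → 1/128 g
quantization → per-second and per-epoch sums. Firmware parity is not
claimed; every constant is in `CountsConfig`. Default epoch 60 s on the
vertical (y) axis. Hip cut-points: adults 100 / 1952 / 5725 cpm, children
100 / 2296 / 4012 cpm (the children's protocol rescaled from its native
15-s epoch; both sets overridable). Misspecification reports show, per
group × true intensity, the percentage of epochs classified under / at /
over the truth, with group-combined and all-combined rows.

## 5. Sequence classifiers

Hidden sizes, optimizer, and batch size are unstated in the source design;
the defaults here are the package's own: recurrent units 32, dense units
32, dropout 0.5, conv 16 filters of width 5, maxpool 2, batch 64, Adam at
1e-3 with a step decay (halved every 8 epochs — under heavy dropout a
constant rate leaves the final epochs oscillating by several accuracy
points, and the reported value is the final epoch's), 20 epochs,
final-epoch validation accuracy reported (best-epoch selection
available). Units were sized for 1-second windows trained on a
single CPU core; doubling them changes the scaled-down accuracies by well
under the run-to-run seed variation. The networks are implemented in numpy
with hand-derived backpropagation (verified against central finite
differences to ~1e-6 relative error) because the package has no deep
learning framework dependency; training is bitwise deterministic given the
config seed. Covariates enter by concatenation to the recurrent output
before the dense layer, standardized with training-split statistics only.

The default split replicates the window-random 90/10 scheme. Note that it
places windows from the same participant — even the same bout — on both
sides, so its accuracies measure within-cohort discrimination, not
generalization to new wearers; `scheme="by_participant"` is the
leakage-safe alternative and is recommended for any generalization claim.

## 6. Problem sizes and what the tests show

The acceptance script and the heavier tests run a scaled-down surrogate of
the full design: 12 participants (6 adults, 6 children), hip + wrist,
sessions at full protocol length, subsampled to 10,000 windows before the
90/10 split, 20 training epochs — sizes chosen so the whole suite runs
comfortably on one CPU core. Parameter-recovery checks use 500
participants per group (calorimetry only). With generator defaults the
full 54-participant, 3-site design yields on the order of 10⁵ windows,
consistent with the scale of the emulated study.

Passing tests demonstrate that the pipeline is internally correct — exact
identities hold, configured distributions are recovered within sampling
error, the classifiers extract the cues the generator encodes — not that
any accuracy would transfer to real recordings, whose orientation drift,
device noise, and behavioral variability the generator deliberately does
not model (no biomechanical simulation, no non-wear, no device binary
formats, no heart-rate modeling).

## 7. Numerical and degenerate-input choices

* Seeds: every stochastic operation takes an explicit seed; sessions
  spawn per-site/per-bout substreams from `numpy.random.SeedSequence`.
* Argmax ties break to the lowest class index; probability rows sum to 1
  within 1e-5.
* Bouts shorter than one trimmed window contribute zero windows (logged,
  not an error); an empty split side, a single-class training set, and a
  missing covariate profile are errors.
* Recording CSV round-trips are lossless at 1e-6 g; malformed or
  non-monotone rows are rejected with line numbers.
* Epoch grids tile from the recording start; partial trailing epochs are
  dropped.
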