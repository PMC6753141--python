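# Methods

## The measurement being modelled

A subject places five fingers on fingertip electrodes; a constant sinusoidal
current is routed through each of the 10 finger pairs in turn, and the RMS
voltage gives the impedance magnitude |Z| at 25 frequencies from 20 kHz to
500 kHz in 20 kHz steps. One placement therefore yields 10 spectra × 25
frequencies = 250 raw values. Only magnitudes are modelled: an RMS-to-DC
detector discards phase. Frequencies below 20 kHz are excluded because
contact pressure and skin hydration dominate there.

## Equivalent-circuit model

Each tissue compartment is a "Z block": a series resistance `Rs`
(extracellular fluid; plus skin resistance at the electrode interfaces) in
series with `Rp ∥ Cp` (intracellular fluid resistance shunted by membrane
capacitance),

```
Z(f) = Rs + Rp / (1 + j·2πf·Rp·Cp).
```

|Z| falls monotonically from `Rs + Rp` at DC toward `Rs` at high frequency.
A finger pair is four blocks: `Z_total = Z1 + (Z2 ∥ Z3) + Z4`, where Z1 and
Z4 are the two electrode/epidermis interfaces and the interior is the
dermis path Z2 in parallel with the sweat-gland/duct path Z3. The wiring
follows the standard electrode–skin equivalent-circuit tradition, in which
the sweat ducts shunt the deeper tissue between the two interface layers.

A uniform physiological state change (temperature, hydration, blood flow)
is modelled as `R → s·R`, `C → C/s` for every component. Every time
constant `Rp·Cp` is preserved, so the complex spectrum scales by exactly
`s`, and the ratio of two pairs' spectra is invariant to machine precision.
This is the unique one-parameter scaling with that exactness property, and
it is the premise of the ratiometric features.

## Synthetic cohort generator

Real multi-session finger-impedance datasets of this geometry are not
publicly available, so experiments run on generated cohorts with the
structure the method assumes:

* **Anatomy.** Each subject owns five finger half-circuits (epidermis,
  dermis, sweat blocks) plus a body resistance, drawn log-normally around
  fixed medians (epidermis 300 Ω / 5 kΩ / 30 nF, dermis 150 Ω / 1 kΩ /
  10 nF, sweat 500 Ω / 2 kΩ / 5 nF, body 100 Ω) with log-sigma
  `subject_sigma = 0.2` (~20 % coefficient of variation). The medians are
  order-of-magnitude plausible for fingertip tissue at 20–500 kHz; no
  component values are printed in the source, and no conclusion here
  depends on their exact values. A pair circuit takes finger *a*'s
  epidermis as Z1, finger *b*'s as Z4, and forms Z2/Z3 by collapsing the
  two fingers' dermis (and sweat) blocks in series — series resistances
  add, parallel-branch resistances add, capacitances combine harmonically —
  with the body resistance absorbed into Z2's series term. Pairs sharing a
  finger share its parameters exactly, inducing realistic correlation
  among the ten spectra.
* **Session drift.** Each (subject, session) draws one state scale
  `s = drift · (1 + γ·(T_ref − T))` applied to all ten pair circuits:
  `drift` is log-normal with sigma `drift_sigma = 0.2`, temperature `T` is
  uniform on 29–37 °C, `γ = 0.02 /°C` and `T_ref = 33 °C`. The linear
  inverse-temperature form encodes the observed monotone inverse
  dependence of mean impedance on hand temperature; only the direction,
  not the functional form, is established by data. Drift is purely
  common-mode by default; `drift_heterogeneity > 0` optionally gives each
  pair an extra independent log-normal factor to study robustness when the
  common-mode assumption is imperfect.
* **Noise.** Each (placement, pair) spectrum is multiplied by `exp(ε)`,
  `ε ~ N(0, noise_sigma²)` with `noise_sigma = 0.02`, standing in for
  electrode re-placement and contact variation. The magnitude is a chosen
  default, not a calibrated one — within- vs between-session variance
  magnitudes are not reported for the real system.

Datasets are exactly reproducible from a single integer seed. The default
geometry mirrors the real study (41 subjects × 5 sessions × 10 repeats);
tests and the benchmark use 8 × 3 × 5 to keep the full suite fast on one
CPU.

**What passing tests show — and don't.** The generator realises the
common-mode drift model exactly, so results on it demonstrate the internal
logic of the method: ratio features cancel what the model says they should
cancel, and classifiers behave accordingly. They do not establish
performance on real hands, where drift is only approximately common-mode,
noise is structured, and anatomy differences are not log-normal. The
published headline numbers derive from an undeposited 41-subject dataset
and are deliberately not targets of this package's experiments; only the
*direction* of the raw-versus-ratiometric comparison is asserted.

## Ratiometric features and combination selection

The transform divides pair spectra element-wise at equal frequency:
feature (c, f) = |Z_num(c)(f)| / |Z_den(c)(f)|, combinations in a fixed
order, frequencies ascending — 250 values, the same dimensionality as the
raw input. Constraining each pair to appear exactly once as numerator and
once as denominator makes the assignment a fixed-point-free permutation
(derangement) of the 10 pairs; a telescoping consequence is that the
product of the ten features at any frequency is 1, i.e. the features'
log-scales are balanced around zero by construction.

The default combination set is the fixed published list — (1,2)/(4,5),
(1,3)/(1,2), (1,5)/(1,3), (1,4)/(1,5), (2,3)/(1,4), (2,5)/(2,3),
(2,4)/(2,5), (3,5)/(2,4), (3,4)/(3,5), (4,5)/(3,4) — whose induced
permutation is a single 10-cycle. Data-driven selection is opt-in and
formalises "balanced scale" on the log axis: with `M_p` the training mean
of `log|Z_p(f)|`, choose the derangement σ minimising
`Σ_p (M_p − M_σ(p))²`. Log scale makes the numerator and denominator roles
symmetric and makes the deviation-from-average criterion well defined (the
derangement mean of log-features is identically 0). Whether the original
selection was computed on linear or log ratios, per subject or pooled, is
not documented; this formalisation is this package's own. The problem is a
linear assignment with the diagonal forbidden and is solved exactly with
the Hungarian method (`scipy.optimize.linear_sum_assignment`); ties are
resolved to the lexicographically smallest assignment list by fixing one
position at a time and keeping only choices that still admit an optimal
completion (tolerance 1e−9 relative). An exhaustive-enumeration oracle
checks the solver on instances with up to 6 items.

## Evaluation protocol

**Leave-one-session-out CV.** One fold per (subject, session): that
session's records of that subject are validation, everything else trains.
This tests exactly the cross-day generalisation that session drift breaks.
Subjects with fewer than two sessions are rejected by name.

**Classifiers and hyperparameters** (fixed, taken as given, no re-search):

| family | settings |
|---|---|
| linear SVM | C = 1.0, kernel scale 16 |
| quadratic SVM | polynomial degree 2, C = 1.0, kernel scale 16, coef0 = 1 |
| KNN | k = 1, Euclidean |
| bagged trees | 30 trees, Gini, ≤ 2165 splits (≤ 2166 leaves) per tree |

SVM features are z-scored on training-fold statistics and then divided by
the kernel scale; the scale value is meaningful relative to standardized
features (the convention of mainstream SVM toolboxes, which standardize by
default before applying a kernel scale), and without standardization a
fixed scale of 16 cannot suit both ohm-valued raw spectra and order-one
ratio features. KNN and the trees use
the features natively (trees are scale-invariant). Multiclass SVM uses
one-vs-one decomposition with one-vs-rest-aggregated decision values
(scikit-learn's `decision_function_shape="ovr"`).

**Scores.** Open-set thresholding needs sweepable per-class confidences in
[0, 1]: a softmax over SVM decision values; for 1-NN a softmax over the
negated distance to each class's nearest training point (raw 1-NN votes
are 0/1 and cannot be swept); vote fractions for the bagged trees. A
record is accepted as its top-scoring class only if that score exceeds the
threshold θ, else rejected; at θ = 0 nothing is rejected and accuracy
equals the closed-set accuracy.

**ROC/EER/AUC.** Genuine scores (score assigned to the true class) and
impostor scores (scores assigned to wrong classes) are pooled across all
folds — verification-style pooling. Thresholds sweep the sorted score set
plus a sentinel above the maximum; FAR(θ) = fraction of impostor scores
≥ θ, FRR(θ) = fraction of genuine scores < θ. The EER interpolates
linearly between the two thresholds bracketing the FAR = FRR crossing; the
AUC is the trapezoid area under (FAR, 1−FRR) traversed in decreasing
threshold order, along which both coordinates are non-decreasing (this
ordering matters when several thresholds share a FAR value). An
unknown-attacker mode (off by default) additionally scores each subject's
records with that subject left out of training entirely, adding
never-enrolled impostor attempts to the pool.

**Finger-pair mode.** For a single subject, the same LOSO machinery
classifies the 10 finger pairs: samples are one pair's 25-point raw
spectrum or one combination's 25-point ratio curve.

## Numerical choices and edge cases

* Exact invariance claims (ratio cancellation, state scaling) are tested at
  1e−12 relative; the telescoping product at 1e−9 absolute; circuit-oracle
  agreement at 1e−10 relative.
* Component values, frequencies, scales and noise sigmas must be strictly
  positive/finite; empty grids, single-class training folds, multi-subject
  input to the finger-pair mode, and single-session subjects raise
  descriptive errors.
* CSV I/O writes floats with `%.17g` and parses with pandas'
  `round_trip` precision, so write→read is bit-exact; frequencies are
  stored as integer hertz to avoid float-key drift.
* Canonical orderings are fixed: pairs lexicographic by (a, b), frequencies
  ascending, combinations in list order; element 0 of a raw vector is pair
  (1,2) at 20 kHz and element 249 is pair (4,5) at 500 kHz.
* The benchmark sizes (8 subjects × 3 sessions × 5 repeats, 10 replicate
  seeds) are the package's chosen desk-scale conditions; all randomness
  derives from explicit integer seeds.

## Known limitations

* Drift in real tissue is only approximately multiplicative and
  common-mode; the generator's default realises it exactly, which is the
  method's best case. Use `drift_heterogeneity` to probe departures.
* No phase information, no Cole–Cole dispersion, no electrode polarization
  model, no sub-20 kHz contact effects, and no modelling of humidity,
  meals, exercise or other specific physiological covariates beyond the
  generic multiplicative factor.
* The score calibrations are monotone mappings of each model's native
  confidence, chosen for sweepability, not calibrated posteriors.
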