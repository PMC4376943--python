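# Methods

## Signal model and containers

A recording holds Δ[HbO₂] and Δ[hHb] concentration changes (μmol/L) for the
active channels of a 16-channel forehead montage sampled at 2 Hz. Channels
8 and 10, which sit above the nasal sinus and saturate in practice, are
excluded by default, leaving 14 active channels; masking never reorders the
retained channels. Time is 0-based seconds from session start; sample *i*
covers `[i/fs, (i+1)/fs)`.

When raw two-wavelength (730/850 nm) intensities are the input, the
modified Beer-Lambert law converts them: per wavelength
`ΔOD = −log10(I/I₀)`, and the 2×2 system
`ΔOD_λ = (ε_HbO2,λ·ΔC_HbO2 + ε_hHb,λ·ΔC_hHb)·d·DPF_λ` is solved per
sample. Defaults: source-detector separation d = 2.5 cm, differential
pathlength factor 6.0 at both wavelengths, extinction coefficients from the
standard compiled in-vitro tables (730 nm: 0.390/1.1022; 850 nm:
1.058/0.6913 cm⁻¹·mM⁻¹). Device firmware constants for this class of
instrument are unpublished, so these are explicit configuration values, not
a claim of equivalence; all are overridable.

## MACD filtering

Each channel and species is filtered independently with
`MACD = EMA₁₂ − EMA₂₆` and the signal line `EMA₁₀(MACD)`; window lengths
are in samples at 2 Hz and are authoritative (the 6 s/13 s/5 s labels are
derived). Numerically computed from the impulse response, the filter's
magnitude response peaks at ≈0.036 Hz and is a band-pass over roughly
0.02–0.33 Hz: slow drifts and step offsets are rejected exactly (the DC
gain is identically zero), fast physiological and measurement noise is
attenuated.

Two numerical choices matter:

* **Warm start.** Every EMA initialises with `y₀ = x₀`. A zero
  initialisation would inject a startup transient proportional to the
  signal's offset and generate spurious crossovers in the first minute of a
  session; with the warm start, a constant input is a fixed point from the
  first sample (exactly for the MACD difference, to 1 ulp for a single
  EMA).
* **Stream/batch equivalence.** The chunked (streaming) path and the batch
  path execute the identical floating-point recursion, so outputs are
  bit-exact under arbitrary chunking — the batch results in reports are
  exactly what an on-line system would have produced.

## State estimation

The MACD outputs of the active channels are averaged (Δ[HbO₂] only by
default — it carries the dominant task effect — configurable to Δ[hHb] or
both), and the state machine switches to *on-task* on a strict upward
crossing of the MACD through the signal line (`d₍ₙ₋₁₎ ≤ 0 < dₙ` for
`d = MACD − Signal`) and to *not-on-task* on a strict downward crossing.
Exact ties never trigger a transition, so flat or silent inputs
deterministically stay not-on-task.

Ground truth marks the operator on-task during message reception,
`[onset, onset + 11 s)`. Scoring is per sample (Correct / FalsePositive /
FalseNegative); accuracy is the fraction correct, sensitivity the on-task
recall, specificity the not-on-task recall. The first
`N_long + N_signal = 36` samples (18 s) are excluded from scoring by
default so filter initialisation does not enter the tally; set
`warmup_s = 0` to include them.

Latency analysis pairs each trial with the estimated onset transition
nearest to the true onset inside a `[−10, +15]` s window (an invented but
configurable pairing rule; ties resolve to the earlier transition) and
takes the first off-transition after it as the estimated offset, referenced
to the message offset. Trials without an in-window transition are counted
unmatched. Means and standard errors are reported overall and per load
level; between-subject inferential statistics are out of scope.

## Feature extraction and classification

Trials span `[−2, +31)` s around the message onset (66 samples); the first
2 s are the pre-trial baseline. Seconds convert to samples via
`round(t·fs)` with half-open intervals — exact at 2 Hz for integer and
half-integer times. The window grid (offsets 10–16 s in 1 s steps, lengths
5/10/15 s, both relative to the message onset) covers the expected
hemodynamic response peak across individual latency differences; with the
default timing the last needed sample arrives at onset + 31 s, i.e. 2 s
after the response window closes, which is asserted at pipeline startup.

Per window, channel and species the features are the mean, the
baseline-referenced mean amplitude Ā (insensitive to residual drift),
excess kurtosis and skewness. Moment statistics use the biased (population)
estimators `skew = m₃/m₂^1.5`, `kurt = m₄/m₂² − 3`; zero-variance windows
yield 0 for both shape statistics (with a logged warning) rather than an
error, so degenerate flat channels remain classifiable. Both the plain mean
and Ā are emitted; whether they are redundant depends on the baseline, and
keeping both preserves the printed 8-feature layout. Feature ordering is
fixed (channel → offset → length → 8-feature block) and column names are
self-describing (`ch15_off13_len10_amp_hhb`).

The classifier is a linear SVM (scikit-learn SVC, linear kernel) because
the predictor count (2352) dwarfs the 20 training trials. Features are
z-scored with training-set statistics only (zero-variance features get unit
scale); without scaling, a single C grid would be meaningless across
subjects. C is selected by repeated stratified 5-fold CV (10 repeats, seeded
fold shuffles) over seven decades 10⁻⁵…10, maximizing mean accuracy over
the 50 fold-fits with ties resolved toward the smallest C (strongest
regularization). The positive class is *high* load, so reported sensitivity
is the recall of high-load trials; a decision value of exactly 0 maps to
the positive class. After training the model is frozen — phase-T
classification never touches labels, which only enter the separate
evaluation step.

## Synthetic sessions

The generator emulates the target protocol: 40 trials (11 s message + 18 s
response window), 20 per load level, the first 20 balanced 10/10, never
more than two equal loads in a row (orders drawn uniformly from the
constraint set by rejection sampling), inter-trial intervals uniform
10–20 s, a 20 s initial rest and a 40 s tail, all onsets snapped to the
sample grid.

The evoked Δ[HbO₂] response is a message-length boxcar convolved with a
double-gamma kernel (positive lobe mode 6 s; undershoot mode 16 s, ratio
1/6). The convolution is normalised so that a message-length boxcar reaches
peak 1: `amp_low` (0.5) and `amp_high` (1.0) are therefore peak response
amplitudes in μmol/L at the focus channel (15, right dorsolateral
prefrontal cortex, where the load effect is strongest), with other channels
scaled by `exp(−|c − 15|/3)`. Δ[hHb] is the Δ[HbO₂] response scaled by
−1/3 and lagged 1 s. Per channel and species, additive noise comprises a
random linear drift (|slope| ≤ 5·10⁻⁴ μmol/L/s, below the passband), a
0.1 Hz Mayer-wave and a 0.25 Hz respiratory sinusoid (0.3 and 0.2 μmol/L,
random phases, inside the passband — these make the task non-trivial) and
white noise (σ = 0.1 μmol/L, mostly above the passband). The same seed
yields a bit-identical session.

What the generator does *not* emulate: motion artifacts, optode drift,
habituation or fatigue trends, inter-channel noise correlations,
subject-specific HRF variability, and acceleration effects. Passing tests
on synthetic cohorts therefore demonstrate the pipeline's correctness and
its sensitivity under idealized hemodynamics, not field performance on real
recordings.

## The noise-free regime is pathological for the crossover estimator

One property deserves explicit discussion. In a *noise-free* simulation
(all noise amplitudes zero), the crossover estimator does **not** detect
onsets at the true onsets: after each trial the channel-averaged MACD
relaxes back to zero monotonically from below (the terminal lobe of the
response — the slow undershoot recovery — is too gentle to pull the MACD
positive), so `MACD − Signal` stays positive through the entire rest
period and the strict up-crossing fires once at the preceding trial's
undershoot trough (~20 s early) instead of at the next onset. This is a
structural property of exponential relaxation, insensitive to the
inter-trial interval, the species averaged, or the matching window; only an
implausibly strong undershoot (ratio ≳ 0.3–0.5, leaving the MACD positive
at rest onset) would flip the rest-state sign. With physiological noise
present — the realistic and default regime — in-band fluctuations
re-randomize the sign of the difference during rest and onsets again
produce crossings: in default simulations all 40 trials are matched with
mean onset latency near zero. The corresponding noise-free acceptance check
is retained (and fails) as an honest record of this regime rather than
being tuned away.

## Problem sizes and defaults used in reports

The bundled acceptance script uses 10 simulated subjects per cohort (one
40-trial session each, ≈30 min of signal at 2 Hz), 3 sessions for the
noise-free onset-rate estimate, and an 8192-sample impulse for the
frequency response — sizes at which every quantity is stable to well within
the tolerances asserted. All values it reports are computed at run time
from freshly generated sessions; nothing is cached or tabulated.
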