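# Methods

This note documents the models, conventions and numerical choices behind
`wearhrv`, and what the synthetic experiments do and do not show about real
wearable data.

## Units and conventions

Timestamps are seconds from record start; NN intervals milliseconds; heart
rate bpm; spectral power ms² (densities ms²/Hz); frequency Hz. All standard
deviations use the population convention (divisor N) to match the estimator
definitions; a `sample=True` flag switches to n−1 where a user needs it.
Windows tile the record from the first beat timestamp as half-open
intervals, which makes every estimator invariant to a constant time offset.
Records are expected to span ≥ 20 h for "24-h" semantics
(`BeatSeries.check_span`); shorter records are accepted by the low-level
operations for testing.

## Preprocessing

Artefact handling follows the de-facto HRV standard: a plausibility range
filter ([300, 2000] ms) plus the Malik rule (beat flagged when its NN
differs from the previous *clean* NN by more than 20%; excluding flagged
beats from the reference prevents flag cascades). Flagged interior beats are
reconstructed by a least-squares quadratic of NN against time through the
two clean beats on each side; flagged runs spanning more than 10 s are
dropped as true gaps rather than fabricated, as are leading/trailing flagged
beats. After reconstruction the retained beats' timestamps are recomputed by
cumulative sum so the timestamp/interval identity holds exactly (this
compresses removed-gap time; estimators that only consume NN values and
window means are unaffected in practice). All thresholds are configurable
via `PreprocessConfig`.

## PPG noise model

The wearable HR error is a per-window lookup calibrated against ECG:
(bias, σ) = (0.03, 5.91), (0.33, 5.09), (−0.16, 4.71), (−0.60, 4.01),
(−0.35, 3.95) bpm for 1/5/10/30/60-min windows, log-linearly interpolated in
window length elsewhere and held flat beyond the calibrated range. Noise is
injected on HR and mapped through `ANN = 60000/(HR+ε)`; only the zero-mean σ
is injected by default (the mean bias is exposed separately and can be added
via `bias_bpm`). Note that at short windows this literal injection is a
large ANN perturbation (~70 ms at 1 min for HR ≈ 70), comparable to the
low-pass deficit it coexists with; noise-on and noise-off analyses are
therefore kept separate throughout, and the correction validation below runs
noise-free to isolate the spectral-truncation effect.

## Spectral analysis

Beat series are unevenly sampled, so PSDs use the Lomb–Scargle periodogram.
The kernel is a vectorised implementation of the classic phase-shifted
formulation, evaluated in frequency chunks so day-long records (≈10⁵ beats)
stay within a small memory footprint; it agrees with
`scipy.signal.lombscargle` to ~1e−12 (asserted in tests) and is several
times faster at this problem size. The raw periodogram `P` (which peaks at
`N A²/4` for a sinusoid of amplitude A) is rescaled by `2T/N` (T = record
span) into a one-sided density over f whose trapezoidal integral over the
evaluated band approximates the signal variance — the "variance"
normalisation contract that makes the corrections dimensionally coherent in
ms².

The default grid is log-spaced with 2000 points from 1/span to
min(0.5 Hz, half the median beat rate): the 24-h HRV spectrum spans more
than four decades with 1/f shape and a linear grid would under-resolve ULF.
Cohort sizes in the shipped experiments use 800 points, which resolves the
same range at ~170 points per decade. Band edges follow the period
definitions ULF 5 min–24 h, VLF 25 s–5 min, LF 7–25 s, HF 2–7 s
(config-overridable). One known artefact: a grid starting at 1/span bisects
the spectral peak of a component with exactly one cycle per record (the
circadian line), so ~half that peak's power falls below the grid; this is
shared by every spectrum built on the same grid and therefore largely
cancels in the adjW power *ratio*, but it is visible in absolute
total-power comparisons.

The a-priori reference spectrum is the pointwise mean of per-subject PSDs on
a common fixed grid, with a cumulative-power interpolant attached. `adjMean`
adds the a-priori power above the window cutoff `f_c = 1/(60w)` (one fixed
number per window, shared by all subjects); `adjW` multiplies the measured
ANN variance by the a-priori total/low ratio. The printed source formula for
the weighted correction is typographically scrambled; this package follows
the multiplicative reading implied by its prose (missing high frequencies
perfectly correlated with measured low frequencies). The "measured variance"
entering both corrections is the time-domain variance of the ANN series,
equivalent under the variance normalisation to integrating its spectrum and
much cheaper.

### What the corrections can and cannot fix

Window averaging is a sinc² filter, not a brick wall: power just below
`f_c` is partially attenuated, so the measured ANN variance underestimates
even the below-cutoff power. The brick-wall corrections do not model this,
leaving a residual negative bias that is proportionally largest at short
windows (where the correction itself is small). On synthetic cohorts sharing
the a-priori spectral shape, adjW shrinks the mean bias at every window
length (e.g. from −10 ms to −6 ms at 1 min and from −25 ms to +2 ms at
60 min in the shipped experiment), but its residual |bias| is *not*
monotone increasing in window length: the 1-min residual (sinc-dominated)
can exceed the 60-min one, where the larger multiplicative correction and
the shared grid truncation partially cancel. On real data, cross-cohort
spectral-shape differences typically dominate and push the 60-min error
higher.

## Cosinor

The 24-h rhythm is fitted by exact linear least squares via the cos/sin
linearisation; amplitude `A = sqrt(β²+γ²)`, acrophase
`φ = atan2(−γ, β)/2π mod 1`. Although the source describes a
"multiple-component" cosinor, only MESOR and the 24-h amplitude feed the
downstream features, so the default is single-component with an optional
harmonics list whose amplitudes are reported but unused. The fit consumes
segment-level HR (default 5-min windows) — the wearable view — not
beat-level data. Preconditions: ≥ 4 samples spanning ≥ half a period and a
full-rank design.

## Validation statistics

`compare_estimator` reports bias (mean ± sample-SD of estimate − truth),
RMSE, Pearson r (NaN-guarded for constant inputs) and a two-sided paired
t-test. `group_ttest` is pooled-variance Student's t by default ("unpaired
t-test" without further qualification), Welch as an option; the sign
convention (first group − second group)/SE makes healthier-higher features
score positive when the low-risk group is passed first.

## Risk models

NYHA classes 0–1 map to low risk, 2–4 to high. Classifiers are trained on a
stratified 70/30 split; features are z-scored on the training split for the
logistic and network models (the forest uses raw features). The network is a
single-hidden-layer leaky-ReLU perceptron with inverted dropout and
minibatch gradient descent, implemented directly in numpy (the model is tiny
— at most 8 hidden units on 3 features); hyper-parameters (1–8 units, leak
0–1, dropout 0–0.99, batch 1–32) are tuned by seeded random search scored on
a stratified 80/20 validation split of the training data, then refitted on
the full training split. Baselines: B1 samples predictions from the
training-class distribution; B2 predicts the training majority class.

Two frozen-coefficient predictors are preserved exactly as published:
`SDNN24 = 47.248 + 951.590·SDANNHR24 − 0.347·MESOR` and
`P(high) = 1/(1+exp(0.121 + 0.283·s − 0.293·m + 0.225·a))`. The coefficient
951.590 is only dimensionally sensible if SDANNHR24 enters in **seconds**
(0.1 s contributes ≈ 95 ms); the logistic model's coefficient magnitudes
(~0.2–0.3) indicate z-scored inputs. Both conventions are frozen and
documented at the call sites.

## Synthetic generator

The generator emulates exactly the structure the method exercises:
instantaneous `NN(t)` = mean + 24-h circadian cosine + band-limited 1/f^α
coloured noise (α = 1 by default, band 2/duration → 0.04 Hz) + LF (0.1 Hz)
and HF (0.25 Hz) sinusoids, evaluated on a 1-s grid. Beats are emitted where
the integrated instantaneous rate crosses successive integers
(integrate-and-fire), guaranteeing the timestamp/interval identity. Ectopics
replace a Binomial(N, rate) subset of NN values with ±[25, 60]%
perturbations (timestamps re-derived by cumulative sum); gaps delete beats
in Poisson-placed windows. The artefact-free series is always returned as
ground truth.

Numerical choices that make the generator testable:

- the coloured-noise realisation is renormalised to its exact target
  variance, and the record fundamental (k ≤ 1) is excluded from its band so
  all components are orthogonal over the record — component variances then
  add exactly and the clean SDNN24 matches the analytic composition to a
  few percent (beat-sampling is the only residual);
- Gaussian tails are soft-limited at 3σ (tanh) and renormalised, keeping
  instantaneous NN inside a physiologic corridor for high-variance subjects;
- subjects calibrated to a target SDNN24 split the non-LF/HF variance
  53.5%/46.5% between circadian and coloured noise, chosen so the ULF share
  of total power matches the ~80% low-frequency dominance reported for
  24-h human HRV; the mean NN is raised when a subject's variance needs
  headroom above the 200 ms floor (high-HRV subjects have slow resting
  rates).

`generate_cohort` draws low-risk subjects with SDNN24 ~ N(142, 31) ms, mean
NN ~ N(860, 50) ms, NYHA 0–1, and high-risk subjects with SDNN24 ~
N(87, 43) ms (truncated at 25 ms), mean NN ~ N(740, 50) ms, NYHA 2–4 —
congestive heart failure presents with reduced HRV, elevated resting HR and
a proportionally damped circadian swing, which is what makes the HR feature
set (SDANNHR24, MESOR, amplitude) more informative than SDNN24 alone in the
classification experiments.

What the generator does **not** model: activity bouts and posture changes,
respiratory-rate variation (HF is a fixed tone), beat-detection errors other
than the ectopic/gap model, and non-stationary spectral shape. Passing tests
therefore demonstrate the correctness of the estimation chain under the
stated spectral/circadian structure, not device-level validity.

## Problem sizes in the shipped experiments

The test suite and acceptance script run 24-h records (~10⁵ beats each):
cohorts of 60 subjects for calibration/t-score checks, a 16-subject
reference cohort for the a-priori spectrum with a 30-subject validation
cohort for the corrections, 100 independent 48-subject cohorts for the
classifier-ordering replicates, and 20 replicates inside the acceptance
script. These sizes give stable cohort means (SE of mean bias well under
1 ms) while keeping a full run to a few minutes.

## Known limitations

- The adjW/adjMean corrections inherit the brick-wall cutoff model; see the
  sinc discussion above.
- The literal per-window HR noise model produces ANN errors at short
  windows that are large relative to typical between-window variance;
  analyses mixing noise injection with spectral corrections should be
  interpreted with that in mind.
- The ectopic flag rate of the Malik rule depends on the short-term
  variability of the underlying series; the shipped defaults reproduce a
  ~2.5% flag rate on the default synthetic profile.
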