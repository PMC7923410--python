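# wearhrv

Estimation of the 24-hour heart-rate-variability metric **SDNN24** from the
semi-continuous heart-rate measures that wrist-worn wearables actually emit,
with spectral bias corrections, circadian (cosinor) modelling and a
cardiovascular-risk classification layer. The package is aimed at
researchers working on HRV from consumer PPG devices: it implements the full
estimation chain and ships a synthetic 24-h beat generator so every step is
testable without access to clinical Holter recordings.

## The problem and the method

SDNN24 — the standard deviation of all normal-to-normal (NN) inter-beat
intervals over 24 h — is the classic global HRV index: values above 100 ms
are considered healthy, 50–100 ms compromised, below 50 ms unhealthy.
Computing it requires a continuous beat stream, which wearables do not
provide; they report heart rate averaged over windows of 1–60 min.

From a window-averaged HR series one can compute

- `SDNN24  = sqrt( Σ (NNᵢ − N̄N)² / N )` — the gold standard (population SD),
- `SDNNi24` — mean of per-window NN standard deviations (short-term power only),
- `SDANN24` — SD of per-window mean NN (ANN); a low-pass-filtered SDNN,
- `SDANNHR24` — SD of `ANN = 60000/(HR + ε)` where ε ~ N(bias, σ²) is the
  calibrated per-window PPG measurement error (σ = 5.91 bpm at 1 min down to
  3.95 bpm at 60 min).

Averaging over a w-minute window discards spectral power above the cutoff
`f_c = 1/(60·w)` Hz, so SDANNHR24 systematically underestimates SDNN24. Two
corrections use an *a-priori* reference spectrum (the cohort-average
Lomb–Scargle PSD, computed on unevenly sampled beat times and normalised so
that its integral equals the signal variance):

- **adjMean**: `sqrt( VAR(ANN) + ∫_{f_c}^{∞} S̄(f) df )` — add the fixed
  cohort-average missing power;
- **adjW**: `sqrt( VAR(ANN) · ( 1 + P_high/P_low ) )` — rescale by the
  a-priori total/low power ratio, assuming the missing high frequencies
  scale with the measured low frequencies.

The circadian HR rhythm is summarised by a fixed-period cosinor fit
`HR(t) = M + A·cos(2π(t/24h + φ)) + ε` (MESOR `M`, amplitude `A`, acrophase
`φ`), and the HR feature set (SDANNHR24, MESOR, amplitude) feeds logistic
regression, random-forest and small neural-network classifiers of
cardiovascular risk (NYHA heart-failure classes 0–1 = low risk, 2–4 = high),
benchmarked against distribution-sampling (B1) and majority-class (B2)
baselines with per-class precision/recall/F1.

## Worked example

Simulate a 24-h subject, estimate with 5-min windows and wearable noise, and
fit the circadian rhythm:

```sh
$ sdnn simulate --seed 7 -o subj.csv --truth subj_clean.csv
simulate: seed=7 beats=104226 -> subj.csv

$ sdnn preprocess subj.csv -o subj_pp.csv
preprocess: n=104226 outliers=63 ectopic=2496 flagged=2.46%

$ sdnn compute subj.csv --window 5 --noise table --seed 42
{
  "sdnn24_ms": 153.64886253350585,
  "sdnni24_ms": 88.72966089673997,
  "sdann24_ms": 123.07317332883677,
  "sdannhr24_ms": 133.72863094513346,
  "window_min": 5.0,
  "n_segments": 288
}

$ sdnn cosinor subj.csv
{
  "mesor_bpm": 72.77234249225137,
  "amplitude_bpm": 13.07736607033891,
  "acrophase_h": 11.89428637756511,
  "residual_sd_bpm": 6.702016484479288
}
```

Reading the numbers: 2.46% of beats were flagged as ectopic/outlier and
reconstructed by quadratic interpolation. The 5-min SDANN24 (123 ms) sits
below SDNN24 (154 ms) — the low-pass underestimation the adjMean/adjW
corrections address — while the injected HR noise pushes SDANNHR24 (134 ms)
slightly above SDANN24. The subject's HR rhythm averages 72.8 bpm with a
±13.1 bpm circadian swing peaking 11.9 h after record start. All three
estimator values classify the subject as `healthy` (SDNN24 > 100 ms).

Cohort-level work uses `sdnn simulate-cohort`, `sdnn apriori`,
`sdnn features`, `sdnn classify` and `sdnn pipeline` (which emits
estimator/correction/t-score/classification tables as CSV + JSON); the same
functionality is available as a library via `wearhrv.*`.

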