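# Methods

This note documents the models, numerical choices and limitations behind
`earsleep`. It is written for a reader who wants to know exactly what the
package computes and what passing its tests does and does not demonstrate.

## Montage model

A cEEGrid provides eight channels R1–R8 recorded against a right-mastoid
reference. Virtual PSG channels are fixed signed linear combinations
(weights ±1, ±0.5, applied in floating point, no normalization):

| label  | combination               |
|--------|---------------------------|
| Fp2_M2 | R1                        |
| F4_M2  | (R1+R2)/2 − R6            |
| C4_M2  | (R2+R3)/2 − (R6+R7)/2     |
| P4_M2  | (R3+R4)/2 − R7            |
| O2_M2  | R7 − R8                   |

R1 is treated as already mastoid-referenced (the recording reference sits on
the right mastoid), so Fp2_M2 carries no re-reference term; every other EEG
derivation's weights sum to zero. The `cEEGrid+EOG` layout adds EOG_L − R6
and EOG_R − R6 (R6 standing in for a mastoid reference). Applying a montage
is a pure linear map, so it commutes with scaling and addition — properties
the test suite asserts directly.

The 36 combinations used by the correlation topography are the 8 singletons
plus the 28 bipolar pairs Ri−Rj (i < j), enumerated in reading order
(R1, R1−R2, R2, R1−R3, R2−R3, R3, …): for each k, all pairs ending at Rk,
then Rk itself.

## Preprocessing

The conditioning chain is a zero-phase 4th-order Butterworth bandpass,
0.5–40 Hz, followed by decimation from 250 Hz to 125 Hz.

* **Zero phase** is implemented as forward–backward application
  (`scipy.signal.sosfiltfilt`) of the causal design, which squares the
  magnitude response: the single-pass −3 dB corners become −6 dB
  (−6.02 dB measured at 40 Hz) and the net phase is identically zero, so
  grapho-element latencies are untouched.
* **Edge handling**: odd-symmetric extension. The default pad of a few dozen
  samples is far too short for the 0.5 Hz corner, whose impulse response
  needs ~12 s to decay below 1e−6; the pad is therefore sized at 8/low_hz
  seconds (4000 samples at 250 Hz), capped at signal length − 1. With this
  pad, filtering is time-reversal symmetric to better than 1e−6 relative.
* **Decimation** keeps every second sample with no extra anti-alias stage:
  the 40 Hz lowpass already bounds content well below the new 62.5 Hz
  Nyquist. Decimation leaves per-tone amplitudes across 1–35 Hz unchanged
  (measured < 0.01%). Note the *filter itself* is not 5%-flat out to 35 Hz —
  its forward–backward response is 0.94 at 30 Hz and 0.78 at 35 Hz; that is
  a property of the mandated 4th-order design, not of the implementation.
* **DC removal** subtracts the per-epoch mean over all samples; it is
  idempotent and linear.

## Correlation topography

Events are cut at sample window [round(onset·fs), round((onset+duration)·fs))
— exactly the annotated interval, variable length, no padding. Every trace
(Fpz reference and each raw grid channel) is DC-removed per epoch.
Correlation is Pearson's product–moment r (the Fisher-Z machinery presumes
it). Aggregation is tanh(mean(atanh r)); r = ±1 is clipped to ±(1 − 1e−12)
before atanh. A zero-variance derived trace yields a missing value (NaN),
which is excluded from averaging, never imputed as 0. Grand averages
Fisher-average the per-participant averages.

## Agreement statistics

* Hypnograms are aligned by truncation to the shorter length, optionally
  capped at `max_epochs` (per-participant truncation of unusable tails;
  5 h 20 min of 30-s epochs = 640).
* Multi-class κ keeps Art as a sixth category; one-vs-rest κ collapses to
  2×2 with Art pooled into "rest". This convention jointly reproduces the
  published overall and per-stage grids, which the acceptance tests assert.
* SE is the Fleiss–Cohen–Everitt (1969) asymptotic variance of unweighted κ,
  cross-checked against statsmodels. It scales as 1/√n.
* Cross-participant κ is computed on concatenated epochs — identical to the
  κ of the elementwise sum of per-participant confusion matrices
  (additivity, asserted as a property). Per-participant κs feed the paired
  one-tailed t-test (alternative: condition B agrees better), delegated to
  `scipy.stats.ttest_rel`; identically constant differences are rejected as
  degenerate rather than reported as infinite t.
* Landis–Koch bands: ≤0 poor, (0, .20] slight, (.20, .40] fair,
  (.40, .60] moderate, (.60, .80] substantial, (.80, 1] almost perfect.
* Comparisons against printed 2-decimal values round half-up.

## Synthetic data model

The generator exists so every pipeline stage is exercised on data with the
right structure; it makes no claim of physiological fidelity.

* **Hypnogram**: first-order Markov chain over (Art, W, N1, N2, N3, REM),
  30-s epochs, started in W. Default transition matrix is
  diagonally dominant (N2 self-transition 0.85, N3 0.88, REM 0.86), giving
  realistic bout lengths and a stage mix with N2 most frequent; Art is rare
  and transient.
* **Source signal** per stage (amplitudes in µV at the frontal source,
  following AASM scoring conventions): W — 10 Hz alpha (20 µV);
  N1 — 5 Hz theta (20 µV); N2 — 1/f background (15 µV sd) plus events;
  N3 — 1.5 Hz delta at 80 µV (slow waves ≥ 75 µV); REM — low-amplitude mixed
  (10 µV sd); Art — large-amplitude 1/f noise (120 µV sd). Oscillation phases
  are random per epoch; the 1/f background is FFT-shaped Gaussian noise.
* **Events** (N2 only): spindles at 2/min (12–14 Hz, Hann-windowed,
  0.5–2 s, 40 µV) and K-complexes at 1/min (one Hann-windowed slow-wave
  period — sharp negative then positive deflection — 0.5–1.5 s, 100 µV).
  Onsets are uniform within the epoch, non-overlapping by rejection
  sampling; annotations carry the true onset and duration.
* **Mixing**: channel c records gain(c) × source + white sensor noise
  (8 µV sd, independent per channel). gain(Fpz) = 1 defines the source
  scale. The grid gains form a C-shaped profile,
  R1..R8 = (1.0, 0.6, 0.1, −0.45, −0.30, −0.10, 0.05, 0.30): the grid wraps
  around the ear, so both ends (R1 strongly, R8 mildly) face the frontal
  source with positive sign while the rear-facing middle (R4, R5) is
  negative. The sign of any combination's correlation with Fpz equals the
  sign of its gain contrast; R1−R4 has the largest contrast (1.45), making
  the expected topography maximal on R1/R1−R4 and negative on R5−R8 — the
  directional structure the analysis must detect. A monotone front-to-rear
  gain profile would fail to make R5−R8 negative, which is why the C-shaped
  profile is the default.
* **REM EOG**: smoothed rise-and-fall deflections (±100 µV, ~2 per epoch)
  added with opposite polarity to EOG_L and EOG_R only.
* **Second scorer**: each epoch is independently relabeled with probability
  ε (default 0.15) through a zero-diagonal, adjacent-stage-biased kernel.
  The implied κ has a closed form — p_o = 1 − ε and
  p_e = Σ_s f_s[(1−ε)f_s + ε(fK)_s] with f the stage frequencies — which the
  simulator reproduces within ±0.05 at 10,000 epochs. Two boundary cases are
  instructive: with a uniform off-diagonal kernel, ε = 5/6 makes the second
  rating exactly independent (κ ≈ 0), while ε = 1 forbids agreement entirely
  (κ = −p_e/(1−p_e) < 0).
* **Reproducibility**: every generator takes an integer seed
  (numpy `default_rng`); the fixture suite derives child seeds from one seed
  via `SeedSequence`, so all artifacts are bit-reproducible end to end.

### What the synthetic data does not capture

A single shared source with white sensor noise means epoch correlations on
synthetic nights are high (~0.95) and nearly uniform in magnitude across
front-pointing combinations; real recordings contain multiple sources,
artifacts and channel-specific physiology, producing the lower (~0.6–0.7)
and more graded correlations seen in practice. Passing the topography tests
therefore demonstrates that the pipeline recovers directional mixing
structure, not that it reproduces any particular correlation magnitude.
Likewise the Markov hypnogram has no ultradian cycle structure, and scorer
errors are epoch-independent, unlike human drift.

## Problem sizes

The full-loop topography check runs 20 seeded 1-hour nights (120 epochs at
250 Hz, ~40–60 spindle events each); the scorer-noise recovery uses 10,000
epochs; signal-chain checks use 20–60 s probes. These sizes put Monte-Carlo
error well below every asserted tolerance while keeping a full run of suite
plus acceptance script around a minute.

## I/O formats

EDF is written by a small built-in codec (16-bit, 1-s records, physical
dimension "uV", symmetric physical range per channel); round-trip error is
bounded by one quantization step, and files are read back identically by
mne's independent EDF reader (asserted in tests). Signals whose length is
not a whole number of seconds are zero-padded to the next record boundary on
write. CSV recordings are wide format (time_s column plus one column per
channel) with the rate inferred from the time column. Hypnograms
(`epoch_index,stage`), events (`onset_s,duration_s,label,channel`) and
label-indexed confusion matrices are plain CSV; stage labels outside
(Art, W, N1, N2, N3, REM) are rejected with the offender named, and
confusion matrices are canonicalised to that order on read.
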