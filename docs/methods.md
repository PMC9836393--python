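# Methods notes

This note records the modelling assumptions, default parameters and the
design decisions taken where the underlying methods leave genuine choices
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Expectation models

All models predict the next note's MIDI pitch over the full 128-symbol
alphabet and all logarithms are natural, so surprise and uncertainty are in
nats. The first note of every composition is scored against the uniform
1/128 prior (surprise and uncertainty `ln 128 ≈ 4.852`). Contexts are
truncated to the most recent k notes and never cross composition
boundaries.

**Zero-probability floor.** Finite-count n-gram models can assign exact
zeros. Every final predictive distribution is therefore mixed with the
uniform distribution at weight 1e−6 and renormalized, capping surprise at
about `ln(128/1e−6) ≈ 18.7` nats. The floor is far below any probability
the models otherwise emit, so it is numerically invisible in ordinary use.

**Gestalt model.** The generative story is: a key (24 equal-tempered major
and minor keys, prior `p_maj/12` per major key) and a latent central pitch
`c` (prior `N(c0, var_c0)` discretized onto 0..127) are drawn per piece;
each note's score is `RangeTerm(x|c) · ProximityTerm(x|x_prev) ·
KeyTerm(x|key)`, normalized over x, with the proximity term omitted for the
first note. Defaults `c0 = 72`, `var_c0 = 34.4` (semitones²), `v_r = 83.2`,
`v_x = 18.2`, `p_maj = 0.81` are corpus-moment estimates from the
literature; `fit_temperley_params` recomputes them as moments of any corpus
(population variances, so a single constant-pitch piece yields variance 0,
handled as a point mass). Three choices were open and are implemented as
follows:

- the posterior over (c, key) is updated after every context note and the
  prediction marginalizes over the full 128 × 24 grid exactly — no point
  estimate and no sampling; the enumeration is O(128·24·128) per note and
  is verified against a naive triple loop to 1e−10;
- key profiles are pitch-class profiles: the profile value depends only on
  `(pitch − tonic) mod 12`; octave structure is carried by the range term;
- without key labels the profiles fall back to flat scale-tone templates
  (uniform over the 7 diatonic degrees, natural minor for minor keys);
  corpus-estimated degree frequencies are preferred when labels exist.

**n-gram smoothing.** "Interpolated smoothing" admits many escape
estimators. We use escape method C: at each order the maximum-likelihood
estimate is blended with the next-lower order using escape mass
`d/(n + d)` (n = context count, d = distinct continuations), recursing to
the uniform floor. The unsmoothed count ratio is exposed separately
(`raw_ngram_ratio`) for diagnostics. The smoothing strategy lives in one
function and is deliberately swappable.

**stm/ltm combination.** The two predictions are combined by a geometric
(log-linear) mixture with weights proportional to `(H_m / ln 128)^(−bias)`,
bias 1 by default — the standard multiplicative-combination choice when
only "entropy weighting" is specified; an entropy-zero model takes all the
weight. The weights are returned per note so mean stm/ltm weights can be
reported; published mean weights for this scheme do not sum to one and are
therefore not asserted anywhere.

**Accuracy and ties.** A note counts as correctly predicted when the
observed pitch is the argmax of the prediction; ties resolve to the lowest
pitch. For a uniform predictor this deterministic rule gives accuracy 0
rather than 1/128, so the chance level is computed as what it is — the
probability 1/128 ≈ 0.8 % of a correct guess under the uniform
distribution — rather than through the argmax rule.

## Synthetic data

**Melodies** are sampled from a key-constrained Markov process: next pitch
∝ `key_weight(pitch) · exp(−(pitch − mean)²/(2·interval_scale²))` over a
3-octave range, in-scale pitch classes weighted 8:1 (tonic 12:1). At
`markov_order = 2` the mean continues a fraction `momentum` (default 0.6)
of the previous interval, making the process genuinely second order — the
substrate for the context-length sweep. Optional verbatim motif reinsertion
(2–6 notes) adds repeated figures; it is disabled in studies that need the
process exactly Markov. Inter-onset intervals are note-value multiples
(0.5–2×) of the base period (`tempo` in notes/s, default 3/s, matching
typical inter-note intervals of a few hundred ms). The variable rhythm is
deliberate: melodies with a strictly constant inter-onset interval make the
time-shifted copies of the onset regressor nearly periodic and hence
collinear, which no real stimulus set exhibits. The generator's exact
transition law is exported (`conditional_distribution`, `MarkovPredictor`)
and serves as matched predictor and ground-truth surprise.

**Recordings** follow the forward model the TRF estimator inverts: each
channel is the sum over regressors of the per-note impulse train convolved
with a known lag-resolved kernel, scaled by per-channel gains, plus white
or 1/f-shaped ("pink") noise. The default kernel is a difference of Gamma
densities with positive peaks near 75 and 200 ms and a sustained negative
deflection over 0.3–0.6 s, the canonical auditory P1/P2/late-negativity
morphology. Kernels live on the same lag grid (−0.2–1.0 s) used for
estimation, so noiseless recovery is exact to numerical precision. Every
generator call owns its RNG stream with the seed in its config.

What the simulation does **not** emulate: sensor topography and field
spread, artifacts (blinks, jumps, muscle), non-linear or adaptive neural
responses, and any coupling between acoustics and the neural signal beyond
the specified regressors. Passing tests therefore demonstrate correctness
of the estimation machinery under the linear-convolution model, not
fidelity to any particular recording system.

## TRF estimation and model comparison

- Design: lags −0.2–1.0 s (73 columns per regressor at 60 Hz); column
  (f, ℓ) at row s holds regressor f at sample s − ℓ, zero-padded, so the
  design-times-kernel product is exactly a convolution. Continuous per-note
  features are z-scored over note entries before placement; onset samples
  use half-up rounding.
- Estimation: SVD-based least squares with an always-included, never
  penalized intercept. Rank deficiency raises an error naming the
  regressors involved (pivoted QR); a pseudo-inverse mode is available and
  flagged in the output.
- Band-pass: zero-phase (forward–backward) Hamming-window FIR, length 3
  cycles of the lower edge; the bad-sample mask is dilated by the filter
  half-length.
- Cross-validation: five contiguous 20 % time blocks. Training rows within
  one lag span of a fold boundary are dropped, so no training row's window
  overlaps held-out data. Channel data are z-scored with training-row
  statistics only (the leak-free variant of global z-scoring). Models are
  fit on the full lag window but predictions are scored from the 0–0.6 s
  lag columns; the per-fold score is the Pearson r over the concatenated
  test rows, summarized as the median across folds and the mean across
  selected channels.
- Channel selection: channels strictly above the 2/3 quantile of the
  onset-model summary r; if ties select nothing, all channels are kept with
  a warning.
- Ridge: penalty chosen by nested CV over contiguous inner blocks; the
  candidate list must include 0 so plain OLS is always in play. A
  zero-variance paired difference in model comparison reports NaN, not ±∞.
- Comparison: per-participant summary-r differences, paired t-tests,
  Holm-adjusted p-values (the adjustment is tested against both the
  step-down definition and a reference implementation), Cohen's d as
  mean/SD of the differences.

## Cluster statistics

- Hat-adjusted t: `t = mean / sqrt((var + σ·max_var)/n)` with σ = 1e−3,
  where `max_var` is the maximum sample variance over the tested map; σ = 0
  recovers the classical one-sample t exactly.
- Cluster formation needs a primary threshold (TFCE does not): two-sided
  α = 0.05 on the hat-t map, configurable. Clusters connect temporally
  adjacent lags within a channel and neighboring channels at the same lag;
  adjacency is an explicit graph (ring or grid builders are provided for
  the synthetic arrays).
- Permutation null: sign flips across participants; p = (1 + #(perm ≥
  obs))/(1 + n_permutations), so p is never zero. TFCE uses
  `Σ_h e(h)^E h^H dh` with E = 0.5, H = 2 and at least 50 integration
  levels from 0.1 to the map maximum, with a max-statistic null for
  per-sample p-values.
- Calibration is measured on pure-noise maps (200 runs); a comparison
  false positive counts only experiments concluding a *positive*
  improvement (Holm-adjusted p < 0.05 and t > 0), the direction a study
  would act on.

## Problem sizes of the bundled studies

The validation studies run at desk scale, chosen to be comfortably
informative on one CPU: kernel recovery uses 400-note melodies (about the
length of a real composition), 4 channels, 20 replications, at
signal-RMS/noise-SD = 0.5; the calibrations use 200 simulated experiments
with 8 participants each (cluster maps 4 × 73; comparisons on ~50 s
recordings); the context sweep uses five 150-note pieces and 8
simulated participants; the default end-to-end experiment uses six
100-note compositions, a 24-piece training corpus, and six participants
with six channels at 60 Hz.

## Known limitations

- The Gestalt model's key inference is exact but assumes a single global
  key per piece; modulations are absorbed by the posterior rather than
  modelled.
- Short-term models see only the current piece; pieces shorter than ~50
  notes give them little to learn, and their entropy-weighted combination
  with the long-term model inherits that.
- Acoustic features (RMS, spectral flatness, gammatone envelope variance)
  assume the audio is aligned to the note table; no onset detection is
  performed. Synthetic experiments without audio carry the acoustic
  columns from generator ground truth or zeros.
- The cluster tests assume exchangeable participants under the null
  (symmetric errors); the permutation p-values are Monte-Carlo estimates
  with resolution 1/(n_permutations + 1).
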