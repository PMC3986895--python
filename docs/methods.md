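# Methods

This note records the model behind `barkit`'s synthetic data, the main
parameter choices and their rationale, the numerical decisions that affect
results, and what the synthetic data can and cannot demonstrate.

## 1. Parametric feature model

`sample_feature_table` draws per-call vectors of the five features with
published per-population distributions — Ex1 duration (ms), F0 start (Hz),
F0 linear trend (dimensionless), frequency range (Hz), peak-frequency
deviation (Hz) — for three populations:

| population   | ex1_duration | f0_start | f0_linear_trend | frequency_range | pf_deviation |
|--------------|-------------:|---------:|----------------:|----------------:|-------------:|
| green_monkey | 262 ± 110    | 254 ± 40 | −0.14 ± 0.12    | 197 ± 708       | 128 ± 68     |
| south_vervet |  99 ± 16     | 282 ± 57 | −0.11 ± 0.23    | 116 ± 831       | 101 ± 53     |
| east_vervet  | 113 ± 19     | 320 ± 61 | −0.10 ± 0.23    | 565 ± 645       | 156 ± 115    |

The default design is the study design: 12/12/13 males contributing
120/120/112 calls (352 in total, 10 calls per male with the deficit spread
over the last males of the third population).

Calls are nested within males. Only pooled per-population SDs are
published, so the male/call variance split is a model choice: a male-level
offset drawn from N(0, ρ·SD²) plus call-level noise N(0, (1−ρ)·SD²), with
`rho_male = 0.25` by default. Marginally each call is N(mean, SD²), so the
pooled moments match the table in expectation for any ρ. ρ = 0.25 gives a
moderate male effect — enough that ignoring male identity would inflate
significance, which is exactly the situation the nested permutation test
exists for. Features are sampled independently (no between-feature
correlations are published) and are not truncated, so the printed moments
are preserved even where SD > mean (frequency range).

## 2. Audio synthesis

`synthesize_element` renders an exhalation as a harmonic series (1/k
amplitude roll-off, all harmonics below 90 % of Nyquist, at most 30) whose
fundamental sweeps linearly, mixed with band-limited Gaussian noise in
proportion `tonal_fraction : 1 − tonal_fraction`, RMS-normalized, with a
5 ms raised-cosine edge ramp. `synthesize_bout` assembles elements into
calls and bouts with exact, deterministic gap structure (defaults:
intra-call gap 50 ms, inter-call gap 300 ms) and returns ground-truth
element labels; `noise_floor` adds Gaussian noise of that RMS everywhere.
The audio exists to exercise segmentation and feature extraction with a
known answer, not to imitate real bark timbre.

## 3. Segmentation

`detect_elements` thresholds the smoothed RMS envelope (1 ms window) at a
level relative to the bout peak (default −30 dB), bridges dropouts shorter
than 10 ms, and discards runs under 20 ms.

`estimate_call_threshold` estimates the intra/inter-call gap boundary from
the inter-unit intervals. Intervals are first rounded to 1 ns so that
float dust (values differing by ~1e−10 ms after envelope arithmetic)
cannot masquerade as distinct interval values. Two regimes:

* **Trivial separation.** If one empty gap between consecutive unique
  interval values covers ≥ 50 % of the whole observed range
  (`dominant_gap_fraction`), is ≥ 10 ms wide in absolute terms
  (`min_dominant_gap_ms`, so sub-resolution "gaps" inside one
  measurement-noise cluster never qualify), has at least two distinct
  values on each side, and carries 10–90 % of the interval mass above it,
  the intervals form two well-separated clusters and the threshold is the
  gap midpoint. Synthesized bouts, whose gaps are constant up to sub-ms
  detection jitter, fall in this regime; a fitted curve carries almost no
  information there and near-tie fits were observed to place the knee
  inside a cluster.
* **Log-survivor curve fit.** Otherwise the empirical log-survivor curve
  log S(t) = log P(interval > t) is fitted by every two-segment
  piecewise-linear partition (each limb ≥ 2 points, exhaustive scan,
  weighted least squares). Each point is weighted by its survivor
  fraction, and points supported by fewer than three surviving intervals
  are dropped, so the data-poor tail — where log S plunges toward −∞ on a
  handful of intervals — cannot dominate. Bimodality is declared only if
  the two-segment fit reduces the single-line weighted SSE by ≥ 20 %
  (`min_improvement`) *and* the first limb falls at least 2× more steeply
  than the second (`min_slope_ratio`); the threshold is the midpoint
  between the limbs. If the kept curve spans < 10 ms, or either criterion
  fails, `NoBreakpointError` is raised: a unimodal interval distribution
  has no defensible call boundary and the estimator refuses to invent one.

The decision constants were calibrated on held-out synthetic scenarios
*before* they were frozen: across bimodal uniform, knee-at-75-ms, unimodal
uniform/exponential and exponential-mixture interval sets, equal-mass
bimodal data produced slope ratios of roughly 3 and up while unimodal data
never exceeded 1.6, so 2.0 separates them with margin on both sides. On
100 noisy synthesized bouts at 20 dB SNR the frozen estimator places the
threshold inside the constructed gap in every bimodal case and rejects
every unimodal case (`scripts/acceptance.py`).

## 4. Features

31 per-call features (`FEATURE_COLUMNS`): call duration, element number,
Ex1 duration; F0 start/end/mean, F0 linear trend; and, from short-time
spectra of the Ex1 element, peak-frequency and energy-quartile (q1–q3)
statistics — medians, linear trends, deviations from the trend line, and
means over the four temporal quarters of the element — plus frequency
range and a tonality index.

Three analysis presets, all 1024-point Hamming FFTs with a 4 ms frame
step: `energy` (16 kHz rate → 15.625 Hz bins; quartiles, peak frequency,
frequency range), `tonality` (energy preset plus a 1.2 kHz lowpass — barks
are tonal only at low frequency and broadband noise otherwise corrupts the
voicing decision), and `f0` (8 kHz rate → 7.8125 Hz bins; autocorrelation
pitch tracking). Contour shape is summarized by a least-squares line: the
linear trend factor is the fitted total change divided by the contour mean
(sign gives direction), the deviation is the mean absolute residual.

Numerical choices: resampling uses polyphase filtering
(`scipy.signal.resample_poly`) with the exact rational rate ratio; filters
are zero-phase (`sosfiltfilt`), so filtering shifts no landmarks in time;
quartiles interpolate linearly within spectral bins rather than snapping
to bin edges.

Measurement floors, verified on synthesized elements and used as the
package's stated recovery conditions: at the `f0` preset one analysis
frame spans 128 ms, so an F0 *start* value is only meaningful for contours
that are flat over at least that span — on 200 constant-F0 elements the
median F0-start error is 0.26 Hz (well under the 7.8125 Hz bin width) and
the median duration error from envelope detection is 2.4 ms. The element
detector recovers onsets/offsets to within 5 ms down to 20 dB SNR
(noise RMS one tenth of element RMS) for detection thresholds in roughly
the −20 to −12 dB range; −15 dB is used in those conditions, while the
−30 dB default suits clean recordings.

## 5. Classification

`JackknifeLDA` is classical linear discriminant classification: pooled
within-class covariance, equal priors, leave-one-out assignment (the
held-out call is classified by a model refit without it; verified exactly
against an independent refit-per-holdout oracle). It reports confusion
counts/percentages, discriminant variance shares, and loadings.
`StepwiseLDASelector` adds features greedily while LOO accuracy improves
by more than 1/n (one call). `NestedPermutedDFA` / `pdfa_nested`
implements a permuted DFA for nested designs: the test statistic is the
mean LOO accuracy over balanced random subsets of calls per male, and the
null distribution permutes population labels across *whole males*, so
within-male correlation cannot manufacture significance. The p-value uses
the add-one rule, p = (1 + #{permuted ≥ observed}) / (1 + n_permutations).
Its type-I error at α = 0.05 was checked over 200 null replicates with
real male structure and falls inside the binomial 95 % band.

## 6. What the synthetic data does and does not show

The parametric generator demonstrates the *machinery*: that segmentation,
feature extraction, LOO-LDA and the nested pDFA are correct, deterministic
under seeds, and statistically calibrated. It does **not** reproduce the
classification rates reported for field recordings, and this is a property
of the generator, not a bug in the estimators:

* Under this generator (independent Gaussians, pooled published SDs,
  ρ = 0.25) the Bayes-optimal rate — measured by plugging the true
  per-population densities into the likelihood — is about 82.5 %.
  Pooled-covariance LDA is the wrong model for these data because the
  published SDs are strongly heteroscedastic across populations (e.g. Ex1
  duration SD 110 vs 16 ms), and it pays roughly 8 points for that
  mis-specification: measured mean LOO accuracy over 20 seeds is ~72–74 %,
  species-level ~92 %, first-discriminant variance share ~82–86 %
  depending on the seed set
  (`scripts/acceptance.py` writes the exact values for a given seed).
* Field recordings also carry between-feature correlations, non-Gaussian
  shape, and 26 further spectral features, none of which the published
  per-feature moments determine; the generator deliberately does not
  invent them.

So synthetic results validate correctness and calibration of the analysis
chain, and give honest effect sizes *for this generator*; they are not a
re-derivation of empirical classification rates.

## 7. Limitations

* The male/call variance split ρ is unidentifiable from published pooled
  SDs; 0.25 is a modelling choice and results depending on it (pDFA
  observed accuracy, male-effect size) should be read accordingly.
* Feature independence in the generator understates how redundant real
  acoustic features are; stepwise selection behaves differently on real
  correlated features.
* The audio synthesizer's gap structure is deterministic; real bouts have
  variable gaps, and the trivial-separation regime of the threshold
  estimator exists largely because of that synthetic regularity.
* Frequency-range draws can be negative (published SD exceeds the mean);
  they are kept to preserve the published moments, at the cost of
  physically impossible individual values.
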