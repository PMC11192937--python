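# Methods

This note documents the models and procedures implemented in tremorkit, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish about real recordings.

## Signal model and preprocessing

The tracked fingertip is modelled as a 2-D pixel trajectory containing a
quasi-sinusoidal tremor (4–8 Hz in essential tremor), slow postural drift
(< 1 Hz), broadband "prediction jitter" from frame-to-frame tracking
variability, confidence dropouts, and occasional gross mislocalisations
(spikes). Conditioning addresses the last three:

* cells with tracker confidence below `confidence_threshold` (default 0.5,
  the common tracker default) are masked;
* a landmark whose position jumps more than `spike_jump_px` (default
  100 px, strict inequality) from its **previous retained** position is
  masked — comparing against the last retained frame, not the immediate
  predecessor, prevents a spike from dragging its successor over the
  threshold;
* masked cells are linearly interpolated from the nearest retained
  neighbours. Edge gaps take the nearest retained value; edge gaps longer
  than 1 s, or any landmark with over half its frames masked, abort with a
  quality error rather than fabricate data.

Repaired cells are assigned confidence 1.0 and lie on straight segments,
which makes conditioning idempotent — verified by test.

Tremor band-passing uses a 4th-order Butterworth (1–10 Hz) applied
forward–backward (zero phase) so that amplitude peaks stay aligned with the
raw motion. A separate high-pass for drift would be redundant inside this
band-pass and is not applied. The accelerometer chain uses the 5th-order
variant of the same filter.

**Scalar reduction.** Trackers provide coordinates, not a tremor scalar.
The package projects the band-passed x/y displacement onto its first
principal axis. For linear tremor this captures the full excursion
regardless of the tremor's direction in the image; the *directionality
index* (variance fraction on the first axis) is recorded, and values below
0.6 add a warning to the signal's provenance because amplitude is then
direction-ambiguous (circular motion gives ≈ 0.5). z-coordinates, when
present, are ignored by default since tracker depth is poorly calibrated.

**Calibration.** Pixel→mm scale comes either from a calibration board or
from the interpupillary distance (real mm / apparent px). Without a
calibration, outputs remain in px and are flagged non-metric.

**Kinetic trials.** Finger-to-nose recordings contain rest periods; the
index-fingertip signal is gated to movement bursts found by the same
envelope rule as the accelerometer pipeline (moving average of |x| over
0.5 s, active above 50 % of its 95th percentile, bursts closer than 0.25 s
merged, shorter than 1 s dropped). These four constants are scale-free
choices, config-exposed, made here because no reference values exist.

## Amplitude and frequency estimation

Short-time spectra use 1 s Hann windows with 50 % overlap, zero-padded to
the next power of two; the window length mirrors the accelerometer
pipeline's 1 s segments for cross-method comparability. The dominant bin
is searched only inside 1–10 Hz (ties go to the lower frequency), so drift
or noise bins can never win.

Amplitude is reported as the **peak-to-peak displacement of the dominant
sinusoidal component**. Peak-to-peak is the convention that matches
clinical rating anchors (~20 mm per score step) and the 10 mm equivalence
margin. It is recovered by integrating spectral energy over the window's
main lobe (peak ± 2 unpadded bins) and applying Parseval's identity,

    A_pp = 4 · sqrt( Σ_lobe |Y_k|² / (N_fft · Σ w_n²) ),

which is exact for a pure sinusoid at any inter-bin position (no scallop
correction table needed). Two consequences: (i) band noise falling inside
the lobe biases amplitude slightly upward — at 10 dB in-band SNR the bias
is ~2–4 %, inside the 5 % recovery target; (ii) the estimate needs no
window-specific calibration constants.

Because the conditioning filter is known, its passband droop is undone:
the per-window amplitude is divided by the filter's zero-phase gain
evaluated at the main lobe's power-weighted centroid (a finer frequency
estimate than the bin centre; using the bin centre instead over-corrects
near the steep 10 Hz edge). The number of filter applications is tracked
in the signal's provenance.

All-zero windows report amplitude 0 with an undefined (NaN) dominant
frequency. Summaries collapse windows into peak and mean amplitude, mean
dominant frequency, and their standard deviations (reported as precision,
ddof = 1, defined as 0 for a single window).

## Diagnostic features

**Harmonic ratio.** The Welch-averaged spectrum (5 s Hann segments, 50 %
overlap, 4× zero-padding for fine bins) is searched for the global in-band
maximum f₁ and the strongest local maximum f₂ at least 1 Hz away from f₁
with relative *amplitude* of at least 5 % (i.e. √(P₂/P₁) ≥ 0.05). The
floor is deliberately on the amplitude scale: a textbook even harmonic at
20 % relative amplitude carries only 4 % of the power and must qualify.
f₂/f₁ ≈ 2 marks an even harmonic, consistent with essential tremor; the
result is "absent" when no second peak qualifies.

**Inter-limb coherence.** Magnitude-squared coherence is estimated from
Welch cross/auto-spectra (1 s Hann segments, 50 % overlap; arguments are
canonically ordered internally so coherence(a,b) and coherence(b,a) are
bit-identical). The significance level uses the classical
independent-segment formula `1 − α^{1/(L−1)}` with `L` counted as the
number of *non-overlapping* segments in the record — a 20-segment record
gives 0.146, and the formula is length-dependent by construction. The
verdict compares the maximum coherence inside the essential-tremor band
(4–8 Hz, config-exposed) with this level; using the full 1–10 Hz band
would conflate drift/noise bins with the tremor peak. Because the
threshold is per-frequency while the verdict takes a band maximum over ~5
bins, a perfectly incoherent pair still exceeds the level in roughly 5 %
of records; Monte-Carlo tests bound this at 10 %.

## Accelerometer pipeline

Axis selection takes the largest band-passed peak-to-peak range (gravity
offsets are removed by the filter; ties break to the lowest index).
Postural recordings are one trial after dropping the first and last second
— an automatable proxy for the manual, video-synchronised trimming of
voluntary arm movements used in laboratory practice, and a documented
deviation from it. Kinetic recordings are segmented into bursts as above.
Per trial, the PSD uses the classic Welch estimator with **rectangular**
1 s windows and 0.5 s overlap (1 Hz bins, no zero-padding), and the in-band
peak is recorded; the summary is the mean and SD across trials. The
accelerometer path estimates frequency only — amplitude from acceleration
would require double integration and is out of scope.

## Statistics

* **Agreement**: Pearson when Shapiro–Wilk accepts normality of both
  series at α (the visual Q-Q inspection of laboratory practice is not
  automatable), Spearman otherwise, with manual override. Mean signed
  error with t-based 95 % CI; Bland–Altman bias and 1.96·SD limits of
  agreement; proportional bias as the regression slope of differences on
  means.
* **TOST equivalence**: two one-sided one-sample t-tests of the paired
  differences against ±SESOI, with the standard 90 % CI duality
  (equivalent ⇔ CI inside the band ⇔ both p < α — exact, tested on random
  instances). Zero-variance differences are flagged degenerate and judged
  by |mean| < SESOI. SESOI defaults: 10 mm amplitude (half a clinical
  anchor step), 0.5 Hz frequency.
* **Paired contrasts**: paired t (Cohen's d_z) or Wilcoxon signed-rank
  with the matched rank-biserial correlation
  r = (Σ ranks⁺ − Σ ranks⁻)/Σ ranks. Effect-size CIs use normal
  approximations (nct-free); the rank-biserial matches an exhaustive
  signed-rank enumeration and an independent implementation in tests.
* **Post-hoc power for correlations**: the critical sample correlation is
  exact (t-transform, n−2 df); the sampling distribution under the
  alternative uses the Fisher-z approximation with bias term
  ρ/(2(n−1)) and SD 1/√(n−3). One-sided by default. At ρ = 0 the power is
  exactly α because the critical value is the exact null quantile. This
  is a reconstruction: the printed clinical power range's exact procedure
  is not documented, and the reconstruction reproduces its lower value
  (0.69 at ρ = 0.72, n = 8) but is not guaranteed to reproduce other
  published power figures.
* **ROUT outlier removal**: straight-line/constant case only (sufficient
  here) — IRLS with Lorentzian weights, robust scale from the 68.27th
  percentile of |residuals| inflated by n/(n−2), residual t-scores with
  Benjamini–Hochberg step-up at rate Q (default 1 %); Q = 0 never flags.
  The final slope/intercept are OLS on the clean points.

## Outcome modelling

Responder binarization: *poor* ⇔ residual amplitude ≥ 20 mm **and**
relative reduction ≤ 30 % under stimulation. (The two published phrasings
of this rule differ; the residual-and-reduction form is implemented and
the other treated as an erratum. Both constants are config-exposed.)

The logistic model uses maximum likelihood (Wald p per coefficient,
likelihood-ratio χ² versus intercept-only, McFadden R² = 1 − ll/ll₀) on a
default feature set of peak kinetic/postural amplitude and dominant
kinetic/postural frequency — "baseline limb kinematics" is otherwise
underspecified, and the set is fully config-driven. One table row is one
analysis unit. Perfect separation is detected (non-convergence or runaway
coefficients) and reported as such, with a lightly ridge-penalised
fallback flagged in the result instead of silent divergence.

LOOCV refits the model n times, pools the held-out probabilities, and
computes AUROC on the pool (per-fold AUROC is undefined for single-sample
folds); class predictions at 0.5 give the confusion matrix, balanced
accuracy and F1. A single-class training fold (only possible when the
minority class has one member) predicts the fold prevalence and warns.

## Synthetic data: what it emulates, and what it does not

The keypoint generator produces a rigid 21-landmark hand whose fingertips
oscillate along one fixed random in-plane axis — tremor amplitude is a
scalar concept, so 1-D motion is the reference condition, with a circular
option for stress tests. Defaults describe a typical trial: 5 Hz, 10 mm
peak-to-peak, 60 Hz video, 30 s, 0.9 mm/px scale, 5 mm drift at 0.3 Hz,
0.5 px white Gaussian jitter, 2 % confidence dropouts, ~1 spike/min of
150–300 px. Amplitudes 2–40 mm and frequencies 4–8 Hz span the clinical
range. Drift is a low-frequency sinusoid and jitter white Gaussian — the
simplest processes matching the named artefacts.

Bilateral recordings mix a shared and an independent narrowband oscillator
(white noise band-passed to ~1.2 Hz around f₀, re-normalised to equal
marginal amplitude): mixing 0 gives independent hands, 1 identical drives.
Two *pure* sinusoids at one frequency are always perfectly coherent, so
stochastic phase modulation is essential; the ~1 Hz bandwidth matches
physiological tremor peak width and keeps the oscillator's correlation
time below one analysis segment, the regime in which the segment-count
threshold formula is calibrated. Narrower-band tremor would genuinely
inflate the false-coherence rate — a property of the threshold, not of
this implementation.

The cohort generator draws baseline features from truncated Gaussians
(frequencies ~5.75/5.9 ± 0.58 Hz; baseline kinetic amplitude
N(35, 10) mm truncated at 20 mm — below the residual threshold a poor
response is unrepresentable by the binarization rule, which would truncate
the generating logistic model), assigns the poor/good label from a
logistic model (default: 55 % poor prevalence at the feature means,
per-mm log-odds ln(1/0.89) on baseline kinetic amplitude), and draws the
relative reduction from label-conditional Gaussians restricted to the
label-consistent interval, so the stored label always agrees with the
binarization rule. Every generator is a pure function of its seed and
returns a serialisable ground-truth record.

What passing the synthetic suites does **not** show: robustness to
non-rigid hand deformation, perspective and out-of-plane motion,
tracker-specific error correlations, non-sinusoidal or amplitude-modulated
tremor, or the clinical distribution of artefacts. The amplitude-recovery
and calibration results are therefore statements about the algorithm, not
about any particular tracker's field accuracy.

## Problem sizes

The test suites simulate 30 s recordings at 60 Hz (video) and 128 Hz
(accelerometer); Monte-Carlo suites use 100 seeds for coherence
calibration, 2000 replicates for TOST, and 50 cohorts of n = 200 for
outcome-model recovery — sizes at which the binomial/Monte-Carlo error of
each assertion is well below its tolerance.

## Known limitations

* ROUT covers straight-line fits only; no general curve fitting.
* Effect-size CIs use normal approximations, not noncentral inversions.
* The coherence threshold assumes independent segments; strongly
  narrowband signals violate this and raise the false-alarm rate.
* Postural trial trimming (fixed 1 s) is a proxy for video-synchronised
  manual segmentation.
* No pose estimation, video decoding, 3-D reconstruction or clinical score
  prediction; the tracker and the rating scale sit outside the package
  boundary.
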