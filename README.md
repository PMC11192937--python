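# tremorkit

Video-based tremor analysis for movement-disorder research: from the
keypoint time series of any 21-landmark hand tracker (and, for validation,
wrist accelerometry) to calibrated tremor amplitude and frequency, advanced
diagnostic features, method-agreement statistics and deep-brain-stimulation
(DBS) outcome prediction.

Clinical tremor severity is still mostly rated by eye on ordinal scales
whose anchor steps are ~20 mm of hand displacement. Markerless hand
tracking turns an ordinary video into per-frame fingertip coordinates, and
this package turns those coordinates into numbers a clinician or researcher
can use — without ever touching the tracker itself. It is aimed at motor
physiology labs and DBS centres that want contact-free tremor quantification
with an auditable, fully testable pipeline.

## What it computes

Given fingertip coordinates `p(t)` at frame rate `f_s` and a pixel→mm scale
`s` (from a calibration board, or `s = IPD_mm / IPD_px` with the patient's
interpupillary distance):

1. **Conditioning** — points with tracker confidence < 0.5 and jumps
   > 100 px from the previous retained frame are masked and linearly
   interpolated.
2. **Tremor signal** — the band-passed (zero-phase Butterworth, 1–10 Hz)
   x/y trajectory is projected onto its principal oscillation axis and
   scaled to mm.
3. **Spectral features** — short-time spectra (1 s Hann windows, 50 %
   overlap) give per-window dominant frequency `f* = argmax_f P(f)` over
   1–10 Hz and the **peak-to-peak displacement** of the dominant sinusoid,

   `A_pp = 4 · sqrt( Σ_lobe |Y_k|² / (N_fft · Σ_n w_n²) )`,

   which follows from Parseval's identity and is exact for a pure sinusoid
   regardless of where it falls between bins. Summaries report peak/mean
   amplitude, mean dominant frequency and their SDs (precision).
4. **Diagnostics** — the harmonic ratio `f₂/f₁` of the two largest spectral
   peaks (≈ 2 supports essential tremor) and the inter-limb
   magnitude-squared coherence with the length-dependent significance level
   `1 − α^{1/(L−1)}` (≈ 0.15 for ~20 one-second segments; essential tremor
   stays below it).
5. **Accelerometer reference** — axis with the largest band-passed range,
   5th-order Butterworth 1–10 Hz, Welch PSD with rectangular 1 s windows
   and 0.5 s overlap; dominant frequency per trial.
6. **Method agreement** — Pearson/Spearman correlation (Shapiro–Wilk
   guided), Bland–Altman limits of agreement, and TOST equivalence against
   a smallest effect size of interest (10 mm amplitude, 0.5 Hz frequency),
   plus ROUT robust outlier removal and post-hoc power for correlations.
7. **Outcome modelling** — responders binarized as *poor* when residual
   amplitude ≥ 20 mm **and** relative reduction ≤ 30 % under stimulation; a
   maximum-likelihood logistic model of response on baseline kinematics
   (Wald tests, likelihood-ratio χ², McFadden R²) evaluated by
   leave-one-out cross-validation (AUROC, balanced accuracy, F1).

A synthetic-data module generates keypoint series, accelerometer traces,
bilateral recordings with controllable coherence, and DBS cohorts from a
known logistic model — every stage is testable against ground truth.

## Worked example

```sh
tremorkit simulate --kind keypoints --seed 3 --out simdata
tremorkit analyze-keypoints --input simdata/keypoints.csv \
    --ipd-mm 63 --ipd-px 70 --out summary.json
```

The simulated recording is a 5 Hz, 10 mm peak-to-peak tremor filmed at
60 Hz for 30 s with realistic tracking noise. `summary.json` contains

```
mean_amplitude_mm      9.99
peak_amplitude_mm     10.40
dominant_frequency_hz  4.69
n_windows             59
```

i.e. the chain recovers the generated 10 mm amplitude to 0.1 % and the
5 Hz frequency to within half a frequency bin (the 1 s window zero-padded
to 64 samples gives 0.9375 Hz bins). The same data through the coherence
command (`tremorkit simulate --kind bilateral --mixing 0 ...`) reports a
peak tremor-band coherence of 0.085 against a threshold of 0.098 —
correctly *non-coherent*, as expected for independent hands.

Library use mirrors the CLI:

```python
import tremorkit as tk

ts, truth = tk.simulate_keypoint_tremor(tk.TremorSimParams(seed=3))
cal = tk.compute_scale(ipd_mm=63, ipd_px=70)          # 0.9 mm/px
signal = tk.analyze_chain(ts, "postural", cal)
summary = tk.summarize_tremor(tk.spectrogram_features(signal))
```

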