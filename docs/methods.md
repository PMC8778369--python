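# Methods

## The problem

Surface EMG controls today's hand prostheses, but residual forearm muscle
is often too weak, variable, or absent for reliable myoelectric control.
EEG decodes motion intent noninvasively but with a much lower
signal-to-noise ratio. `neurofuse` implements a multimodal strategy: train
a classifier on *fused* EEG+EMG time–frequency images while both sensors
are available (e.g., during rehabilitation), then transfer the learned
convolutional base to a single-modality model for daily use.

Because clinical recordings of this kind are not publicly deposited, the
package includes a first-class synthetic generator whose statistical
structure matches the experimental protocol, so every stage is testable.

## Signal model (synthetic generator)

A session consists of cue-locked epochs of 4.5 s (window −1.5…+3.0 s
around the cue; configurable) at 500 Hz, with three movement classes
(wrist dorsi/volar flexion, radial/ulnar deviation, hand grasp/open),
by default 100 trials per class (five sets of twenty repetitions).

**EEG** (9 motor-cortex channels: Fc3, Fc4, Cz, C1, C2, C3, C4, Cp3, Cp4):
pink (1/f-power) background noise plus mu (~10 Hz) and beta (~20 Hz)
oscillations with random phase and ±0.2 Hz frequency jitter per trial.
After the cue the oscillation amplitude on channel *c* in a class-*k*
trial is multiplied by `1 − erd_depth[k, c]` (event-related
desynchronization); band power therefore drops by `(1 − d)²`. The
oscillation amplitude is calibrated so that the oscillation-to-background
power ratio *within the oscillation's 1-Hz analysis bin* equals `snr`
(default 3.0). With that definition, the measured ERDS at the mu bin is
approximately `−(1 − (1−d)²)·snr/(1+snr)·100 %`, which stays within
±10 percentage points of `−100·d` for depths 0.2–0.8 at snr ≈ 3 — the
basis of the parameter-recovery check.

**EMG** (4 forearm muscles: flexor carpi ulnaris, extensor digitorum
communis, palmaris longus, extensor carpi radialis): white background
noise plus 30–249 Hz band-limited noise gated by a smooth post-cue
envelope (raised-cosine ramps, 2.5 s hold — the protocol's action
duration), scaled per class×muscle by `emg_gain` in multiples of the
background RMS (default 3).

Class information is spatial, mirroring motor somatotopy: which channels
desynchronize and which muscles activate. The default matrices give each
class two preferred EEG channels and two active muscles.

**What the generator does not emulate:** volume conduction and channel
correlations, eye/muscle artifacts in EEG, electrode-placement variation,
session nonstationarity, and within-pair movement variability (each
movement pair is one homogeneous class). Passing tests therefore
demonstrate the pipeline's correctness and the method's internal logic on
signals with the protocol's structure — not clinical performance.

## Preprocessing

60 Hz mains notch (IIR, Q=30) on both modalities; Butterworth order-4
bandpass 15–249 Hz for EMG and 5–35 Hz for EEG; all filters zero-phase
(forward–backward) so cue alignment is preserved. The nominal EMG upper
edge of 500 Hz is not realisable at a 500 Hz sampling rate; the default
caps it at 249 Hz and logs the cap. EEG artifact removal uses FastICA on
the concatenated epochs; components whose excess kurtosis exceeds a
threshold (default 5.0, common EEGLAB practice) are zeroed before
reconstruction. On clean simulated data nothing is rejected and
reconstruction is exact to numerical tolerance.

## ERDS maps and feature images

For each frequency bin the signal is bandpass filtered, linearly
detrended per trial, squared, averaged over the map's trials (default 5,
drawn without replacement within a map) and within 46 time bins tiling
the 4.5 s epoch. With R(f) the mean activity power over the reference
interval, the map value is `(P(t,f) − R(f))/R(f)·100 %`. Presets: EEG
5–35 Hz in 1 Hz steps (31 bands centred on integer frequencies); EMG
30–247 Hz in 7 Hz contiguous bands (31 bands, last band capped below
Nyquist where needed). Maps are 46×31 per channel; grayscale images
concatenate channels horizontally: 46×279 (EEG), 46×124 (EMG), 46×403
(fused). Padded single-modality images place the modality in its fused
columns and zero-fill the rest, so one 46×403×1 input serves all models.

Numerical choices worth knowing:

* **Per-bin filtering** is done in the frequency domain with the squared
  Butterworth magnitude response (the zero-phase forward–backward
  response) under periodic boundary conditions. Time-domain filtfilt on a
  4.5 s epoch with a 1 Hz-wide band rings for ~1–2 s and leaks
  phase-dependent transients deep into the epoch; the circular form
  confines the artifact to the outermost ~0.3 s.
* **Reference interval** defaults to −1.2…−0.5 s: fully pre-cue but clear
  of the contaminated epoch edge. This is the single most
  result-sensitive free choice and is configurable.
* A 1 Hz band averaged over n trials has per-bin relative power
  SD ≈ 1.3/√n (≈1 degree of freedom per 0.1 s bin), so individual map
  bins wander substantially at n = 5; map-level statements in the tests
  average over maps. Finite-epoch smearing biases a step response by
  ~2 pp.
* **Grayscale clipping** defaults to (−100 %, +150 %): ERD is bounded
  below by −100 % but ERS is unbounded above.
* Reference power below 1e−12 raises a degenerate-reference error rather
  than dividing silently.

**Bootstrap significance**: trials are resampled with replacement
(default 500 resamples); a bin is significant when the percentile
interval of the resampled ERDS (reference recomputed per resample)
excludes zero. Fewer than 20 resamples is rejected. The percentile method
on heavily skewed per-trial powers is anticonservative: under a true null
at 30 trials per map the measured false-positive rate is ≈0.07 at nominal
α = 0.05 (a known property of percentile intervals at this effective
degrees-of-freedom; bias-corrected methods would be needed to remove it,
and are deliberately out of scope because the percentile rule is the
method specified). Significance is computed but does not mask image
pixels unless explicitly enabled.

**Datasets**: per class, `n_maps_per_class` images are built from 5-trial
draws; the train/test split is at the map level (70/30 by default). The
study layer defaults to the *strict* split, partitioning raw trials
before drawing maps so no trial feeds both a train and a test image —
without it, test maps share trials with training maps and measured test
accuracy is inflated by trial memorization (we observed near-100 %
"accuracy" on information-free null simulations with the free draw).
The unrestricted free draw remains available.

## The classifier

Five convolutional blocks (same-padded 3×3 kernels; defaults
8/16/32/32/64 filters, ReLU), max pooling along the time axis only
(window 2, stride 2; 46→23→11→5→2→1, degrading to identity at extent 1),
dropout (0.5) before a fully connected softmax head over 3 classes;
cross-entropy loss. Training is SGDM (momentum 0.9), initial learning
rate 0.01 (grid 0.1–0.001 available via `grid_search_lr`, ties to the
smaller rate), 10 epochs, batch 16, shuffled every epoch, validation
metrics every 3 iterations; validation data never update weights. A
global gradient-norm ceiling (5.0) guards the first SGDM steps, which
otherwise occasionally kill the ReLUs and park the loss at the uniform
plateau. The network is implemented directly in NumPy (im2col-style
shifted matrix products, explicit backprop); a low-capacity preset
(4/8/8/8/16 filters) exists for quick studies.

**Transfer learning**: starting from the fused-image pretrained bundle,
conv blocks 1–4 are frozen (the lower layers are reused as-is), the
classification head is *reinitialized* — trained as a new layer, since
the pretrained head weighs the other modality's now-blank columns — and
block 5 plus the new head are retrained at 3×10⁻⁴ for 10 epochs on
padded single-modality images; a stricter mode freezes all five blocks.
Frozen parameters are bit-identical before and after — verified, not
assumed. Because a frozen prefix never changes, its activations are
computed once per dataset and training runs only above it.

## Evaluation and the synthetic study

Accuracy is correct/total × 100. Paired model comparisons use the
two-sided Wilcoxon signed-rank test, group comparisons the two-sided
Mann–Whitney U test, both exact for n ≤ 12 (the subject-table sizes);
all-zero paired differences are reported as degenerate rather than NaN.
Significance threshold 0.05.

`run_study` treats each seed as one synthetic subject: simulate →
preprocess → feature images → {single-EEG, single-EMG, multimodal
pretrain, TL-EEG, TL-EMG} → report, with the paired TL-vs-single
comparison across seeds. The `weak_eeg_sim` preset encodes the asymmetry
the method targets: every class desynchronizes the same motor channels
(base depth 0.4) with only a small somatotopic contrast (0.5 × the
preference pattern), which is what makes single-modal EEG genuinely hard
— wrist and hand movements engage largely the same cortex — while EMG
keeps distinct per-muscle activation and stays highly separable. The
preset was calibrated once so single-modal EEG lands mid-range between
chance and ceiling (the regime the method addresses) and then frozen.

Two safeguards matter for honest test accuracies. First, the strict trial
partition is built **once per recording and shared by every layout**: if
the fused (pretraining) dataset and the padded (transfer) dataset
partitioned trials independently, the pretrained base would have seen raw
trials sitting in the transfer dataset's test pool, and transfer scored
far above chance even on information-free null simulations before this
was fixed. Second, a from-scratch model that cannot fit its own training
split (train accuracy < 50 %, the surviving form of the plateau failure)
is retrained once at a tenth of the learning rate; only training metrics
are consulted.

With both safeguards, the desk-scale study shows single-EMG ~100 %,
single-EEG in the 30–60 % band with high between-seed spread, and TL-EEG
statistically indistinguishable from single-EEG in the mean, with lower
between-seed variance. A clear transfer *advantage* does not emerge on
this simulation, and the reason is structural: the only link between the
modalities here is the shared class label, so the convolutional base
pretrained on fused images offers the EEG columns only generic texture
features, not EEG-specific structure. (Before the shared-partition
safeguard existed, transfer appeared to add ~30 points; that entire gain
was traced to raw-trial leakage between the pretraining set and the
transfer test set.) A robust transfer gain would require cross-modal
structure — correlated latent dynamics, shared artifacts, richer EEG
patterns — that the generator deliberately does not invent; whether a
given recording provides it is exactly what this pipeline lets one test.

Study problem sizes used by the tests and the acceptance script — 60
trials per class, 60 maps per class, the low-capacity network, 10 seeds —
are the package's choice of a desk-scale study; the full-size defaults
(100 maps per class, 8/16/32/32/64 filters) remain available.

## Known limitations

* The EDF writer/reader covers EDF+C as this package exports it (one
  record per trial, one annotation channel); it is cross-checked against
  an independent reader but is not a general-purpose EDF library.
* Finite-epoch narrowband filtering leaves the outermost ~0.3 s of every
  map least reliable; the default reference interval avoids it, map
  consumers should too.
* The percentile bootstrap's null false-positive rate exceeds its nominal
  α (see above).
* Test accuracies on small map counts carry binomial noise of several
  percentage points; the study reports means over seeds for that reason.
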