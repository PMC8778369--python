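# neurofuse

Motion-intention classification from EEG and surface EMG via
time–frequency (ERDS-map) image features, a compact convolutional
classifier, and freeze-and-retrain transfer learning from a multimodal
fused model back to a single modality.

**For whom:** BCI and prosthetics researchers who want a tested,
end-to-end reference implementation of multimodal ERDS-image
classification — including a synthetic signal generator that stands in
for clinical recordings — and signal-processing engineers who need the
individual stages (filtering, ICA cleanup, ERDS maps, bootstrap
significance, image assembly) as a library.

## The method

For each frequency band *f* and time bin *t* around the movement cue, the
event-related (de)synchronization is the relative band-power change
against a pre-cue reference interval:

    ERDS(t, f) = (P(t, f) − R(f)) / R(f) × 100 %

computed by bandpass filtering, detrending, squaring, and averaging over
5 randomly drawn trials and 0.1 s bins. EEG uses 5–35 Hz in 1 Hz steps,
EMG 30–247 Hz in 7 Hz bands — 31 bands each over 46 time bins, giving a
46×31 grayscale map per channel. Maps concatenate into images: 46×279
(9 EEG channels), 46×124 (4 EMG channels), 46×403 (fused). A five-block
CNN (3×3 convolutions, time-axis-only max pooling, dropout, softmax) is
trained with SGDM (lr 0.01, 10 epochs, shuffled, validation every 3
iterations). Transfer learning freezes conv blocks 1–4 of the
fused-image model and retrains block 5 + head at lr 3×10⁻⁴ on
single-modality images zero-padded into the fused layout. Models are
compared with Eq-style accuracy (correct/total × 100), the Wilcoxon
signed-rank test (paired) and the Mann–Whitney U test (groups), exact at
small n.

See `docs/methods.md` for the signal model, numerical choices, and
limitations.

## Worked example

```python
import numpy as np
from neurofuse.study import StudyConfig, run_study, weak_eeg_sim

cfg = StudyConfig(sim=weak_eeg_sim(), small_net=True, n_seeds=5, seed=0)
report = run_study(cfg)
print(report.summary())
```

which prints (abridged; ~5 minutes on one CPU):

```
Synthetic study report
======================
config hash: cce5c43fc41e
seeds: [0, 1, 2, 3, 4]

Mean accuracy (%) over seeds:
  single_eeg    42.22 +- 14.90
  single_emg   100.00 +- 0.00
  multimodal    97.78 +- 3.31
  tl_eeg        41.85 +- 7.24
  tl_emg       100.00 +- 0.00
tl_eeg - single_eeg: median diff +3.70 pp, Wilcoxon signed-rank p=1.0000 (n=5)
tl_emg - single_emg: median diff +0.00 pp, Wilcoxon signed-rank degenerate (n=5)
```

Each seed is one synthetic "subject" with weakly informative EEG (all
classes desynchronize the same motor channels, differing only by a small
somatotopic contrast) and strongly informative EMG. Single-modal EMG is
near ceiling and single-modal EEG lands mid-range with high
between-subject spread. The transfer-learned EEG model — reusing the
convolutional base pretrained on fused EEG+EMG images — matches
single-modal EEG in the mean with visibly lower between-subject variance;
on this generator, where the class label is the only link between
modalities, transfer does not add a systematic accuracy gain (see
`docs/methods.md` for the analysis). The Wilcoxon lines are the paired
comparisons across seeds; the TL-EMG one is degenerate because both EMG
models sit at ceiling on every seed.

The same pipeline is scriptable stage by stage:

```bash
neurofuse simulate --out session.npz --seed 1 --edf session.edf
neurofuse features session.npz --out fused.npz --mode fused --seed 1
neurofuse pretrain fused.npz --out model.npz --small
neurofuse features session.npz --out eeg_pad.npz --mode eeg-padded --seed 2
neurofuse tl eeg_pad.npz --pretrained model.npz --out tl.npz
neurofuse predict eeg_pad.npz --model tl.npz
neurofuse run-study --out-dir study_out --seeds 10
```

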