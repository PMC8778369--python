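"""Synthetic cue-locked EEG+EMG trial generator.

Emulates the statistical structure of a three-class wrist/hand movement
protocol: nine motor-cortex EEG channels carrying mu (~10 Hz) and beta
(~20 Hz) rhythms that desynchronize after a visual cue, and four forearm
EMG channels carrying broadband (30-249 Hz) activity gated by a smooth
post-cue activation envelope.  A shared per-trial class label drives both
modalities, so multimodal fusion and transfer learning are testable
without clinical recordings.

The event-related desynchronization (ERD) is implemented as an amplitude
scaling of the oscillatory component: after the cue, the mu/beta amplitude
on channel c in a trial of class k is multiplied by ``1 - erd_depth[k, c]``
(band power therefore drops by the factor ``(1 - erd_depth)**2``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "EEG_CHANNELS",
    "EMG_CHANNELS",
    "SimConfig",
    "TrialSet",
    "default_erd_depth",
    "default_emg_gain",
    "simulate_trialset",
]

#: The nine motor-cortical channels used for classification.
EEG_CHANNELS = ("Fc3", "Fc4", "Cz", "C1", "C2", "C3", "C4", "Cp3", "Cp4")

#: The four forearm muscles recorded with surface electrodes.
EMG_CHANNELS = (
    "flexor carpi ulnaris",
    "extensor digitorum communis",
    "palmaris longus",
    "extensor carpi radialis",
)

#: Class labels: m1 wrist dorsi/volar flexion, m2 radial/ulnar deviation,
#: m3 hand grasp/open.
CLASS_NAMES = ("m1", "m2", "m3")


def default_erd_depth(n_classes: int = 3, n_channels: int = 9,
                      depth: float = 0.5) -> np.ndarray:
    """Class x EEG-channel ERD depth matrix.

    Classes are separated spatially, mirroring motor somatotopy: each class
    suppresses the mu/beta rhythm on its own subset of channels.  Channel
    order is :data:`EEG_CHANNELS`.
    """
    m = np.zeros((n_classes, n_channels))
    # channel indices: Fc3 Fc4 Cz C1 C2 C3 C4 Cp3 Cp4
    patterns = [
        [5, 6, 0, 1],   # m1: C3/C4 strong, Fc3/Fc4 secondary
        [3, 4, 2],      # m2: C1/C2, Cz
        [7, 8, 2],      # m3: Cp3/Cp4, Cz
    ]
    for k in range(n_classes):
        idx = patterns[k % len(patterns)]
        m[k, idx[:2]] = depth
        for j in idx[2:]:
            m[k, j] = max(m[k, j], depth * 0.5)
    return m[:, :n_channels]


def default_emg_gain(n_classes: int = 3, n_muscles: int = 4,
                     gain: float = 3.0) -> np.ndarray:
    """Class x muscle activation-amplitude matrix (multiples of background RMS)."""
    m = np.zeros((n_classes, n_muscles))
    patterns = [
        [0, 2],  # m1: flexor carpi ulnaris + palmaris longus
        [0, 3],  # m2: flexor carpi ulnaris + extensor carpi radialis
        [1, 3],  # m3: extensor digitorum communis + extensor carpi radialis
    ]
    for k in range(n_classes):
        for j in patterns[k % len(patterns)]:
            if j < n_muscles:
                m[k, j] = gain
    return m


@dataclass
class SimConfig:
    """Parameters of the synthetic recording session.

    Attributes
    ----------
    n_classes : int
        Number of movement classes (default 3).
    trials_per_class : int
        Cue-locked repetitions per class (default 100: five sets of
        twenty repetitions).
    fs : float
        Sampling rate in Hz (default 500).
    trial_span : (float, float)
        Epoch window in seconds relative to the cue; default (-1.5, 3.0),
        i.e. a 4.5 s epoch.
    erd_depth : ndarray (n_classes, n_eeg_channels)
        Fraction of post-cue oscillatory *amplitude* suppressed per
        class x channel; entries in [0, 1).
    emg_gain : ndarray (n_classes, n_emg_channels)
        Post-cue EMG activation amplitude per class x muscle, in multiples
        of the background RMS.
    snr : float
        Oscillation-to-background power ratio within the oscillation's
        1-Hz frequency bin (default 3.0).
    """

    n_classes: int = 3
    trials_per_class: int = 100
    fs: float = 500.0
    trial_span: tuple[float, float] = (-1.5, 3.0)
    n_eeg_channels: int = 9
    n_emg_channels: int = 4
    erd_depth: np.ndarray | None = None
    emg_gain: np.ndarray | None = None
    snr: float = 3.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_onset: float = 0.2       # s after cue at which suppression is full
    action_duration: float = 2.5  # s the movement is held
    emg_background_rms: float = 10.0   # uV
    eeg_background_rms: float = 10.0   # uV broadband pink-noise RMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erd_depth is None:
            self.erd_depth = default_erd_depth(self.n_classes, self.n_eeg_channels)
        if self.emg_gain is None:
            self.emg_gain = default_emg_gain(self.n_classes, self.n_emg_channels)
        self.erd_depth = np.asarray(self.erd_depth, dtype=float)
        self.emg_gain = np.asarray(self.emg_gain, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("fs", "snr", "mu_freq", "beta_freq", "erd_onset",
                     "action_duration", "emg_background_rms",
                     "eeg_background_rms"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"SimConfig.{name} must be finite, got {v!r}")
        for name in ("n_classes", "trials_per_class", "n_eeg_channels",
                     "n_emg_channels"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"SimConfig.{name} must be a positive count, got {v!r}")
        lo, hi = self.trial_span
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"trial_span must be finite and increasing, got {self.trial_span}")
        if not np.all(np.isfinite(self.erd_depth)):
            raise ValueError("erd_depth contains non-finite entries")
        if not np.all(np.isfinite(self.emg_gain)):
            raise ValueError("emg_gain contains non-finite entries")
        if np.any(self.erd_depth < 0) or np.any(self.erd_depth >= 1):
            raise ValueError("erd_depth entries must lie in [0, 1)")
        if self.erd_depth.shape != (self.n_classes, self.n_eeg_channels):
            raise ValueError(
                f"erd_depth shape {self.erd_depth.shape} != "
                f"({self.n_classes}, {self.n_eeg_channels})")
        if self.emg_gain.shape != (self.n_classes, self.n_emg_channels):
            raise ValueError(
                f"emg_gain shape {self.emg_gain.shape} != "
                f"({self.n_classes}, {self.n_emg_channels})")

    @property
    def n_samples(self) -> int:
        return int(round((self.trial_span[1] - self.trial_span[0]) * self.fs))

    @property
    def cue_index(self) -> int:
        return int(round(-self.trial_span[0] * self.fs))

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TrialSet:
    """Cue-locked multichannel epochs with class labels.

    ``eeg`` is (trials, channels, samples) in uV, likewise ``emg``.
    ``cue_index`` is the sample index of the trigger within each epoch.
    """

    eeg: np.ndarray
    emg: np.ndarray
    labels: np.ndarray
    fs: float
    cue_index: int
    eeg_channel_names: tuple[str, ...] = EEG_CHANNELS
    emg_channel_names: tuple[str, ...] = EMG_CHANNELS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.eeg.ndim != 3 or self.emg.ndim != 3:
            raise ValueError("eeg and emg must be (trials, channels, samples)")
        if len(self.labels) != self.eeg.shape[0] or len(self.labels) != self.emg.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not (0 <= self.cue_index < self.eeg.shape[2]):
            raise ValueError("cue_index must lie within the epoch")
        if self.eeg.shape[1] != len(self.eeg_channel_names):
            raise ValueError("eeg channel-name count mismatch")
        if self.emg.shape[1] != len(self.emg_channel_names):
            raise ValueError("emg channel-name mismatch")

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue."""
        return (np.arange(self.n_samples) - self.cue_index) / self.fs

    def modality(self, which: str) -> np.ndarray:
        if which == "eeg":
            return self.eeg
        if which == "emg":
            return self.emg
        raise ValueError(f"unknown modality {which!r}; expected 'eeg' or 'emg'")

    def channel_names(self, which: str) -> tuple[str, ...]:
        if which == "eeg":
            return self.eeg_channel_names
        if which == "emg":
            return self.emg_channel_names
        raise ValueError(f"unknown modality {which!r}")

    def copy_with(self, **kw) -> "TrialSet":
        d = dict(eeg=self.eeg, emg=self.emg, labels=self.labels, fs=self.fs,
                 cue_index=self.cue_index,
                 eeg_channel_names=self.eeg_channel_names,
                 emg_channel_names=self.emg_channel_names)
        d.update(kw)
        return TrialSet(**d)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float, rms: float) -> tuple[np.ndarray, np.ndarray]:
    """1/f-power noise via spectral shaping.

    Returns the noise array (``shape + (n_samples,)``) and the one-sided
    per-frequency expected power spectrum (same frequency grid as
    ``np.fft.rfftfreq``), normalised so total expected power equals
    ``rms**2``.  The spectrum lets callers compute the expected background
    power in any band analytically.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(freqs[nz])
    # normalise expected total power (excluding DC) to rms**2
    power = amp ** 2
    power *= rms ** 2 / power.sum()
    amp = np.sqrt(power)
    w = rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(shape + (len(freqs),))
    spec = w * amp
    spec[..., 0] = 0.0
    # irfft scaling: with iid complex-normal w (E|w|^2 = 2) each positive
    # bin k plus its conjugate contributes 4*amp_k^2/n^2 to Var(x_t), so a
    # factor n/2 makes the band power in [f_lo,f_hi] equal sum(power[band]).
    x = np.fft.irfft(spec, n=n_samples, axis=-1) * (n_samples / 2.0)
    return x, power


def _band_power_of_spectrum(power: np.ndarray, freqs: np.ndarray,
                            f_lo: float, f_hi: float) -> float:
    """Expected noise power within [f_lo, f_hi] from a one-sided spectrum."""
    sel = (freqs >= f_lo) & (freqs < f_hi)
    return float(power[sel].sum())


def _post_cue_envelope(times: np.ndarray, onset: float, duration: float,
                       ramp: float = 0.2) -> np.ndarray:
    """Smooth 0->1->0 gate starting at the cue, sustained for ``duration``."""
    env = np.zeros_like(times)
    up = (times >= 0) & (times < onset)
    env[up] = 0.5 * (1 - np.cos(np.pi * times[up] / onset))
    hold = (times >= onset) & (times < duration)
    env[hold] = 1.0
    down = (times >= duration) & (times < duration + ramp)
    env[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - duration) / ramp))
    return env


def simulate_trialset(cfg: SimConfig) -> TrialSet:
    """Generate a cue-locked EEG+EMG :class:`TrialSet` from ``cfg``.

    EEG per trial/channel: pink background noise plus mu and beta
    oscillations whose post-cue amplitude is scaled by
    ``1 - erd_depth[class, channel]``.  Oscillation amplitude is calibrated
    so that the oscillation-to-background power ratio inside the
    oscillation's 1-Hz bin equals ``cfg.snr``.

    EMG per trial/muscle: white background noise plus 30-249 Hz band-limited
    noise gated by a smooth post-cue envelope scaled by
    ``emg_gain[class, muscle]``.

    Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_trials = cfg.n_classes * cfg.trials_per_class
    ns = cfg.n_samples
    t = (np.arange(ns) - cfg.cue_index) / cfg.fs  # seconds rel. cue

    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    rng.shuffle(labels)

    # ---- EEG ----------------------------------------------------------
    eeg, bg_power = _pink_noise(rng, (n_trials, cfg.n_eeg_channels), ns,
                                cfg.fs, cfg.eeg_background_rms)
    freqs = np.fft.rfftfreq(ns, d=1.0 / cfg.fs)

    # ERD gate: 1 pre-cue, (1 - depth) while the action is held
    gate = _post_cue_envelope(t, cfg.erd_onset, cfg.action_duration + 0.3,
                              ramp=0.3)

    for f0 in (cfg.mu_freq, cfg.beta_freq):
        bg_in_bin = _band_power_of_spectrum(bg_power, freqs, f0 - 0.5, f0 + 0.5)
        osc_amp = np.sqrt(2.0 * cfg.snr * bg_in_bin)  # sine of power snr*bg
        phase = rng.uniform(0, 2 * np.pi, size=(n_trials, cfg.n_eeg_channels))
        jitter = rng.uniform(-0.2, 0.2, size=(n_trials, cfg.n_eeg_channels))
        depth = cfg.erd_depth[labels][:, :, None]          # (trials, ch, 1)
        amp_t = 1.0 - depth * gate[None, None, :]          # amplitude scale
        carrier = np.sin(2 * np.pi * (f0 + jitter)[:, :, None] * t[None, None, :]
                         + phase[:, :, None])
        eeg += osc_amp * amp_t * carrier

    # ---- EMG ----------------------------------------------------------
    emg = rng.standard_normal((n_trials, cfg.n_emg_channels, ns)) * cfg.emg_background_rms
    env = _post_cue_envelope(t, cfg.erd_onset, cfg.action_duration, ramp=0.2)
    # band-limited carrier noise, 30-249 Hz, unit RMS
    from scipy.signal import butter, sosfiltfilt
    hi = min(249.0, 0.499 * cfg.fs)
    sos = butter(4, [30.0, hi], btype="bandpass", fs=cfg.fs, output="sos")
    carrier = sosfiltfilt(sos, rng.standard_normal((n_trials, cfg.n_emg_channels, ns)), axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)
    gain = cfg.emg_gain[labels][:, :, None] * cfg.emg_background_rms
    emg += gain * env[None, None, :] * carrier

    return TrialSet(eeg=eeg, emg=emg, labels=labels, fs=cfg.fs,
                    cue_index=cfg.cue_index,
                    eeg_channel_names=tuple(EEG_CHANNELS[: cfg.n_eeg_channels])
                    if cfg.n_eeg_channels <= len(EEG_CHANNELS)
                    else tuple(f"EEG{i}" for i in range(cfg.n_eeg_channels)),
                    emg_channel_names=tuple(EMG_CHANNELS[: cfg.n_emg_channels])
                    if cfg.n_emg_channels <= len(EMG_CHANNELS)
                    else tuple(f"EMG{i}" for i in range(cfg.n_emg_channels)))
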