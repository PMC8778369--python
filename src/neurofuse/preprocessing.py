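"""Filtering, ICA artifact cleanup, and channel selection.

The standard chain mirrors common electrophysiology practice: a 60 Hz
mains notch on both modalities, a 15-249 Hz bandpass for EMG, a 5-35 Hz
bandpass for EEG, then ICA-based artifact removal on the EEG.  All filters
are zero-phase (forward-backward) by default so cue alignment is preserved.

Note on the EMG band: a 15-500 Hz passband is not realisable at a 500 Hz
sampling rate (Nyquist 250 Hz); the default upper edge is capped at 249 Hz
and the cap is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import kurtosis

from neurofuse.simulate import TrialSet

logger = logging.getLogger("neurofuse")

__all__ = [
    "FilterSpec",
    "ICAResult",
    "apply_filter",
    "run_ica_cleanup",
    "select_channels",
    "standard_chain",
]


@dataclass(frozen=True)
class FilterSpec:
    """A notch or bandpass filter description.

    ``kind`` is ``"notch"`` (band = (f0,) centre frequency, ``q`` quality
    factor) or ``"bandpass"`` (band = (lo, hi) Hz, Butterworth of ``order``).
    ``zero_phase`` applies the filter forward and backward.
    """

    kind: str
    band: tuple[float, ...]
    order: int = 4
    q: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("notch", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "notch" and len(self.band) != 1:
            raise ValueError("notch filter takes a single centre frequency")
        if self.kind == "bandpass":
            if len(self.band) != 2 or not self.band[0] < self.band[1]:
                raise ValueError("bandpass band must be (low, high) with low < high")

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2.0
        for edge in self.band:
            if not 0 < edge < nyq:
                raise ValueError(
                    f"filter edge {edge} Hz is not strictly inside (0, {nyq}) "
                    f"at fs={fs} Hz; cap the edge below Nyquist (e.g. "
                    f"{min(edge, nyq - 1):g} Hz) or resample")

    # presets --------------------------------------------------------------
    @staticmethod
    def mains_notch(f0: float = 60.0) -> "FilterSpec":
        return FilterSpec("notch", (f0,))

    @staticmethod
    def eeg_bandpass() -> "FilterSpec":
        """The 5-35 Hz EEG passband."""
        return FilterSpec("bandpass", (5.0, 35.0))

    @staticmethod
    def emg_bandpass(fs: float = 500.0) -> "FilterSpec":
        """The EMG passband, nominally 15-500 Hz, capped below Nyquist."""
        hi = 500.0
        nyq = fs / 2.0
        if hi >= nyq:
            hi = min(249.0, nyq - 1.0)
            logger.warning(
                "EMG bandpass upper edge 500 Hz exceeds Nyquist (%g Hz at "
                "fs=%g); capping at %g Hz", nyq, fs, hi)
        return FilterSpec("bandpass", (15.0, hi))


def _design(spec: FilterSpec, fs: float):
    if spec.kind == "notch":
        b, a = sps.iirnotch(spec.band[0], spec.q, fs=fs)
        return sps.tf2sos(b, a)
    return sps.butter(spec.order, spec.band, btype="bandpass", fs=fs,
                      output="sos")


def filter_array(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply ``spec`` along the last axis of ``x``."""
    spec.validate_for(fs)
    sos = _design(spec, fs)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def apply_filter(ts: TrialSet, spec: FilterSpec, modality: str) -> TrialSet:
    """Return a copy of ``ts`` with one modality filtered.

    Trial count, labels and cue alignment are unchanged.
    """
    x = ts.modality(modality)
    y = filter_array(x, spec, ts.fs)
    logger.info("applied %s filter %s (order %d) to %s", spec.kind, spec.band,
                spec.order, modality)
    return ts.copy_with(**{modality: y})


def standard_chain(ts: TrialSet, ica_threshold: float = 5.0,
                   seed: int = 0) -> tuple[TrialSet, "ICAResult"]:
    """Notch both modalities, bandpass EMG 15-249 Hz and EEG 5-35 Hz,
    then ICA-clean the EEG.  Returns the cleaned trial set and ICA result."""
    out = apply_filter(ts, FilterSpec.mains_notch(), "eeg")
    out = apply_filter(out, FilterSpec.mains_notch(), "emg")
    out = apply_filter(out, FilterSpec.emg_bandpass(ts.fs), "emg")
    out = apply_filter(out, FilterSpec.eeg_bandpass(), "eeg")
    out, ica = run_ica_cleanup(out, kurtosis_threshold=ica_threshold, seed=seed)
    return out, ica


# --------------------------------------------------------------------------
# ICA
# --------------------------------------------------------------------------

@dataclass
class ICAResult:
    """Outcome of ICA decomposition and artifact rejection on the EEG.

    ``unmixing @ (x - mean)`` gives sources; ``mixing`` maps sources back.
    ``scores`` is the excess kurtosis per component; components whose score
    exceeds the threshold are listed in ``rejected``.
    """

    mixing: np.ndarray
    unmixing: np.ndarray
    mean: np.ndarray
    scores: np.ndarray
    rejected: list[int]
    threshold: float


def run_ica_cleanup(ts: TrialSet, kurtosis_threshold: float = 5.0,
                    seed: int = 0) -> tuple[TrialSet, ICAResult]:
    """Decompose concatenated EEG epochs with FastICA, drop high-kurtosis
    components, and reconstruct.

    Components with excess kurtosis above ``kurtosis_threshold`` are
    treated as artifacts (spike-like, heavy-tailed activity).  With no
    component flagged the reconstruction equals the input to numerical
    tolerance.
    """
    from sklearn.decomposition import FastICA

    n_trials, n_ch, n_samp = ts.eeg.shape
    X = ts.eeg.transpose(1, 0, 2).reshape(n_ch, -1).T   # (time, channels)
    if X.shape[0] < n_ch:
        raise ValueError("fewer samples than channels; cannot run ICA")

    # rank check with names of offending channels
    sd = X.std(axis=0)
    rank = np.linalg.matrix_rank(np.cov(X.T))
    if rank < n_ch:
        flat = [ts.eeg_channel_names[i] for i in np.where(sd < 1e-12)[0]]
        corr = np.corrcoef(X.T)
        dup = [ts.eeg_channel_names[j]
               for i in range(n_ch) for j in range(i + 1, n_ch)
               if abs(corr[i, j]) > 1 - 1e-10]
        bad = sorted(set(flat + dup)) or list(ts.eeg_channel_names)
        raise ValueError(
            f"EEG data are rank deficient (rank {rank} < {n_ch}); "
            f"suspect channels: {bad}")

    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=int(seed), max_iter=1000, tol=1e-3)
    S = ica.fit_transform(X)                      # (time, components)
    scores = kurtosis(S, axis=0, fisher=True)
    rejected = [int(i) for i in np.where(scores > kurtosis_threshold)[0]]

    S_clean = S.copy()
    if rejected:
        S_clean[:, rejected] = 0.0
    X_clean = S_clean @ ica.mixing_.T + ica.mean_
    eeg_clean = X_clean.T.reshape(n_ch, n_trials, n_samp).transpose(1, 0, 2)

    result = ICAResult(mixing=ica.mixing_, unmixing=ica.components_,
                       mean=ica.mean_, scores=scores, rejected=rejected,
                       threshold=kurtosis_threshold)
    logger.info("ICA: %d/%d components rejected (kurtosis > %g)",
                len(rejected), n_ch, kurtosis_threshold)
    return ts.copy_with(eeg=eeg_clean), result


def select_channels(ts: TrialSet, names: list[str] | tuple[str, ...],
                    modality: str = "eeg") -> TrialSet:
    """Reorder/subset one modality's channels to exactly ``names``.

    The requested order is preserved: it defines the feature-image column
    layout downstream.
    """
    have = list(ts.channel_names(modality))
    unknown = [n for n in names if n not in have]
    if unknown:
        raise ValueError(
            f"unknown {modality} channel(s) {unknown}; available: {have}")
    idx = [have.index(n) for n in names]
    x = ts.modality(modality)[:, idx]
    return ts.copy_with(**{modality: x,
                           f"{modality}_channel_names": tuple(names)})
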