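"""Filters, ICA cleanup, and channel selection."""

import numpy as np
import pytest
from scipy.signal import periodogram

from neurofuse.preprocessing import (
    FilterSpec,
    apply_filter,
    filter_array,
    run_ica_cleanup,
    select_channels,
    standard_chain,
)
from neurofuse.simulate import TrialSet

FS = 500.0


def band_power_psd(x, fs, lo, hi):
    f, p = periodogram(x, fs=fs)
    sel = (f >= lo) & (f < hi)
    return p[..., sel].sum(axis=-1) * (f[1] - f[0])


class TestFilters:
    def test_notch_removes_mains(self):
        # steady-state response: judge the central part, away from the
        # filter's startup transient at the record edges
        t = np.arange(2250) / FS
        x = np.sin(2 * np.pi * 60 * t)
        y = filter_array(x, FilterSpec.mains_notch(), FS)[250:-250]
        assert np.sqrt((y ** 2).mean()) < 0.05 * np.sqrt((x ** 2).mean())

    def test_bandpass_rejects_dc(self):
        x = np.full(2250, 7.3)
        y = filter_array(x, FilterSpec.eeg_bandpass(), FS)
        assert abs(y.mean()) < 1e-6

    def test_bandpass_stopband_suppression(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 2250))
        y = filter_array(x, FilterSpec.eeg_bandpass(), FS)
        stop = band_power_psd(y, FS, 45, 250).mean()
        passband = band_power_psd(y, FS, 5, 35).mean()
        assert stop < 0.01 * passband

    def test_edge_at_nyquist_rejected_with_guidance(self):
        spec = FilterSpec("bandpass", (15.0, 250.0))
        with pytest.raises(ValueError, match="cap the edge"):
            spec.validate_for(FS)

    def test_emg_preset_caps_upper_edge(self):
        spec = FilterSpec.emg_bandpass(FS)
        assert spec.band[1] == 249.0

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2250)
        y = rng.standard_normal(2250)
        spec = FilterSpec.eeg_bandpass()
        lhs = filter_array(2.5 * x - 1.3 * y, spec, FS)
        rhs = 2.5 * filter_array(x, spec, FS) - 1.3 * filter_array(y, spec, FS)
        assert np.allclose(lhs, rhs, atol=1e-9 * np.abs(lhs).max())

    def test_apply_filter_preserves_trials_and_labels(self, small_trialset):
        out = apply_filter(small_trialset, FilterSpec.eeg_bandpass(), "eeg")
        assert out.n_trials == small_trialset.n_trials
        assert np.array_equal(out.labels, small_trialset.labels)
        assert np.array_equal(out.emg, small_trialset.emg)  # other modality untouched


class TestICA:
    def test_clean_data_high_threshold_identity(self, small_trialset):
        clean, res = run_ica_cleanup(small_trialset, kurtosis_threshold=50.0,
                                     seed=0)
        assert res.rejected == []
        err = np.abs(clean.eeg - small_trialset.eeg).max()
        assert err < 1e-6 * np.abs(small_trialset.eeg).max()

    def test_infinite_threshold_rejects_nothing(self, small_trialset):
        _, res = run_ica_cleanup(small_trialset, kurtosis_threshold=np.inf)
        assert res.rejected == []

    def test_spike_artifact_component_is_flagged(self, small_trialset):
        eeg = small_trialset.eeg.copy()
        rng = np.random.default_rng(0)
        spikes = np.zeros(eeg.shape[2])
        spikes[rng.choice(eeg.shape[2], 12, replace=False)] = 400.0
        eeg[:, 2, :] += spikes  # channel-localized spike train, huge kurtosis
        dirty = small_trialset.copy_with(eeg=eeg)
        clean, res = run_ica_cleanup(dirty, kurtosis_threshold=5.0, seed=0)
        assert len(res.rejected) >= 1
        # cleanup reduces the spike channel's kurtosis toward the clean data
        from scipy.stats import kurtosis
        k_dirty = kurtosis(dirty.eeg[:, 2, :].ravel())
        k_clean = kurtosis(clean.eeg[:, 2, :].ravel())
        assert k_clean < k_dirty / 2

    def test_rank_deficient_names_channels(self, small_trialset):
        eeg = small_trialset.eeg.copy()
        eeg[:, 1, :] = eeg[:, 0, :]  # duplicate Fc4 := Fc3
        dup = small_trialset.copy_with(eeg=eeg)
        with pytest.raises(ValueError, match="rank deficient"):
            run_ica_cleanup(dup)


class TestChannelSelection:
    def test_requested_order_is_kept(self, small_trialset):
        out = select_channels(small_trialset, ["C4", "Cz", "Fc3"])
        assert out.eeg_channel_names == ("C4", "Cz", "Fc3")
        src = list(small_trialset.eeg_channel_names)
        assert np.array_equal(out.eeg[:, 1], small_trialset.eeg[:, src.index("Cz")])

    def test_identity_selection(self, small_trialset):
        out = select_channels(small_trialset,
                              list(small_trialset.eeg_channel_names))
        assert np.array_equal(out.eeg, small_trialset.eeg)

    def test_unknown_name_lists_available(self, small_trialset):
        with pytest.raises(ValueError, match="Xz.*available"):
            select_channels(small_trialset, ["Xz"])

    def test_nine_channel_montage_from_larger_set(self, small_trialset):
        # simulate a wider montage, then select the nine motor channels
        extra = small_trialset.copy_with(
            eeg=np.concatenate([small_trialset.eeg] * 2, axis=1),
            eeg_channel_names=tuple(small_trialset.eeg_channel_names)
            + tuple(f"X{i}" for i in range(9)))
        nine = ("Fc3", "Fc4", "Cz", "C1", "C2", "C3", "C4", "Cp3", "Cp4")
        out = select_channels(extra, list(nine))
        assert out.eeg.shape[1] == 9
        assert out.eeg_channel_names == nine


class TestChain:
    def test_full_chain_preserves_mu_power(self, small_trialset):
        """notch -> 5-35 Hz -> ICA (nothing rejected) keeps 10-Hz power."""
        out, res = standard_chain(small_trialset, ica_threshold=50.0)
        assert res.rejected == []
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, (9.5, 10.5), btype="bandpass", fs=FS, output="sos")
        p0 = (sosfiltfilt(sos, small_trialset.eeg, axis=-1) ** 2).mean()
        p1 = (sosfiltfilt(sos, out.eeg, axis=-1) ** 2).mean()
        assert p1 / p0 == pytest.approx(1.0, abs=0.1)
        assert np.array_equal(out.labels, small_trialset.labels)
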