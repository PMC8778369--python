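"""ERDS maps: geometry, closed form, scale invariance, bootstrap."""

import numpy as np
import pytest

from neurofuse.simulate import TrialSet
from neurofuse.erds import (
    DegenerateReferenceError,
    ERDSMap,
    ERDSSpec,
    BootstrapSpec,
    _erds_from_powers,
    bootstrap_mask,
    compute_trial_powers,
    erds_map,
    to_grayscale,
)

FS = 500.0
NS = 2250
CUE = 750


def am_noise_trialset(n_trials=40, post_gain=np.sqrt(0.5), seed=0,
                      ramp=150):
    """White-noise EEG whose amplitude is scaled post-cue: every frequency
    bin's power changes by post_gain**2, giving a flat known ERDS level."""
    rng = np.random.default_rng(seed)
    amp = np.ones(NS)
    i = np.arange(ramp)
    amp[CUE:CUE + ramp] = 1 - (1 - post_gain) * 0.5 * (1 - np.cos(np.pi * i / ramp))
    amp[CUE + ramp:] = post_gain
    eeg = rng.standard_normal((n_trials, 9, NS)) * amp
    emg = rng.standard_normal((n_trials, 4, NS))
    return TrialSet(eeg=eeg, emg=emg, labels=np.zeros(n_trials, int),
                    fs=FS, cue_index=CUE)


class TestGeometry:
    def test_preset_bin_counts(self):
        assert ERDSSpec.eeg_preset().n_freq_bins == 31
        assert ERDSSpec.emg_preset().n_freq_bins == 31
        assert ERDSSpec.eeg_preset().n_time_bins == 46

    def test_eeg_map_shape(self, small_trialset):
        m = erds_map(small_trialset, np.arange(5), "C3", ERDSSpec.eeg_preset())
        assert m.values.shape == (46, 31)

    def test_emg_bands_are_contiguous_7hz(self):
        bands = ERDSSpec.emg_preset().freq_bands(FS)
        assert len(bands) == 31
        assert bands[0] == (30.0, 37.0)
        assert bands[-1][0] == 240.0
        assert bands[-1][1] <= FS / 2

    def test_infeasible_sampling_rate_raises(self):
        # at fs=400 the upper EMG bands lie entirely above Nyquist; the
        # preset cannot silently shrink its 31-bin geometry
        with pytest.raises(ValueError, match="Nyquist"):
            ERDSSpec.emg_preset().freq_bands(400.0)

    def test_reference_must_precede_cue(self):
        with pytest.raises(ValueError):
            ERDSSpec(5, 35, 1, reference_interval=(0.0, 0.5))


class TestValues:
    def test_stationary_signal_gives_zero_map(self):
        # a 1-Hz band averaged over n trials has per-bin relative power
        # SD ~ 1.3/sqrt(n); at n=100 that is ~13%, so individual bins
        # wander but the map mean is tight
        ts = am_noise_trialset(n_trials=100, post_gain=1.0, seed=1)
        spec = ERDSSpec.eeg_preset().replace(trials_per_map=100)
        m = erds_map(ts, np.arange(100), "C3", spec)
        assert abs(m.values.mean()) < 3.0
        assert np.abs(m.values).max() < 60.0  # ~4.5 sigma Monte-Carlo bound

    def test_halved_power_reads_minus_fifty(self):
        """Post-cue amplitude x sqrt(0.5): plateau ERDS is -50%.

        Averaged over independent maps to beat the Monte-Carlo wander; the
        tolerance allows the ~2 pp smearing a narrowband filter introduces
        on a finite epoch (the filter's energy spreads over ~1/bandwidth).
        """
        spec = ERDSSpec.eeg_preset().replace(trials_per_map=40)
        plateaus = []
        for seed in range(6):
            ts = am_noise_trialset(post_gain=np.sqrt(0.5), seed=seed)
            m = erds_map(ts, np.arange(40), "C3", spec)
            plateaus.append(m.values[30:39].mean())
        assert np.mean(plateaus) == pytest.approx(-50.0, abs=5.0)

    def test_closed_form_from_constructed_powers(self):
        """(A - R)/R x 100 computed exactly from analytic powers."""
        spec = ERDSSpec.eeg_preset()
        nt, nf = spec.n_time_bins, spec.n_freq_bins
        R = 2.0
        p = np.full((5, nt, nf), R)
        p[:, 23:, :] = R / 2  # activity half the reference, post-cue only
        vals = _erds_from_powers(p, spec, 1e-12)
        assert np.allclose(vals[23:], -50.0, rtol=0.02)
        assert np.allclose(vals[:10], 0.0, atol=1e-9)

    def test_scale_invariance(self, small_trialset):
        spec = ERDSSpec.eeg_preset()
        m1 = erds_map(small_trialset, np.arange(5), "Cz", spec)
        scaled = small_trialset.copy_with(eeg=small_trialset.eeg * 37.5)
        m2 = erds_map(scaled, np.arange(5), "Cz", spec)
        assert np.allclose(m1.values, m2.values, atol=1e-6)

    def test_degenerate_reference_raises(self):
        ts = am_noise_trialset(seed=3)
        ts = ts.copy_with(eeg=np.zeros_like(ts.eeg))
        with pytest.raises(DegenerateReferenceError, match="degenerate"):
            erds_map(ts, np.arange(5), "C3", ERDSSpec.eeg_preset())

    def test_cache_matches_direct_computation(self, small_trialset):
        spec = ERDSSpec.eeg_preset()
        cache = compute_trial_powers(small_trialset, spec, "eeg")
        idx = np.array([0, 2, 4, 6, 8])
        m_direct = erds_map(small_trialset, idx, "C4", spec)
        m_cached = erds_map(small_trialset, idx, "C4", spec, power_cache=cache)
        assert np.allclose(m_direct.values, m_cached.values, rtol=1e-10)

    def test_wrong_trial_count_rejected(self, small_trialset):
        with pytest.raises(ValueError, match="5 trial indices"):
            erds_map(small_trialset, np.arange(4), "C3", ERDSSpec.eeg_preset())


class TestGrayscale:
    @pytest.mark.parametrize("value,expected", [
        (-100.0, 0.0),   # lower clip boundary
        (0.0, 0.5),      # midpoint of a symmetric range
        (250.0, 1.0),    # clipped above
        (100.0, 1.0),
    ])
    def test_symmetric_clip_mapping(self, value, expected):
        g = to_grayscale(np.array([[value]]), clip_range=(-100, 100))
        assert g[0, 0] == pytest.approx(expected)

    def test_invalid_clip_range(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((2, 2)), clip_range=(10, -10))

    def test_nonsignificant_masking(self):
        m = ERDSMap(values=np.full((2, 2), 50.0), times=np.zeros(2),
                    freqs=np.zeros(2), channel="C3",
                    significance=np.array([[True, False], [False, True]]))
        g = to_grayscale(m, clip_range=(-100, 100), mask_nonsignificant=True)
        assert g[0, 1] == 0.0 and g[0, 0] == pytest.approx(0.75)


class TestBootstrap:
    def test_zero_variance_all_significant(self):
        spec = ERDSSpec.eeg_preset().replace(
            bootstrap=BootstrapSpec(True, 200, 0.05))
        nt, nf = spec.n_time_bins, spec.n_freq_bins
        p = np.full((5, nt, nf), 2.0)
        p[:, 23:, :] = 1.0  # identical trials, true ERDS -50% post-cue
        mask = bootstrap_mask(p, spec)
        assert mask[23:].all()
        assert not mask[:10].any()

    def test_alpha_one_nothing_significant(self):
        spec = ERDSSpec.eeg_preset().replace(
            bootstrap=BootstrapSpec(True, 200, 1.0))
        rng = np.random.default_rng(0)
        p = rng.chisquare(5, size=(20, spec.n_time_bins, spec.n_freq_bins))
        assert not bootstrap_mask(p, spec).any()

    def test_too_few_resamples_rejected(self):
        spec = ERDSSpec.eeg_preset().replace(
            bootstrap=BootstrapSpec(True, 10, 0.05))
        with pytest.raises(ValueError, match="meaningless"):
            bootstrap_mask(np.ones((5, 46, 31)), spec)

    def test_erds_map_attaches_mask_when_enabled(self, small_trialset):
        spec = ERDSSpec.eeg_preset().replace(
            bootstrap=BootstrapSpec(True, 50, 0.05))
        m = erds_map(small_trialset, np.arange(5), "C3", spec)
        assert m.significance is not None
        assert m.significance.shape == m.values.shape
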