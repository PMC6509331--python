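"""Filters, bad-channel/sample screening, ICA cleaning, trial rejection, CAR."""

import numpy as np
import pytest
import scipy.signal as sps

from mrcpkit.data import ChannelInfo, EEGRecording, EpochSet
from mrcpkit.preprocessing import (
    bandpass,
    common_average_reference,
    detect_bad_channels,
    fit_ica,
    identify_artifact_ics,
    mark_bad_trials,
    notch,
    remove_ics,
    robust_sample_mask,
)

from conftest import toy_recording

RATE = 256.0


def sine_recording(freqs, n_channels=2, dur=8.0, amp=1.0, dc=0.0, seed=0):
    t = np.arange(int(dur * RATE)) / RATE
    sig = np.stack(
        [amp * np.sin(2 * np.pi * f * t) + dc for f in (freqs * n_channels)[:n_channels]]
    )
    chans = [
        ChannelInfo(name=f"s{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_channels)
    ]
    return EEGRecording(signals=sig, rate=RATE, channels=chans), t


def mid(x, frac=0.25):
    n = len(x)
    return x[int(n * frac) : int(n * (1 - frac))]


class TestBandpass:
    def test_dc_rejected(self):
        rec, _ = sine_recording([0.0], dc=5.0)
        out = bandpass(rec, 0.3, 3.0)
        assert np.abs(mid(out.signals[0])).max() < 5.0 * 10 ** (-60 / 20)

    def test_passband_gain_and_phase(self):
        rec, t = sine_recording([1.0], dur=60.0)
        out = bandpass(rec, 0.3, 3.0, mode="zero_phase")
        y = mid(out.signals[0], 0.4)
        ref = mid(np.sin(2 * np.pi * 1.0 * t), 0.4)
        gain = np.dot(y, ref) / np.dot(ref, ref)
        # analytic two-pass Butterworth magnitude oracle: gain = |H|^2
        sos = sps.butter(4, [0.3, 3.0], btype="bandpass", fs=RATE, output="sos")
        _, h = sps.sosfreqz(sos, worN=[1.0], fs=RATE)
        expect = np.abs(h[0]) ** 2
        assert 0.95 <= expect <= 1.0
        assert gain == pytest.approx(expect, abs=5e-3)
        # zero phase: in-quadrature component vanishes
        quad = mid(np.cos(2 * np.pi * 1.0 * t), 0.4)
        assert abs(np.dot(y, quad) / np.dot(quad, quad)) < 1e-2

    def test_stopband_attenuation_squared_by_two_pass(self):
        rec, _ = sine_recording([10.0], dur=60.0)
        out = bandpass(rec, 0.3, 3.0, mode="zero_phase")
        # steady-state residual in the centre, clear of edge transients
        assert np.abs(mid(out.signals[0], 0.4)).max() < 1e-3

    def test_causal_mode_is_causal(self):
        rec = toy_recording(n_channels=1, n_samples=2048, seed=3)
        rec2 = rec.copy()
        rec2.signals[:, 1024:] += 50.0  # future change
        a = bandpass(rec, 0.3, 3.0, mode="causal")
        b = bandpass(rec2, 0.3, 3.0, mode="causal")
        np.testing.assert_array_equal(a.signals[:, :1024], b.signals[:, :1024])

    def test_causal_steady_state_no_onset_transient(self):
        rec, _ = sine_recording([0.0], dc=3.0)
        out = bandpass(rec, 0.3, 3.0, mode="causal")
        # constant input with steady-state init decays smoothly, never rings
        assert np.abs(out.signals[0, 0]) < 1e-9

    def test_zero_phase_group_delay_is_zero(self):
        rng = np.random.default_rng(0)
        chans = [ChannelInfo(name="x", kind="EEG", position=(0, 0))]
        rec = EEGRecording(
            signals=rng.standard_normal((1, 4096)), rate=RATE, channels=chans
        )
        out = bandpass(rec, 0.3, 30.0)
        xc = np.correlate(out.signals[0], rec.signals[0], mode="full")
        assert np.argmax(xc) == 4095  # zero lag

    def test_invalid_band(self):
        rec, _ = sine_recording([1.0])
        with pytest.raises(ValueError):
            bandpass(rec, 3.0, 0.3)
        with pytest.raises(ValueError):
            bandpass(rec, 0.3, 200.0)


class TestNotch:
    def test_line_frequency_suppressed(self):
        rec, _ = sine_recording([50.0], dur=16.0)
        out = notch(rec, 50.0)
        assert np.sqrt(np.mean(mid(out.signals[0]) ** 2)) < 0.03 * np.sqrt(0.5)

    def test_neighbour_band_preserved(self):
        rec, t = sine_recording([10.0])
        out = notch(rec, 50.0)
        ref = mid(np.sin(2 * np.pi * 10.0 * t))
        gain = np.dot(mid(out.signals[0]), ref) / np.dot(ref, ref)
        assert 0.9 <= gain <= 1.0

    def test_zero_in_zero_out(self):
        rec, _ = sine_recording([1.0], amp=0.0)
        out = notch(rec)
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-12)


class TestBadChannels:
    def _clean_rec(self, names, seed=0):
        rng = np.random.default_rng(seed)
        chans = [
            ChannelInfo(name=n, kind="EEG", position=(float(i), 0.0))
            for i, n in enumerate(names)
        ]
        return EEGRecording(
            signals=rng.standard_normal((len(names), 2048)),
            rate=RATE, channels=chans,
        )

    def test_clean_recording_flags_only_afz(self):
        rec = self._clean_rec(["AFz", "Cz", "C3", "C4", "Pz", "Fz"])
        assert detect_bad_channels(rec) == {"AFz"}

    def test_high_variance_channel_flagged(self):
        rec = self._clean_rec(["AFz", "Cz", "C3", "C4", "Pz", "Fz", "Oz", "F3"])
        rec.signals[3] *= 10.0
        assert detect_bad_channels(rec) == {"AFz", "C4"}

    def test_without_afz_policy_only(self):
        rec = self._clean_rec(["Cz", "C3", "C4", "Pz"])
        assert detect_bad_channels(rec) == set()

    def test_all_bad_is_an_error(self):
        rec = self._clean_rec(["AFz", "Cz"])
        with pytest.raises(RuntimeError):
            detect_bad_channels(rec, default_bad=("AFz", "Cz"))


class TestRobustSampleMask:
    def test_gaussian_keeps_nearly_everything(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 100_000))
        mask = robust_sample_mask(x, k=10.4)
        # 10.4 MAD ~ 7 sd for normal data: essentially no exclusions
        assert mask.mean() > 0.9999

    def test_single_outlier_masked(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (1, 1000))
        x[0, 500] = 100.0
        mask = robust_sample_mask(x)
        assert not mask[0, 500] and mask.sum() >= 999

    def test_constant_channel_kept_entirely(self):
        x = np.full((2, 100), 3.14)
        assert robust_sample_mask(x).all()


def _mixing_rec(n_sources=3, n_channels=8, n=6000, seed=0):
    """Super-Gaussian sources mixed to channels, plus an EOG pair."""
    rng = np.random.default_rng(seed)
    s = rng.laplace(size=(n_sources, n))
    A = rng.standard_normal((n_channels, n_sources))
    chans = [
        ChannelInfo(name=f"e{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_channels)
    ]
    rec = EEGRecording(signals=A @ s, rate=RATE, channels=chans)
    return rec, s, A


class TestICA:
    def test_source_recovery_up_to_permutation_sign(self):
        rec, s, _ = _mixing_rec()
        model = fit_ica(rec, variance_keep=0.999)
        est = model.sources(rec)
        # match each true source to its best-correlated component
        for k in range(s.shape[0]):
            r = [abs(np.corrcoef(s[k], est[j])[0, 1]) for j in range(est.shape[0])]
            assert max(r) > 0.95

    def test_rank_two_input_gives_two_components(self):
        rec, s, _ = _mixing_rec(n_sources=2, n_channels=6)
        model = fit_ica(rec, variance_keep=0.99)
        assert model.n_components == 2

    def test_unmixing_mixing_identity_on_subspace(self):
        rec, _, _ = _mixing_rec()
        model = fit_ica(rec, variance_keep=0.999)
        np.testing.assert_allclose(
            model.unmixing @ model.mixing, np.eye(model.n_components), atol=1e-8
        )

    def test_mask_shields_fit_from_spikes(self):
        rec, s, A = _mixing_rec(seed=2)
        spiky = rec.copy()
        spike_at = np.arange(100, 6000, 500)
        spiky.signals[:, spike_at] += 500.0
        mask = np.ones_like(spiky.signals, dtype=bool)
        mask[:, spike_at] = False
        m_clean = fit_ica(rec, variance_keep=0.999, seed=1)
        m_masked = fit_ica(spiky, variance_keep=0.999, mask=mask, seed=1)
        est_c = m_clean.sources(rec)
        est_m = m_masked.sources(rec)
        # same sources recovered (match by correlation)
        for k in range(est_c.shape[0]):
            r = [abs(np.corrcoef(est_c[k], est_m[j])[0, 1]) for j in range(est_m.shape[0])]
            assert max(r) > 0.95

    def test_too_few_samples_rejected(self):
        rec, _, _ = _mixing_rec(n=6000)
        mask = np.zeros_like(rec.signals, dtype=bool)
        mask[:, :10] = True
        with pytest.raises(ValueError):
            fit_ica(rec, mask=mask)


def _blinky_rec(n=8000, seed=0, blink=True, muscle=False):
    """Low-frequency EEG-like base + optional blink projected to EOG/frontal."""
    rng = np.random.default_rng(seed)
    n_eeg = 8
    # heavy-tailed low-pass base: separable by ICA and not muscle-like
    b_lp, a_lp = sps.butter(4, 12.0, btype="lowpass", fs=RATE)
    base = sps.lfilter(b_lp, a_lp, rng.laplace(size=(n_eeg, n)), axis=1) * 3.0
    t = np.arange(n) / RATE
    blink_tc = np.zeros(n)
    if blink:
        for onset in np.arange(1.0, n / RATE - 1, 2.5):
            sel = (t >= onset) & (t < onset + 0.3)
            blink_tc[sel] += 40 * np.sin(np.pi * (t[sel] - onset) / 0.3) ** 2
    muscle_tc = np.zeros(n)
    if muscle:
        b, a = sps.butter(4, [40, 70], btype="bandpass", fs=RATE)
        muscle_tc = 10 * sps.lfilter(b, a, rng.standard_normal(n))
    frontal_gain = np.linspace(1.0, 0.1, n_eeg)
    sig = base + frontal_gain[:, None] * blink_tc[None, :]
    sig[n_eeg - 1] += muscle_tc
    eog = blink_tc + 0.2 * rng.standard_normal(n)
    chans = [
        ChannelInfo(name=f"f{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_eeg)
    ] + [ChannelInfo(name="EOG1", kind="EOG")]
    rec = EEGRecording(signals=np.vstack([sig, eog[None, :]]), rate=RATE, channels=chans)
    return rec, blink_tc


class TestArtifactICs:
    def test_blink_component_flagged_and_removed(self):
        rec, blink_tc = _blinky_rec()
        model = fit_ica(rec, variance_keep=0.999, max_iter=60)
        flagged = identify_artifact_ics(model, rec)
        assert flagged  # the blink component is found
        src = model.sources(rec)
        best = max(range(src.shape[0]), key=lambda j: abs(np.corrcoef(src[j], blink_tc)[0, 1]))
        assert best in flagged
        cleaned = remove_ics(rec, model, flagged)
        # frontal blink energy drops > 90 %
        sel = blink_tc > 10
        before = np.sqrt(np.mean(rec.signals[0, sel] ** 2))
        after = np.sqrt(np.mean(cleaned.signals[0, sel] ** 2))
        assert after < 0.5 * before

    def test_no_artifacts_flags_nothing(self):
        rec, _ = _blinky_rec(blink=False)
        model = fit_ica(rec, variance_keep=0.999, max_iter=60)
        assert identify_artifact_ics(model, rec) == set()

    def test_broadband_high_frequency_source_flagged_spectrally(self):
        rec, _ = _blinky_rec(blink=False, muscle=True)
        model = fit_ica(rec, variance_keep=0.999, max_iter=60)
        flagged = identify_artifact_ics(model, rec, eog_corr_threshold=1.1)
        assert flagged  # caught by the high/low band-power rule alone

    def test_empty_removal_is_identity(self):
        rec, _ = _blinky_rec(blink=False)
        model = fit_ica(rec, variance_keep=0.999, max_iter=60)
        out = remove_ics(rec, model, set())
        np.testing.assert_array_equal(out.signals, rec.signals)

    def test_removing_all_zeroes_retained_subspace(self):
        rec, _, _ = _mixing_rec(n_sources=3, n_channels=5)
        model = fit_ica(rec, variance_keep=0.9999)
        out = remove_ics(rec, model, set(range(model.n_components)))
        resid = out.signals - out.signals.mean(axis=1, keepdims=True)
        assert np.abs(resid).max() < 1e-6 * np.abs(rec.signals).max()

    def test_bad_index_rejected(self):
        rec, _ = _blinky_rec(blink=False)
        model = fit_ica(rec, variance_keep=0.999, max_iter=60)
        with pytest.raises(ValueError):
            remove_ics(rec, model, {99})


def _epochs(data, rate=RATE, labels=None):
    n_tr, n_ch, _ = data.shape
    chans = [
        ChannelInfo(name=f"c{i}", kind="EEG", position=(float(i), 0.0))
        for i in range(n_ch)
    ]
    return EpochSet(
        data=data, rate=rate, t0_offset=0.0, channels=chans,
        labels=np.array(labels if labels is not None else ["x"] * n_tr, dtype=object),
    )


class TestTrialRejection:
    def test_amplitude_spike_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, (20, 3, 256))
        data[7, 1, 100] = 150.0
        report = mark_bad_trials(_epochs(data))
        assert report.rejected[7] and "amplitude" in report.reasons[7]

    def test_gaussian_null_flag_rate_small(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5, (100, 4, 128))
        report = mark_bad_trials(_epochs(data))
        assert report.n_rejected / 100 < 0.05

    def test_identical_trials_unflagged(self):
        data = np.tile(np.sin(np.linspace(0, 6, 128)), (10, 2, 1))
        report = mark_bad_trials(_epochs(data))
        assert report.n_rejected == 0

    def test_outlier_kurtosis_trial_flagged(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, (40, 3, 256))
        # heavy-tailed trial, amplitude below the 100 uV gate
        data[11] = rng.standard_t(df=1.05, size=(3, 256)).clip(-90, 90) * 0.8
        report = mark_bad_trials(_epochs(data))
        assert report.rejected[11]
        assert report.reasons[11] & {"kurtosis", "joint_probability"}

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            mark_bad_trials(_epochs(np.zeros((2, 2, 10))))


class TestCAR:
    def test_mean_zero_and_idempotent(self, small_offline_session):
        rec, _ = small_offline_session
        out = common_average_reference(rec)
        eeg = out.channel_indices(kind="EEG", good_only=True)
        np.testing.assert_allclose(out.signals[eeg].mean(axis=0), 0.0, atol=1e-9)
        again = common_average_reference(out)
        np.testing.assert_allclose(again.signals, out.signals, atol=1e-9)

    def test_single_channel_deflection_algebra(self):
        m = 5
        chans = [
            ChannelInfo(name=f"c{i}", kind="EEG", position=(float(i), 0.0))
            for i in range(m)
        ]
        sig = np.zeros((m, 10))
        sig[2] = 7.0
        rec = EEGRecording(signals=sig, rate=RATE, channels=chans)
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.signals[2], 7.0 * (m - 1) / m)

    def test_eog_untouched(self):
        chans = [
            ChannelInfo(name="a", kind="EEG", position=(0, 0)),
            ChannelInfo(name="b", kind="EEG", position=(1, 0)),
            ChannelInfo(name="EOG1", kind="EOG"),
        ]
        sig = np.array([[1.0] * 5, [3.0] * 5, [9.0] * 5])
        rec = EEGRecording(signals=sig, rate=RATE, channels=chans)
        out = common_average_reference(rec)
        np.testing.assert_array_equal(out.signals[2], 9.0)

    def test_epochs_variant(self):
        data = np.random.default_rng(0).normal(size=(4, 3, 16))
        out = common_average_reference(_epochs(data))
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
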