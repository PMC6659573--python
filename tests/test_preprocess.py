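"""Filtering, epoching, baseline, artifact flagging, bad channels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from motionerp import (
    Event,
    EventList,
    Recording,
    average_epochs,
    bandpass_eeg,
    baseline_subtract,
    flag_blink_trials,
    manage_bad_channels,
    reject_artifacts,
    segment,
)
from motionerp.errors import MotionErpError, QualityError
from motionerp.preprocess import EpochSet


def make_recording(data, events=(), kinds=None, labels=None):
    n = data.shape[0]
    labels = labels or tuple(f"C{i}" for i in range(n))
    kinds = kinds or ("eeg",) * n
    return Recording(data=data, srate=1000.0, channel_labels=labels,
                     channel_kinds=kinds, events=EventList(list(events)))


def make_epochs(data, window=(-500.0, 1000.0), kinds=None, labels=None):
    n_ch = data.shape[1]
    return EpochSet(
        data=data, srate=1000.0, window=window,
        channel_labels=labels or tuple(f"C{i}" for i in range(n_ch)),
        channel_kinds=kinds or ("eeg",) * n_ch,
    )


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        t = np.arange(20000) / 1000.0
        sig = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(sig[None, :])
        out = bandpass_eeg(rec).data[0][5000:15000]
        ref = sig[5000:15000]
        amp = out.std() / ref.std()
        assert abs(amp - 1.0) < 0.05
        # zero-phase: peak positions unchanged
        lag = np.argmax(np.correlate(out, ref, "full")) - (ref.size - 1)
        assert lag == 0

    def test_dc_removed(self):
        rec = make_recording(np.full((1, 30000), 100.0))
        out = bandpass_eeg(rec).data[0]
        assert abs(out[10000:20000].mean()) < 1.0

    def test_50hz_attenuated_20db(self):
        t = np.arange(20000) / 1000.0
        sig = np.sin(2 * np.pi * 50 * t)
        out = bandpass_eeg(make_recording(sig[None, :])).data[0][5000:15000]
        assert out.std() / np.sqrt(0.5) < 10 ** (-20 / 20)

    def test_high_cutoff_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((1, 1000)))
        with pytest.raises(MotionErpError, match="Nyquist"):
            bandpass_eeg(rec, high=600.0)

    def test_emg_channel_untouched(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 5000))
        rec = make_recording(data, kinds=("eeg", "emg"), labels=("C1", "EMG"))
        out = bandpass_eeg(rec)
        assert np.array_equal(out.data[1], data[1])


class TestSegment:
    def test_80_events_give_80_trials_of_1500_samples(self):
        rng = np.random.default_rng(1)
        events = [Event(1000 + 2000 * i, "stimulus", "fast") for i in range(80)]
        rec = make_recording(rng.normal(size=(2, 163000)), events)
        ep = segment(rec)
        assert ep.data.shape == (80, 2, 1500)
        assert list(ep.trial_ids) == list(range(80))

    def test_edge_event_flagged_not_crashed(self):
        rec = make_recording(np.ones((1, 3000)),
                             [Event(100, "stimulus", "fast"),
                              Event(1500, "stimulus", "fast")])
        ep = segment(rec)
        assert ep.flagged(["edge"]).tolist() == [True, False]

    def test_constant_channel_yields_constant_epochs(self):
        rec = make_recording(np.full((1, 5000), 5.0),
                             [Event(2000, "stimulus", "slow")])
        ep = segment(rec)
        assert np.all(ep.data == 5.0)


class TestBaseline:
    def test_baseline_mean_zero_after(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.normal(3.2, 1.0, (4, 2, 1500)))
        out = baseline_subtract(ep)
        sl = out.sample_range((-500.0, 0.0))
        assert np.allclose(out.data[:, :, sl].mean(axis=2), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.normal(size=(2, 1, 1500)))
        once = baseline_subtract(ep)
        twice = baseline_subtract(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_ramp_mean_removed_matches_closed_form(self):
        # linear ramp crossing zero at -250 ms: baseline mean is the ramp's
        # value at the window midpoint
        t = np.arange(-500, 1000, dtype=float)
        ramp = 0.1 * (t + 250.0)
        ep = make_epochs(ramp[None, None, :])
        out = baseline_subtract(ep)
        expected_mean = 0.1 * (np.arange(-500, 0) + 250.0).mean()
        assert np.allclose(ep.data - out.data, expected_mean)

    def test_window_outside_epoch_raises(self):
        ep = make_epochs(np.zeros((1, 1, 1500)))
        with pytest.raises(MotionErpError):
            baseline_subtract(ep, (-700.0, 0.0))


class TestBlinkFlagging:
    def _epochs_with_blink(self, at_ms):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 5, (3, 2, 1500))
        t = np.arange(-500, 1000)
        blink = 150.0 * np.exp(-0.5 * ((t - at_ms) / 40.0) ** 2)
        data[0, 1] += blink
        return make_epochs(data, kinds=("eeg", "eog"), labels=("C0", "EOG"))

    def test_blink_inside_interval_flagged(self):
        ep = flag_blink_trials(self._epochs_with_blink(-100.0))
        assert ep.flagged(["blink"]).tolist() == [True, False, False]

    def test_blink_after_200ms_not_flagged(self):
        ep = flag_blink_trials(self._epochs_with_blink(400.0))
        assert not ep.flagged(["blink"]).any()

    def test_quiet_eog_no_flags(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.normal(0, 5, (4, 2, 1500)),
                         kinds=("eeg", "eog"), labels=("C0", "EOG"))
        assert not flag_blink_trials(ep).flagged(["blink"]).any()

    def test_missing_eog_raises(self):
        ep = make_epochs(np.zeros((1, 1, 1500)))
        with pytest.raises(MotionErpError, match="EOG"):
            flag_blink_trials(ep)


class TestArtifactRejection:
    def _quiet(self, n_trials=3, n_ch=2):
        return np.zeros((n_trials, n_ch, 1500))

    def test_step_over_50uv_flagged(self):
        data = self._quiet()
        data[0, 0, 600:] += 60.0          # jump at +100 ms
        ep, rep = reject_artifacts(make_epochs(data))
        assert ep.flagged(["eeg_artifact"]).tolist() == [True, False, False]

    def test_amplitude_over_150uv_flagged(self):
        data = self._quiet()
        t = np.arange(-500, 1000)
        data[1, 1] += 160.0 * np.exp(-0.5 * ((t - 450) / 30.0) ** 2)
        ep, _ = reject_artifacts(make_epochs(data))
        assert ep.flagged(["eeg_artifact"]).tolist() == [False, True, False]

    def test_excursion_outside_interval_ignored(self):
        data = self._quiet()
        t = np.arange(-500, 1000)
        data[0, 0] += 160.0 * np.exp(-0.5 * ((t - 800) / 20.0) ** 2)
        # keep the rise slower than the step criterion
        assert np.abs(np.diff(data[0, 0])).max() < 50
        ep, _ = reject_artifacts(make_epochs(data))
        assert not ep.flagged(["eeg_artifact"]).any()

    def test_rejection_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 60, (12, 3, 1500))
        loose, _ = reject_artifacts(make_epochs(data), amp_thresh=200.0,
                                    step_thresh=80.0)
        tight, _ = reject_artifacts(make_epochs(data), amp_thresh=150.0,
                                    step_thresh=50.0)
        assert set(np.nonzero(loose.flagged())[0]) <= set(
            np.nonzero(tight.flagged())[0])

    def test_commutes_with_blink_flagging(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 5, (6, 3, 1500))
        data[2, 0, 700:] += 90.0
        data[4, 2] += 200.0 * np.exp(
            -0.5 * ((np.arange(-500, 1000) + 100) / 40.0) ** 2)
        ep = make_epochs(data, kinds=("eeg", "eeg", "eog"),
                         labels=("C0", "C1", "EOG"))
        a = reject_artifacts(flag_blink_trials(ep))[0]
        b = flag_blink_trials(reject_artifacts(ep)[0])
        assert a.flags == b.flags


class TestBadChannels:
    def test_bad_channel_interpolated_and_fraction_reset(self, montage):
        rng = np.random.default_rng(8)
        labels = montage.labels
        data = rng.normal(0, 5, (10, 63, 1500))
        data[:3, 5, :] = 500.0             # one channel artifactual in 30%
        ep = make_epochs(data, labels=labels)
        ep, rep = reject_artifacts(ep)
        fixed, rep2 = manage_bad_channels(ep, rep, montage)
        assert rep2.excluded_channels == [labels[5]]
        assert rep2.channel_fraction[labels[5]] == 0.0
        assert not fixed.flagged().any()

    def test_spatially_constant_map_reproduced(self, montage):
        data = np.full((4, 63, 100), 7.0)
        data[:, 10, :] = 9000.0
        ep = EpochSet(data=data, srate=1000.0, window=(0.0, 100.0),
                      channel_labels=montage.labels,
                      channel_kinds=("eeg",) * 63)
        ep2, rep = reject_artifacts(ep, interval=(0.0, 100.0))
        fixed, _ = manage_bad_channels(ep2, rep, montage,
                                       reject_kwargs={"interval": (0.0, 100.0)})
        assert np.allclose(fixed.data[:, 10, :], 7.0, atol=1e-6)

    def test_no_bad_channels_identity(self, montage):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 5, (5, 63, 200))
        ep = EpochSet(data=data, srate=1000.0, window=(0.0, 200.0),
                      channel_labels=montage.labels,
                      channel_kinds=("eeg",) * 63)
        ep2, rep = reject_artifacts(ep, interval=(0.0, 200.0))
        fixed, _ = manage_bad_channels(ep2, rep, montage)
        assert np.array_equal(fixed.data, ep2.data)

    def test_too_many_bad_channels_hard_error(self, montage):
        data = np.zeros((4, 63, 100))
        data[:, :20, :] = 400.0
        ep = EpochSet(data=data, srate=1000.0, window=(0.0, 100.0),
                      channel_labels=montage.labels,
                      channel_kinds=("eeg",) * 63)
        ep2, rep = reject_artifacts(ep, interval=(0.0, 100.0))
        with pytest.raises(QualityError, match="20%"):
            manage_bad_channels(ep2, rep, montage)


class TestAveraging:
    def test_divisor_is_included_count(self):
        data = np.ones((10, 1, 1500))
        ep = make_epochs(data)
        for t in (0, 3, 7):
            ep.add_flag(t, "eeg_artifact")
        avg, n = average_epochs(ep)
        assert n == 7
        assert np.allclose(avg, 1.0)

    def test_alternating_trials_cancel(self):
        data = np.ones((8, 1, 1500))
        data[1::2] = -1.0
        avg, n = average_epochs(make_epochs(data))
        assert n == 8
        assert np.allclose(avg, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_linear_in_trial_data(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 2, 30))
        b = rng.normal(size=(5, 2, 30))
        ep = lambda d: EpochSet(data=d, srate=1000.0, window=(0.0, 30.0),
                                channel_labels=("C0", "C1"),
                                channel_kinds=("eeg", "eeg"))
        avg_sum, _ = average_epochs(ep(a + 2 * b))
        avg_a, _ = average_epochs(ep(a))
        avg_b, _ = average_epochs(ep(b))
        assert np.allclose(avg_sum, avg_a + 2 * avg_b, atol=1e-12)
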