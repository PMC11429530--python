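import numpy as np
import pandas as pd
import pytest

from gonogo import montage, preprocess
from gonogo.errors import (
    FormatError,
    InvalidConfigError,
    InvalidInputError,
    UnsupportedOperationError,
)
from gonogo.io_core.containers import Recording

from conftest import ALL_CHANNELS, make_epochs

FS = 512.0


def _sine_recording(freq, fs=FS, seconds=60, amplitude=1.0):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t), (23, 1))
    return Recording(data, fs, ALL_CHANNELS), t


def _projected_amplitude(x, t, freq):
    a = 2 * np.mean(x * np.sin(2 * np.pi * freq * t))
    b = 2 * np.mean(x * np.cos(2 * np.pi * freq * t))
    return np.hypot(a, b), np.degrees(np.arctan2(b, a))


class TestBandpass:
    def test_passband_amplitude_and_phase(self):
        rec, t = _sine_recording(15.0)
        out = preprocess.bandpass_zero_phase(rec)
        mid = slice(int(20 * FS), int(40 * FS))
        amp, phase = _projected_amplitude(out.data[0, mid], t[mid], 15.0)
        assert amp == pytest.approx(1.0, rel=0.01)
        assert abs(phase) < 0.5

    def test_stopband_attenuation(self):
        rec, t = _sine_recording(60.0)
        out = preprocess.bandpass_zero_phase(rec)
        mid = slice(int(20 * FS), int(40 * FS))
        amp, _ = _projected_amplitude(out.data[0, mid], t[mid], 60.0)
        assert 20 * np.log10(amp) < -20

    def test_dc_removed(self):
        rec = Recording(np.full((23, int(30 * FS)), 100.0), FS, ALL_CHANNELS)
        out = preprocess.bandpass_zero_phase(rec)
        mid = slice(int(10 * FS), int(20 * FS))
        assert np.abs(out.data[0, mid]).max() < 1.0

    def test_invalid_band_rejected(self):
        rec, _ = _sine_recording(10.0, seconds=2)
        with pytest.raises(InvalidConfigError):
            preprocess.bandpass_zero_phase(rec, 30.0, 0.1)


class TestReref:
    def _rec_with_ears(self, ear_values):
        names = ALL_CHANNELS + ["A1", "A2"][: len(ear_values)]
        data = np.ones((len(names), 100))
        for i, v in enumerate(ear_values, start=23):
            data[i] = v
        return Recording(data, FS, names)

    def test_zero_ears_identity(self):
        rec = self._rec_with_ears([0.0, 0.0])
        out = preprocess.reref_linked_ears(rec, ["A1", "A2"])
        np.testing.assert_array_equal(out.data[rec.eeg_index],
                                      rec.data[rec.eeg_index])

    def test_constant_ears_shift(self):
        rec = self._rec_with_ears([3.0, 3.0])
        out = preprocess.reref_linked_ears(rec, ["A1", "A2"])
        np.testing.assert_allclose(out.data[rec.eeg_index], 1.0 - 3.0)

    def test_online_left_ear_half_subtraction(self):
        rec = self._rec_with_ears([4.0])
        out = preprocess.reref_linked_ears(rec, ["A1"])
        np.testing.assert_allclose(out.data[rec.eeg_index], 1.0 - 2.0)

    def test_missing_ear_channel(self):
        rec = self._rec_with_ears([0.0])
        with pytest.raises(FormatError):
            preprocess.reref_linked_ears(rec, ["A2"])


class TestResample:
    def test_downsample_preserves_amplitude(self):
        t = np.arange(int(30 * 1000)) / 1000.0
        rec = Recording(np.tile(np.sin(2 * np.pi * 10 * t), (23, 1)), 1000.0,
                        ALL_CHANNELS)
        out = preprocess.resample(rec, 512.0)
        assert out.fs == 512.0
        tr = np.arange(out.n_samples) / 512.0
        mid = slice(int(10 * 512), int(20 * 512))
        amp, _ = _projected_amplitude(out.data[0, mid], tr[mid], 10.0)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_identity_when_target_equals_source(self, quiet_recording):
        out = preprocess.resample(quiet_recording, 512.0)
        np.testing.assert_array_equal(out.data, quiet_recording.data)

    def test_event_index_rescaled(self):
        ev = pd.DataFrame({"onset_sample": [1000], "condition": ["Go"], "block": [0]})
        rec = Recording(np.zeros((23, 5000)), 1000.0, ALL_CHANNELS, events=ev)
        out = preprocess.resample(rec, 512.0)
        assert abs(out.events["onset_sample"].iloc[0] - 512) <= 1

    def test_upsampling_unsupported(self, quiet_recording):
        with pytest.raises(UnsupportedOperationError):
            preprocess.resample(quiet_recording, 1000.0)


class TestExtractEpochs:
    def test_epoch_grid_convention(self):
        first, last = preprocess.epoch_sample_range(512.0, (-500.0, 600.0))
        assert (first, last) == (-256, 307)
        assert last - first + 1 == 564

    def test_count_echo_and_t0(self, quiet_recording):
        epochs = preprocess.extract_epochs(quiet_recording)
        # events 1 and 3 are valid Go (pressed in window), event 2 valid NoGo
        assert epochs.n_trials == 3
        assert epochs.t0_index == 256
        assert epochs.n_samples == 564

    def test_edge_event_dropped(self, rng):
        data = rng.standard_normal((23, 2000))
        ev = pd.DataFrame({"onset_sample": [100], "condition": ["NoGo"], "block": [0]})
        rec = Recording(data, FS, ALL_CHANNELS, events=ev)
        epochs = preprocess.extract_epochs(rec)
        assert epochs.n_trials == 0

    def test_error_trials_are_not_epoched(self, rng):
        data = rng.standard_normal((23, int(20 * FS)))
        ev = pd.DataFrame({"onset_sample": [4096, 4096 + 563],
                           "condition": ["Go", "Go"], "block": [0, 0]})
        rp = pd.DataFrame({"press_sample": [4096 + 20]})  # fast RT error
        rec = Recording(data, FS, ALL_CHANNELS, ev, rp)
        epochs = preprocess.extract_epochs(rec)
        assert epochs.n_trials == 0


class TestEmcp:
    def _contaminated(self, rng, coeff=0.4, n_trials=100, eeg_sd=1.0):
        n_s = 564
        eeg = eeg_sd * rng.standard_normal((n_trials, 19, n_s))
        eog = 3.0 * rng.standard_normal((n_trials, 4, n_s))
        wave = 150 * np.hanning(128)
        blink_mask = np.zeros((n_trials, n_s), dtype=bool)
        for tr in range(0, n_trials, 2):
            s = rng.integers(0, n_s - 128)
            eog[tr, 0, s: s + 128] += wave * rng.uniform(0.7, 1.3)
            blink_mask[tr, s: s + 128] = True
        prop = np.zeros((4, 19))
        prop[0, 0] = coeff  # VEOGU -> Fp1
        contaminated = eeg + np.einsum("ec,tes->tcs", prop, eog)
        data = np.concatenate([contaminated, eog], axis=1)
        epochs = make_epochs(data)
        return epochs, contaminated, blink_mask

    def test_planted_coefficient_recovered(self, rng):
        epochs, contaminated, blink_mask = self._contaminated(rng)
        out, model = preprocess.emcp_correct(epochs)
        assert model.blink_coefficients[0, 0] == pytest.approx(0.4, abs=0.02)
        pre = np.abs(contaminated[:, 0, :][blink_mask]).mean()
        post = np.abs(out.data[:, 0, :][blink_mask]).mean()
        assert post < 0.1 * pre

    def test_null_coefficients_near_zero(self, rng):
        epochs, _, _ = self._contaminated(rng, coeff=0.0)
        _, model = preprocess.emcp_correct(epochs)
        assert np.abs(model.blink_coefficients).max() < 0.02
        assert np.abs(model.saccade_coefficients).max() < 0.02

    def test_zero_eog_identity(self, rng):
        data = rng.standard_normal((10, 23, 564))
        data[:, 19:] = 0.0
        epochs = make_epochs(data)
        out, model = preprocess.emcp_correct(epochs)
        np.testing.assert_array_equal(out.data, epochs.data)
        assert np.all(model.blink_coefficients == 0)


class TestInterpolation:
    def test_smooth_field_reconstruction(self):
        pos = montage.positions()
        center = pos[montage.EEG_CHANNELS.index("Cz")]
        field = 5 * np.exp(-0.5 * (np.arccos(np.clip(pos @ center, -1, 1)) / 1.0) ** 2)
        data = np.broadcast_to(field[None, :, None], (1, 19, 20)).copy()
        epochs = make_epochs(data, channel_names=montage.EEG_CHANNELS, t0=10,
                             conditions=["Go"])
        out = preprocess.interpolate_channels(epochs, ["P3"])
        i = montage.EEG_CHANNELS.index("P3")
        err = np.abs(out.data[0, i] - field[i]).max()
        assert err < 0.1 * np.sqrt((field ** 2).mean())

    def test_empty_bad_list_identity(self, rng):
        epochs = make_epochs(rng.standard_normal((2, 23, 30)), t0=10)
        out = preprocess.interpolate_channels(epochs, [])
        np.testing.assert_array_equal(out.data, epochs.data)

    def test_four_bad_channels_hard_error(self, rng):
        epochs = make_epochs(rng.standard_normal((1, 23, 30)), t0=10,
                             conditions=["Go"])
        with pytest.raises(InvalidInputError):
            preprocess.interpolate_channels(epochs, ["Fp1", "Fp2", "F3", "F4"])


class TestBaseline:
    def test_constant_trial_zeroed(self):
        epochs = make_epochs(np.full((2, 23, 564), 10.0))
        out = preprocess.baseline_correct(epochs)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self, rng):
        epochs = make_epochs(rng.standard_normal((4, 23, 564)))
        out = preprocess.baseline_correct(epochs)
        times = out.times_ms
        mask = (times >= -100) & (times < 0)
        np.testing.assert_allclose(out.data[:, :, mask].mean(axis=2), 0.0,
                                   atol=1e-12)

    def test_linear_ramp(self):
        ramp = np.linspace(0, 10, 564)
        epochs = make_epochs(np.broadcast_to(ramp, (1, 23, 564)).copy(),
                             conditions=["Go"])
        out = preprocess.baseline_correct(epochs)
        times = epochs.times_ms
        mask = (times >= -100) & (times < 0)
        np.testing.assert_allclose(out.data[0, 0], ramp - ramp[mask].mean(),
                                   atol=1e-12)

    def test_window_outside_epoch_rejected(self, rng):
        epochs = make_epochs(rng.standard_normal((1, 23, 50)), t0=10,
                             conditions=["Go"])
        with pytest.raises(InvalidConfigError):
            preprocess.baseline_correct(epochs, (-2000.0, -1500.0))


class TestArtifactReject:
    def _clean(self, rng, n=4):
        t = np.arange(564) / 512.0
        data = 20 * np.sin(2 * np.pi * 7 * t) + rng.standard_normal((n, 23, 564))
        return data

    def test_extreme_spike_rejected(self, rng):
        data = self._clean(rng)
        data[1, 3, 100] = 151.0
        out = preprocess.artifact_reject_auto(make_epochs(data))
        assert not out.accepted[1] and out.reason[1] == "extreme"

    def test_voltage_jump_rejected(self, rng):
        data = self._clean(rng)
        data[2, 5, 300:] += 60.0
        out = preprocess.artifact_reject_auto(make_epochs(data))
        assert not out.accepted[2] and out.reason[2] == "jump"

    def test_flatline_rejected(self, rng):
        data = self._clean(rng)
        data[3, 7, :] = 5.0
        out = preprocess.artifact_reject_auto(make_epochs(data))
        assert not out.accepted[3] and out.reason[3] == "flat"

    def test_clean_epoch_accepted(self, rng):
        out = preprocess.artifact_reject_auto(make_epochs(self._clean(rng)))
        assert out.accepted.all()

    def test_strict_inequality_at_threshold(self, rng):
        data = self._clean(rng) * 0
        # slow ramp peaking exactly at the threshold: no jump, not flat,
        # |v| reaches 150.0 but never exceeds it -> kept (strict ">")
        data += np.linspace(0.0, 150.0, 564)
        out = preprocess.artifact_reject_auto(make_epochs(data))
        assert out.accepted.all()

    def test_rejection_monotone_in_thresholds(self, rng):
        data = self._clean(rng, n=12)
        data += 100 * rng.standard_normal((12, 1, 1))
        tight = preprocess.RejectionThresholds(extreme_abs=80, jump=30,
                                               flat_delta=0.05)
        loose = preprocess.RejectionThresholds(extreme_abs=160, jump=60,
                                               flat_delta=0.01)
        out_tight = preprocess.artifact_reject_auto(make_epochs(data), tight)
        out_loose = preprocess.artifact_reject_auto(make_epochs(data), loose)
        # loosening thresholds never rejects a previously accepted trial
        assert np.all(out_loose.accepted >= out_tight.accepted)


class TestPrestimReject:
    def _epochs(self, onsets):
        data = np.zeros((len(onsets), 23, 564))
        return make_epochs(data, onset_sample=np.array(onsets),
                           conditions=["Go"] * len(onsets))

    def test_press_in_prestim_rejected(self):
        epochs = self._epochs([1000])
        responses = pd.DataFrame({"press_sample": [1000 - 100]})  # ~-200 ms
        out = preprocess.reject_prestim_response(epochs, responses)
        assert not out.accepted[0] and out.reason[0] == "prestim_press"

    def test_no_prestim_press_identity(self):
        epochs = self._epochs([1000, 2000])
        responses = pd.DataFrame({"press_sample": [1200, 2300]})
        out = preprocess.reject_prestim_response(epochs, responses)
        assert out.accepted.all()

    def test_press_exactly_at_onset_retained(self):
        epochs = self._epochs([1000])
        responses = pd.DataFrame({"press_sample": [1000]})
        out = preprocess.reject_prestim_response(epochs, responses)
        assert out.accepted[0]

    def test_press_at_window_start_rejected(self):
        epochs = self._epochs([1000])
        responses = pd.DataFrame({"press_sample": [1000 - 256]})
        out = preprocess.reject_prestim_response(epochs, responses)
        assert not out.accepted[0]


class TestMatch:
    def _epochs(self, n_go, n_nogo):
        n = n_go + n_nogo
        return make_epochs(np.zeros((n, 23, 10)), t0=5,
                           conditions=["Go"] * n_go + ["NoGo"] * n_nogo)

    def test_61_68_matches_to_61(self):
        out = preprocess.match_trial_counts(self._epochs(61, 68), seed=0)
        assert int(out.accepted_mask("Go").sum()) == 61
        assert int(out.accepted_mask("NoGo").sum()) == 61
        assert (out.reason[~out.accepted] == "match_surplus").all()

    def test_equal_counts_identity(self):
        out = preprocess.match_trial_counts(self._epochs(40, 40), seed=0)
        assert out.accepted.all()

    def test_seed_determinism(self):
        a = preprocess.match_trial_counts(self._epochs(50, 70), seed=9)
        b = preprocess.match_trial_counts(self._epochs(50, 70), seed=9)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_empty_condition_hard_error(self):
        with pytest.raises(InvalidInputError):
            preprocess.match_trial_counts(self._epochs(0, 10), seed=0)
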