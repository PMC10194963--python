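"""EEG preprocessing, epoching/rejection, ROI averaging, event filtering,
and container round-trips."""

import numpy as np
import pytest

from okninfo import syndata
from okninfo.core_io import (
    ROI_CHANNELS,
    EpochCriteria,
    Recording,
    RoiDefinition,
    epoch_and_reject,
    filter_switch_events,
    load_session,
    preprocess,
    read_events_tsv,
    read_eye_samples,
    read_eyelink_events,
    reject_channels,
    roi_average,
    save_session,
    write_events_tsv,
)
from okninfo.okn import SwitchEvent


def _recording(data, rate=512.0):
    names = [f"CH{i}" for i in range(data.shape[0])]
    return Recording(data=data, rate=rate, ch_names=names)


class TestPreprocess:
    def test_dc_offset_removed(self):
        data = np.full((8, 4096), 40.0)
        out = preprocess(_recording(data))
        assert np.abs(out.data[:, 200:-200].mean()) < 0.01 * 40.0

    def test_50hz_notch_attenuation(self):
        t = np.arange(8192) / 512.0
        sine = np.sin(2 * np.pi * 50.0 * t)
        data = np.tile(sine, (8, 1))
        data[0] += np.sin(2 * np.pi * 7.0 * t)  # keep avg-ref from nulling
        out = preprocess(_recording(data))
        # channel 0 retains the 7 Hz tone after average reference; isolate 50 Hz
        from scipy.signal import welch

        f, p = welch(out.data[0], fs=250.0, nperseg=1024)
        p50 = p[np.argmin(np.abs(f - 50.0))]
        p7 = p[np.argmin(np.abs(f - 7.0))]
        assert 10 * np.log10(p7 / max(p50, 1e-20)) > 20.0

    def test_average_reference(self):
        rng = np.random.default_rng(0)
        out = preprocess(_recording(rng.normal(size=(8, 4096))))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_resampled_rate(self):
        rng = np.random.default_rng(1)
        out = preprocess(_recording(rng.normal(size=(8, 5120)), rate=512.0))
        assert out.rate == 250.0
        assert out.data.shape[1] == 2500


class TestRejectChannels:
    def test_identical_channels_none_flagged(self):
        data = np.tile(np.random.default_rng(2).normal(size=2000), (10, 1))
        keep, drop = reject_channels(_recording(data))
        assert drop == []

    def test_scaled_channel_flagged(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(12, 2000))
        data[4] *= 10.0
        _, drop = reject_channels(_recording(data))
        assert drop == ["CH4"]

    def test_flags_invariant_to_order(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(12, 2000))
        data[4] *= 10.0
        rec = _recording(data)
        perm = rng.permutation(12)
        rec2 = Recording(data=data[perm], rate=512.0,
                         ch_names=[rec.ch_names[i] for i in perm])
        assert set(reject_channels(rec)[1]) == set(reject_channels(rec2)[1])

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            reject_channels(_recording(np.zeros((4, 100))))


class TestFilterSwitchEvents:
    def _ev(self, times, dirs=None):
        if dirs is None:
            dirs = ["to_INT" if i % 2 == 0 else "to_DIF" for i in range(len(times))]
        return [SwitchEvent(t, d, "button") for t, d in zip(times, dirs)]

    def test_min_interval_rule(self):
        kept, log = filter_switch_events(self._ev([0.0, 1.5, 5.0, 9.0]))
        assert [e.time for e in kept] == [0.0, 5.0, 9.0]
        assert log["min_inter_switch"] == 1

    def test_repetition_rule(self):
        ev = self._ev([0.0, 5.0], ["to_INT", "to_INT"])
        kept, log = filter_switch_events(ev)
        assert [e.time for e in kept] == [0.0]
        assert log["repetition"] == 1

    def test_multiple_response_rule(self):
        # event at 10.0 has another response 0.3 s after it (inside +0.5 s)
        ev = self._ev([5.0, 10.0, 10.3], ["to_INT", "to_DIF", "to_INT"])
        kept, log = filter_switch_events(ev)
        times = [e.time for e in kept]
        assert 10.0 not in times
        assert log["multiple_responses"] >= 1

    def test_counts_conserved(self, clean_session):
        kept, log = filter_switch_events(clean_session.switch_events)
        assert log["retained"] + log["min_inter_switch"] + log["repetition"] + log[
            "multiple_responses"
        ] == log["total"]

    def test_retained_events_have_clean_history(self, clean_session):
        """Every retained switch has >= 2 s of single-percept history, so no
        previous switch falls inside the 2000-ms pre-window."""
        kept, _ = filter_switch_events(clean_session.switch_events)
        all_times = np.array([e.time for e in clean_session.switch_events])
        for e in kept:
            before = all_times[(all_times < e.time) & (all_times > e.time - 2.0)]
            assert before.size == 0


class TestEpochAndReject:
    def _events(self, times):
        return [SwitchEvent(t, "to_INT" if i % 2 == 0 else "to_DIF", "button")
                for i, t in enumerate(times)]

    def test_all_zero_recording_no_rejections(self):
        rec = _recording(np.zeros((4, 2500)), rate=250.0)
        eps = epoch_and_reject(rec, self._events([3.0, 6.0]))
        assert eps.n_epochs == 2
        assert eps.rejection_log["amplitude"] == 0
        assert eps.rejection_log["slope"] == 0
        assert eps.data.shape[2] == 625  # -2000..+500 ms at 250 Hz

    def test_amplitude_rejection(self):
        data = np.zeros((4, 2500))
        data[2, 900] = 200.0  # single 200 uV sample inside the first epoch
        rec = _recording(data, rate=250.0)
        eps = epoch_and_reject(rec, self._events([4.0, 8.0]))
        assert eps.rejection_log["amplitude"] == 1
        assert eps.n_epochs == 1

    @pytest.mark.parametrize("rise,kept", [(80.0, 0), (40.0, 1)])
    def test_slope_rejection_threshold(self, rise, kept):
        n = 2500
        data = np.zeros((4, n))
        # linear drift of `rise` uV across the -2..+0.5 s epoch around t=4 s
        i0, i1 = int(2.0 * 250), int(4.5 * 250)
        data[1, i0:i1] = np.linspace(0.0, rise, i1 - i0)
        rec = _recording(data, rate=250.0)
        eps = epoch_and_reject(rec, self._events([4.0]))
        assert eps.n_epochs == kept

    def test_edge_event_skipped_and_logged(self):
        rec = _recording(np.zeros((4, 1000)), rate=250.0)
        eps = epoch_and_reject(rec, self._events([0.5]))
        assert eps.n_epochs == 0
        assert eps.rejection_log["skipped_edge"] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        rec = _recording(rng.normal(0, 60, (4, 25000)), rate=250.0)
        events = self._events(np.arange(3.0, 95.0, 4.0))
        eps = epoch_and_reject(rec, events)
        log = eps.rejection_log
        assert log["retained"] + log["amplitude"] + log["slope"] + log["skipped_edge"] == log["total"]


class TestRoiAverage:
    def _epochs(self, data, ch_names):
        from okninfo.core_io import EpochSet

        return EpochSet(
            data=data, times=np.arange(data.shape[2]) * 4.0, rate=250.0,
            ch_names=ch_names, labels=["to_INT"] * data.shape[0],
            lock_times=np.zeros(data.shape[0]),
        )

    def test_identical_channels_identity(self):
        chans = list(ROI_CHANNELS["front"])
        row = np.random.default_rng(6).normal(size=50)
        data = np.tile(row, (3, 6, 1))
        out = roi_average(self._epochs(data, chans), "front")
        np.testing.assert_allclose(out.values, np.tile(row, (3, 1)))

    def test_opposite_channels_cancel(self):
        roi = RoiDefinition(name="pair", channels=("A", "B"))
        v = np.random.default_rng(7).normal(size=(2, 1, 30))
        data = np.concatenate([v, -v], axis=1)
        out = roi_average(self._epochs(data, ["A", "B"]), roi)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_front_roi_has_six_channels(self):
        assert len(ROI_CHANNELS["front"]) == 6
        assert all(len(v) == 6 for v in ROI_CHANNELS.values())
        all_ch = sum(ROI_CHANNELS.values(), [])
        assert len(all_ch) == len(set(all_ch))  # disjoint ROIs

    def test_missing_channel_named_in_error(self):
        data = np.zeros((2, 2, 10))
        with pytest.raises(KeyError, match="AF3"):
            roi_average(self._epochs(data, ["X1", "X2"]), "front")


class TestContainerRoundTrip:
    def test_hdf5_bit_exact(self, tmp_path, clean_session):
        path = tmp_path / "session.h5"
        save_session(path, clean_session)
        back = load_session(path)
        np.testing.assert_array_equal(
            np.nan_to_num(back.okn.samples), np.nan_to_num(clean_session.okn.samples)
        )
        np.testing.assert_array_equal(back.eeg.data, clean_session.eeg.data)
        assert back.eeg.ch_names == clean_session.eeg.ch_names
        assert back.switch_events == clean_session.switch_events
        assert back.button_events == clean_session.button_events
        np.testing.assert_array_equal(
            back.ground_truth.schedule.switch_times,
            clean_session.ground_truth.schedule.switch_times,
        )
        assert back.ground_truth.schedule.percepts == clean_session.ground_truth.schedule.percepts

    def test_events_tsv_round_trip(self, tmp_path):
        events = [
            SwitchEvent(1.25, "to_INT", "button"),
            SwitchEvent(3.5, "to_DIF", "okn_crossing"),
        ]
        path = tmp_path / "events.tsv"
        write_events_tsv(path, events)
        assert read_events_tsv(path) == events


class TestEyeText:
    def test_read_samples_with_missing(self, tmp_path):
        path = tmp_path / "samples.asc"
        path.write_text(
            "MSG 100 start\n"
            "1000\t512.1\t384.0\t900\n"
            "1002\t.\t.\t0\n"
            "1004\t513.0\t384.2\t901\n"
        )
        tr = read_eye_samples(path, column=1)
        assert tr.samples.size == 3
        assert np.isnan(tr.samples[1])
        assert tr.samples[0] == pytest.approx(512.1)

    def test_read_eyelink_events(self, tmp_path):
        path = tmp_path / "events.asc"
        path.write_text(
            "EBLINK R 1000 1200\n"
            "ESACC R 1500 1540 40 1 2 3 4\n"
        )
        ev = read_eyelink_events(path)
        assert ev["blink"] == [(1.0, 1.2)]
        assert ev["saccade"] == [(1.5, 1.54)]
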