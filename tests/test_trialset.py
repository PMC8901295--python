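"""Trial container invariants, montage selection, file round trips, filtering."""

import dataclasses

import numpy as np
import pytest

from dtfnet import Montage, TrialSet, bandpass, epoch_continuous, load_trialset, save_trialset, select_channels
from dtfnet.exceptions import MontageError, ValidationError
from dtfnet.trialset import FULL32_LABELS, MOTOR10_LABELS


def _ts(data, labels=None, classes=None, fs=500.0):
    data = np.asarray(data, dtype=float)
    n_t, n_c, _ = data.shape
    return TrialSet(
        data=data,
        fs=fs,
        channel_labels=labels or [f"ch{i}" for i in range(n_c)],
        class_labels=classes if classes is not None else [(-1) ** i for i in range(n_t)],
    )


class TestInvariants:
    def test_valid_roundtrip_of_fields(self, rng):
        ts = _ts(rng.standard_normal((3, 2, 10)))
        assert (ts.n_trials, ts.n_channels, ts.n_samples) == (3, 2, 10)

    @pytest.mark.parametrize(
        "shape", [(0, 2, 10), (3, 1, 10), (3, 2, 1)], ids=["no-trials", "one-channel", "one-sample"]
    )
    def test_degenerate_shapes_rejected(self, rng, shape):
        with pytest.raises(ValidationError):
            _ts(np.zeros(shape) if 0 in shape else rng.standard_normal(shape))

    def test_label_mismatches_rejected(self, rng):
        data = rng.standard_normal((3, 2, 10))
        with pytest.raises(ValidationError):
            _ts(data, labels=["C3"])
        with pytest.raises(ValidationError):
            _ts(data, classes=[1, -1])
        with pytest.raises(ValidationError):
            _ts(data, classes=[0, 1, 2])

    def test_nonfinite_sample_names_trial_and_channel(self, rng):
        data = rng.standard_normal((3, 2, 10))
        data[1, 0, 4] = np.nan
        with pytest.raises(ValidationError, match="trial 1.*ch0"):
            _ts(data)


class TestMontage:
    def test_motor10_selection_order(self, rng):
        ts = _ts(rng.standard_normal((4, 32, 20)), labels=list(FULL32_LABELS))
        sub = select_channels(ts, Montage.motor10())
        assert sub.channel_labels == MOTOR10_LABELS
        for k, name in enumerate(MOTOR10_LABELS):
            np.testing.assert_array_equal(sub.data[:, k], ts.data[:, FULL32_LABELS.index(name)])

    def test_pair2_rows_equal_original(self, rng):
        ts = _ts(rng.standard_normal((4, 32, 20)), labels=list(FULL32_LABELS))
        sub = select_channels(ts, Montage.pair2())
        np.testing.assert_array_equal(sub.data[:, 0], ts.data[:, FULL32_LABELS.index("C3")])
        np.testing.assert_array_equal(sub.data[:, 1], ts.data[:, FULL32_LABELS.index("C4")])

    def test_idempotent_and_identity(self, rng):
        ts = _ts(rng.standard_normal((4, 10, 20)), labels=list(MOTOR10_LABELS))
        once = select_channels(ts, Montage.motor10())
        twice = select_channels(once, Montage.motor10())
        np.testing.assert_array_equal(once.data, twice.data)
        np.testing.assert_array_equal(once.data, ts.data)

    def test_case_insensitive_match(self, rng):
        ts = _ts(rng.standard_normal((2, 2, 10)), labels=["c3 ", " C4"])
        sub = select_channels(ts, Montage.custom(["C4", "C3"]))
        np.testing.assert_array_equal(sub.data[:, 0], ts.data[:, 1])

    def test_missing_label_named(self, rng):
        ts = _ts(rng.standard_normal((2, 2, 10)), labels=["C3", "C4"])
        with pytest.raises(MontageError, match="Oz"):
            select_channels(ts, Montage.custom(["C3", "Oz"]))


class TestRoundTrips:
    def test_array_container_bit_exact(self, small_trialset, tmp_path):
        p = save_trialset(small_trialset, tmp_path / "ts.npz")
        back = load_trialset(p)
        np.testing.assert_array_equal(back.data, small_trialset.data)
        assert back.channel_labels == small_trialset.channel_labels
        np.testing.assert_array_equal(back.class_labels, small_trialset.class_labels)
        assert back.epoch_window == small_trialset.epoch_window
        assert back.fs == small_trialset.fs

    def test_delimited_text_roundtrip(self, rng, tmp_path):
        ts = _ts(rng.standard_normal((3, 2, 10)), labels=["C3", "C4"])
        save_trialset(ts, tmp_path / "txt", format="delimited-text")
        back = load_trialset(tmp_path / "txt", format="delimited-text")
        assert back.data.shape == (3, 2, 10)
        assert np.max(np.abs(back.data - ts.data)) <= 1e-12
        assert back.channel_labels == ("C3", "C4")

    def test_unknown_format_rejected(self, small_trialset, tmp_path):
        with pytest.raises(ValidationError):
            save_trialset(small_trialset, tmp_path / "x", format="parquet")
        with pytest.raises(ValidationError):
            load_trialset(tmp_path / "nope.npz")


class TestEpoching:
    def test_imagery_window_sample_count(self, rng):
        # 9 s continuous recording at 500 Hz, epoch [3, 9) s -> (9-3)*500 samples
        cont = rng.standard_normal((2, 9 * 500))
        epochs, y = epoch_continuous(cont, 500.0, onsets_s=[0.0], labels=[1], start_s=3.0, end_s=9.0)
        assert epochs.shape == (1, 2, 3000)
        np.testing.assert_array_equal(epochs[0], cont[:, 1500:4500])

    def test_out_of_range_epoch_rejected(self, rng):
        cont = rng.standard_normal((2, 1000))
        with pytest.raises(ValidationError):
            epoch_continuous(cont, 500.0, [1.0], [1], 0.0, 2.0)


class TestBandpass:
    fs = 500.0

    def _tone(self, freq, seconds=10.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        return _ts(np.stack([np.stack([x, x])]), fs=self.fs)

    @staticmethod
    def _rms(ts):
        core = ts.data[..., 500:-500]  # ignore filter edge transients
        return np.sqrt(np.mean(core**2))

    def test_stopband_tone_suppressed(self):
        ts = self._tone(50.0)
        out = bandpass(ts, 8.0, 30.0)
        assert self._rms(out) < 0.05 * self._rms(ts)

    def test_passband_tone_preserved(self):
        ts = self._tone(20.0)
        out = bandpass(ts, 8.0, 30.0)
        assert abs(self._rms(out) - self._rms(ts)) < 0.05 * self._rms(ts)

    def test_zero_in_zero_out(self):
        ts = _ts(np.zeros((2, 2, 1000)), fs=self.fs)
        out = bandpass(ts, 8.0, 30.0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_linearity_and_trial_permutation(self, rng):
        ts = _ts(rng.standard_normal((4, 3, 1000)), fs=self.fs)
        out = bandpass(ts, 8.0, 30.0)
        scaled = bandpass(dataclasses.replace(ts, data=3.5 * ts.data), 8.0, 30.0)
        np.testing.assert_allclose(scaled.data, 3.5 * out.data, atol=1e-9)
        perm = [2, 0, 3, 1]
        permuted = bandpass(
            dataclasses.replace(ts, data=ts.data[perm], class_labels=ts.class_labels[perm]),
            8.0,
            30.0,
        )
        np.testing.assert_allclose(permuted.data, out.data[perm], atol=1e-12)

    def test_band_outside_nyquist_rejected(self):
        ts = self._tone(20.0, seconds=2.0)
        with pytest.raises(ValidationError):
            bandpass(ts, 8.0, 300.0)
        with pytest.raises(ValidationError):
            bandpass(ts, 30.0, 8.0)
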