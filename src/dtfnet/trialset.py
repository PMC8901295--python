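"""Trial containers, montages, file I/O and optional band-pass filtering.

The universal input of the pipeline is a :class:`TrialSet`: a stack of
epoched multichannel EEG trials (trials x channels x samples, microvolts)
with a sampling rate, ordered 10-20-system channel labels and a per-trial
class label in {-1, +1} (left / right hand imagery).

Two native on-disk formats are supported:

* *array container* — a single ``.npz`` file, lossless round trip;
* *delimited text* — a directory with one TSV per trial (channels as
  columns, header row of channel labels) plus a YAML metadata sidecar.

Continuous BrainVision / EDF recordings are accepted read-only by
delegating parsing to :mod:`mne` and cutting epochs around stimulus
markers.
"""

from __future__ import annotations

import dataclasses
import math
import pathlib
from collections.abc import Mapping, Sequence

import numpy as np
import yaml
from scipy import signal as _sig

from .exceptions import MontageError, ValidationError

__all__ = [
    "TrialSet",
    "Montage",
    "load_trialset",
    "save_trialset",
    "select_channels",
    "bandpass",
    "epoch_continuous",
]

#: The ten motor-area channels used for the mid-sized montage, in order.
MOTOR10_LABELS = ("F3", "F4", "C3", "C4", "Fz", "Cz", "FC1", "FC2", "FC5", "FC6")

#: Standard 32-electrode cap layout (10-20 extended).
FULL32_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
)


def _norm_label(label: str) -> str:
    return label.strip().lower()


@dataclasses.dataclass(frozen=True)
class TrialSet:
    """Epoched multichannel trials with class labels.

    Parameters
    ----------
    data
        Real array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered channel names (10-20 system).
    class_labels
        Per-trial integer label in ``{-1, +1}``.
    epoch_window
        ``(start_s, end_s)`` of the epoch relative to trial onset; defaults
        to the 3-9 s imagery window of the acquisition protocol.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    class_labels: np.ndarray
    epoch_window: tuple[float, float] = (3.0, 9.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        labels = np.asarray(self.class_labels, dtype=np.int64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(str(c) for c in self.channel_labels))
        object.__setattr__(self, "class_labels", labels)
        object.__setattr__(self, "epoch_window", (float(self.epoch_window[0]), float(self.epoch_window[1])))
        if data.ndim != 3:
            raise ValidationError(f"data must be 3-D (trials, channels, samples); got shape {data.shape}")
        n_trials, n_channels, n_samples = data.shape
        if n_trials < 1:
            raise ValidationError("a TrialSet needs at least one trial")
        if n_channels < 2:
            raise ValidationError("a TrialSet needs at least two channels")
        if n_samples < 2:
            raise ValidationError("a TrialSet needs at least two samples per trial")
        if len(self.channel_labels) != n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for {n_channels} channels"
            )
        if len(set(_norm_label(c) for c in self.channel_labels)) != n_channels:
            raise ValidationError("channel labels must be unique (case-insensitive)")
        if labels.shape != (n_trials,):
            raise ValidationError(f"class_labels must have shape ({n_trials},); got {labels.shape}")
        if not np.all(np.isin(labels, (-1, 1))):
            raise ValidationError("class labels must be -1 or +1")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive; got {self.fs}")
        if not np.isfinite(data).all():
            bad = np.argwhere(~np.isfinite(data))
            t, c, _ = bad[0]
            raise ValidationError(
                f"non-finite sample in trial {t}, channel {self.channel_labels[c]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        """Index of a channel by name (case-insensitive, whitespace-stripped)."""
        wanted = _norm_label(label)
        for i, c in enumerate(self.channel_labels):
            if _norm_label(c) == wanted:
                return i
        raise MontageError(f"channel {label!r} not present in {list(self.channel_labels)}")


@dataclasses.dataclass(frozen=True)
class Montage:
    """A named, ordered channel selection."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(c) for c in self.labels))
        if len(set(_norm_label(c) for c in self.labels)) != len(self.labels):
            raise ValidationError("montage labels must be unique")

    @classmethod
    def pair2(cls) -> "Montage":
        """The two primary sensorimotor channels C3, C4."""
        return cls("pair2", ("C3", "C4"))

    @classmethod
    def motor10(cls) -> "Montage":
        """Ten channels in or near the motor area."""
        return cls("motor10", MOTOR10_LABELS)

    @classmethod
    def full32(cls) -> "Montage":
        """The full 32-electrode cap."""
        return cls("full32", FULL32_LABELS)

    @classmethod
    def custom(cls, labels: Sequence[str]) -> "Montage":
        return cls("custom", tuple(labels))

    @classmethod
    def named(cls, name: str) -> "Montage":
        try:
            return {"pair2": cls.pair2, "motor10": cls.motor10, "full32": cls.full32}[name]()
        except KeyError:
            raise MontageError(f"unknown montage name {name!r}") from None


def select_channels(ts: TrialSet, montage: Montage) -> TrialSet:
    """Return a TrialSet restricted to the montage channels, in montage order.

    Channel matching is case-insensitive with whitespace stripped. Missing
    channels raise :class:`MontageError` naming the offending label.
    """
    idx = [ts.channel_index(label) for label in montage.labels]
    return TrialSet(
        data=ts.data[:, idx, :],
        fs=ts.fs,
        channel_labels=tuple(montage.labels),
        class_labels=ts.class_labels,
        epoch_window=ts.epoch_window,
    )


def bandpass(ts: TrialSet, low_hz: float, high_hz: float, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass of every trial and channel.

    Filtering is OFF by default in the pipeline: narrowing the band also
    discards autoregressive structure the downstream features rely on and
    tends to cost classification accuracy, so the main analysis runs on
    unfiltered data. It remains available for exploration.

    The filter is applied forward and backward (``sosfiltfilt``), doubling
    the effective attenuation and cancelling phase distortion.
    """
    nyq = ts.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=ts.fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, ts.data, axis=-1)
    return dataclasses.replace(ts, data=filtered)


def epoch_continuous(
    data: np.ndarray,
    fs: float,
    onsets_s: Sequence[float],
    labels: Sequence[int],
    start_s: float,
    end_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a continuous recording (channels x samples) into epochs.

    Each epoch covers the half-open window ``[onset + start_s, onset + end_s)``
    with sample index ``floor(t * fs)``, so a 3-9 s window at 500 Hz yields
    exactly 3000 samples.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValidationError("continuous data must be 2-D (channels, samples)")
    if end_s <= start_s:
        raise ValidationError("epoch end must exceed epoch start")
    n_len = int(math.floor(end_s * fs)) - int(math.floor(start_s * fs))
    epochs = []
    for onset in onsets_s:
        i0 = int(math.floor((onset + start_s) * fs))
        i1 = i0 + n_len
        if i0 < 0 or i1 > data.shape[1]:
            raise ValidationError(
                f"epoch [{onset + start_s}, {onset + end_s}) s falls outside the recording"
            )
        epochs.append(data[:, i0:i1])
    return np.stack(epochs, axis=0), np.asarray(labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

ARRAY_FORMAT = "array-container"
TEXT_FORMAT = "delimited-text"
_CONTINUOUS_FORMATS = ("brainvision", "edf")


def save_trialset(ts: TrialSet, path: str | pathlib.Path, format: str = ARRAY_FORMAT) -> pathlib.Path:
    """Write a TrialSet to disk in one of the native formats.

    The array container round-trips bit-exactly; the delimited-text format
    serialises samples with 17 significant digits, which is also exact for
    IEEE doubles.
    """
    path = pathlib.Path(path)
    if format == ARRAY_FORMAT:
        np.savez(
            path,
            data=ts.data,
            fs=np.float64(ts.fs),
            channel_labels=np.asarray(ts.channel_labels, dtype=np.str_),
            class_labels=ts.class_labels,
            epoch_window=np.asarray(ts.epoch_window, dtype=np.float64),
        )
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    if format == TEXT_FORMAT:
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "fs": float(ts.fs),
            "channel_labels": list(ts.channel_labels),
            "class_labels": [int(v) for v in ts.class_labels],
            "epoch_window": [float(v) for v in ts.epoch_window],
            "n_trials": int(ts.n_trials),
        }
        (path / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        header = "\t".join(ts.channel_labels)
        for t in range(ts.n_trials):
            np.savetxt(
                path / f"trial_{t:04d}.tsv",
                ts.data[t].T,  # samples as rows, channels as columns
                fmt="%.17g",
                delimiter="\t",
                header=header,
                comments="",
            )
        return path
    raise ValidationError(f"unknown save format {format!r}")


def _load_array(path: pathlib.Path) -> TrialSet:
    with np.load(path, allow_pickle=False) as arc:
        return TrialSet(
            data=arc["data"],
            fs=float(arc["fs"]),
            channel_labels=tuple(str(c) for c in arc["channel_labels"]),
            class_labels=arc["class_labels"],
            epoch_window=tuple(arc["epoch_window"]),
        )


def _load_text(path: pathlib.Path) -> TrialSet:
    meta_path = path / "metadata.yaml"
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    trials = []
    for t in range(int(meta["n_trials"])):
        f = path / f"trial_{t:04d}.tsv"
        if not f.exists():
            raise ValidationError(f"missing trial file {f}")
        arr = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=2)
        trials.append(arr.T)
    return TrialSet(
        data=np.stack(trials, axis=0),
        fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        class_labels=np.asarray(meta["class_labels"], dtype=np.int64),
        epoch_window=tuple(meta["epoch_window"]),
    )


def _load_continuous(path: pathlib.Path, format: str, epoch_spec) -> TrialSet:
    # mne is an optional dependency used only for vendor formats
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise ValidationError("reading BrainVision/EDF requires the 'mne' package") from exc
    if epoch_spec is None:
        raise ValidationError("continuous recordings require an epoch_spec (marker_map, start_s, end_s)")
    marker_map, start_s, end_s = epoch_spec
    if not isinstance(marker_map, Mapping):
        raise ValidationError("epoch_spec marker map must map annotation description -> class label")
    if format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    onsets, labels = [], []
    for ann in raw.annotations:
        desc = str(ann["description"]).strip()
        if desc in marker_map:
            onsets.append(float(ann["onset"]))
            labels.append(int(marker_map[desc]))
    if not onsets:
        raise ValidationError(f"no annotations matching {sorted(marker_map)} in {path}")
    data = raw.get_data() * 1e6  # mne returns volts; trials are stored in microvolts
    epochs, y = epoch_continuous(data, raw.info["sfreq"], onsets, labels, start_s, end_s)
    return TrialSet(
        data=epochs,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        class_labels=y,
        epoch_window=(float(start_s), float(end_s)),
    )


def load_trialset(
    path: str | pathlib.Path,
    format: str = ARRAY_FORMAT,
    epoch_spec: tuple[Mapping[str, int], float, float] | None = None,
) -> TrialSet:
    """Read a TrialSet from disk.

    ``format`` is one of ``array-container`` (npz), ``delimited-text``
    (directory of TSVs), ``brainvision`` or ``edf``. Continuous formats
    require ``epoch_spec = (marker_map, start_s, end_s)`` where
    ``marker_map`` maps annotation descriptions to class labels.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise ValidationError(f"no such file or directory: {path}")
    if format == ARRAY_FORMAT:
        return _load_array(path)
    if format == TEXT_FORMAT:
        return _load_text(path)
    if format in _CONTINUOUS_FORMATS:
        return _load_continuous(path, format, epoch_spec)
    raise ValidationError(f"unknown load format {format!r}")
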