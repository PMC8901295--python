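"""Frequency-domain transfer matrices and the Directed Transfer Function.

A fitted MVAR model ``x(t) = sum_k Lambda_k x(t-k) + e(t)`` has the
characteristic matrix

.. math:: A(f) = I - \\sum_{k=1}^{p} \\Lambda_k\\, e^{-j 2\\pi f k / f_s},

whose inverse ``H(f) = A(f)^{-1}`` maps innovation noise to the observed
spectrum. The DTF row-normalises the squared magnitudes of H:

.. math:: \\gamma^2_{ij}(f) = \\frac{|H_{ij}(f)|^2}{\\sum_{m=1}^{N} |H_{im}(f)|^2},

the fraction of the total inflow to channel i attributable to channel j at
frequency f. Rows sum to one and every entry lies in [0, 1]; a zero entry
means no information flows from j into i at that frequency. The DTF
depends only on the coefficient matrices and the sampling rate — never on
the innovation covariance.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .exceptions import SingularSpectrumError
from .mvar import MVARModel

__all__ = ["SpectralTransfer", "DTFMatrix", "transfer_matrix", "dtf_matrix", "READOUT_FREQS_HZ"]

#: Default read-out frequencies spanning the mu and beta bands.
READOUT_FREQS_HZ = (10.0, 15.0, 20.0, 25.0, 30.0)

_COND_LIMIT = 1e12


@dataclasses.dataclass(frozen=True)
class SpectralTransfer:
    """Transfer matrices H(f), one complex N x N matrix per frequency."""

    freqs: np.ndarray
    H: np.ndarray  # (n_freqs, N, N) complex

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=np.float64))
        object.__setattr__(self, "H", np.asarray(self.H, dtype=np.complex128))
        if self.H.shape[0] != self.freqs.size:
            raise ValueError("one H matrix required per frequency")


@dataclasses.dataclass(frozen=True)
class DTFMatrix:
    """Row-stochastic DTF connectivity gamma^2, one N x N matrix per frequency.

    ``gamma2[f][i, j]`` is the normalised flow from channel j into channel i
    at ``freqs[f]``.
    """

    freqs: np.ndarray
    gamma2: np.ndarray  # (n_freqs, N, N) real
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=np.float64))
        object.__setattr__(self, "gamma2", np.asarray(self.gamma2, dtype=np.float64))
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if self.gamma2.ndim != 3 or self.gamma2.shape[0] != self.freqs.size:
            raise ValueError("gamma2 must be (n_freqs, N, N)")
        if len(self.channel_labels) != self.gamma2.shape[1]:
            raise ValueError("channel_labels must match the matrix size")

    @property
    def n_channels(self) -> int:
        return self.gamma2.shape[1]

    def at(self, freq_hz: float) -> np.ndarray:
        """The gamma^2 matrix at one evaluated frequency."""
        idx = np.flatnonzero(np.isclose(self.freqs, freq_hz))
        if idx.size == 0:
            raise KeyError(f"{freq_hz} Hz was not evaluated; have {self.freqs.tolist()}")
        return self.gamma2[idx[0]]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (frequency_hz, from_channel, to_channel, gamma2)."""
        rows = []
        labels = self.channel_labels
        for f, g in zip(self.freqs, self.gamma2):
            for i in range(self.n_channels):
                for j in range(self.n_channels):
                    rows.append((f, labels[j], labels[i], g[i, j]))
        return pd.DataFrame(rows, columns=["frequency_hz", "from_channel", "to_channel", "gamma2"])


def transfer_matrix(model: MVARModel, freqs: Sequence[float]) -> SpectralTransfer:
    """Evaluate H(f) = A(f)^{-1} at the requested frequencies.

    Frequencies must lie in [0, fs/2]. A characteristic matrix with
    condition number above 1e12 raises :class:`SingularSpectrumError`
    naming the frequency — a stable fitted model cannot produce one, so
    hitting this signals a broken fit rather than a property of the data.
    """
    freqs = np.asarray(list(freqs), dtype=np.float64)
    nyq = model.fs / 2.0
    if freqs.size == 0:
        raise ValueError("at least one frequency is required")
    if np.any(freqs < 0) or np.any(freqs > nyq):
        raise ValueError(f"frequencies must lie in [0, {nyq}] Hz; got {freqs.tolist()}")
    n = model.n_channels
    lags = np.arange(1, model.order + 1)
    H = np.empty((freqs.size, n, n), dtype=np.complex128)
    for fi, f in enumerate(freqs):
        phases = np.exp(-2j * np.pi * f * lags / model.fs)
        A = np.eye(n, dtype=np.complex128) - np.tensordot(phases, model.coeff_mats, axes=(0, 0))
        if np.linalg.cond(A) > _COND_LIMIT:
            raise SingularSpectrumError(f"characteristic matrix singular at {f} Hz")
        H[fi] = np.linalg.inv(A)
    return SpectralTransfer(freqs=freqs, H=H)


def dtf_matrix(model: MVARModel, freqs: Sequence[float] = READOUT_FREQS_HZ) -> DTFMatrix:
    """Compute the DTF gamma^2 matrices of a model at the given frequencies."""
    st = transfer_matrix(model, freqs)
    power = np.abs(st.H) ** 2
    row_sums = power.sum(axis=2, keepdims=True)
    if np.any(row_sums <= 0):  # impossible for an invertible A(f); assert anyway
        raise SingularSpectrumError("zero total inflow row in |H(f)|^2")
    return DTFMatrix(freqs=st.freqs, gamma2=power / row_sums, channel_labels=model.channel_labels)
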