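"""Per-trial feature extraction: AR parameters, DTF network flows, fusion.

Two scikit-learn transformers do the work and compose with sklearn
pipelines and model selection:

* :class:`ARFeatureExtractor` — per channel, the Burg AR coefficients
  a_1..a_p, concatenated channel-major (N*p features per trial);
* :class:`DTFFeatureExtractor` — per trial, one MVAR fit over all
  channels, then the off-diagonal DTF entries gamma^2 at each requested
  frequency (|freqs| * N * (N-1) features per trial).

Both operate on 3-D arrays of shape (trials, channels, samples); module
functions wrap them to consume :class:`~dtfnet.trialset.TrialSet` objects
and return labelled :class:`FeatureTable` containers whose feature names
record provenance (e.g. ``ar:C3:a2``, ``dtf30:FC1->Cz``).

Extraction is strictly per-trial: permuting trials permutes feature rows
identically and nothing is shared across trials except a model order fixed
in advance (or selected once on a small calibration subset).
"""

from __future__ import annotations

import dataclasses
import pathlib
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dtf import READOUT_FREQS_HZ, dtf_matrix
from .exceptions import EstimationError, ValidationError
from .mvar import LEAST_SQUARES, fit_ar_burg, fit_mvar, select_order_aic
from .trialset import TrialSet

__all__ = [
    "FeatureTable",
    "ARFeatureExtractor",
    "DTFFeatureExtractor",
    "ar_features",
    "dtf_features",
    "fuse_features",
    "standardize",
]


@dataclasses.dataclass(frozen=True)
class FeatureTable:
    """Trials x features matrix with named columns and class labels."""

    X: np.ndarray
    feature_names: tuple[str, ...]
    class_labels: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.class_labels, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "class_labels", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2:
            raise ValidationError(f"X must be 2-D; got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValidationError("feature matrix contains non-finite values")
        if len(self.feature_names) != X.shape[1]:
            raise ValidationError("one name required per feature column")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if y.shape != (X.shape[0],):
            raise ValidationError("one class label required per trial")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "class_label", self.class_labels)
        return df

    def save(self, path: str | pathlib.Path) -> None:
        """Delimited-text dump (17 significant digits; lossless for doubles)."""
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path: str | pathlib.Path, provenance: dict | None = None) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            X=df.drop(columns=["class_label"]).to_numpy(dtype=np.float64),
            feature_names=tuple(c for c in df.columns if c != "class_label"),
            class_labels=df["class_label"].to_numpy(dtype=np.int64),
            provenance=provenance or {},
        )


def _check_trials_3d(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValidationError(f"expected (trials, channels, samples); got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValidationError("trial data contains non-finite values")
    return X


class ARFeatureExtractor(TransformerMixin, BaseEstimator):
    """Univariate Burg AR coefficients of every channel, channel-major.

    Parameters
    ----------
    order : int, default 6
        AR order p, fixed across trials so feature vectors share a length.
    channel_labels : sequence of str, optional
        Used in feature names; defaults to ``ch0..chN-1``.
    """

    def __init__(self, order: int = 6, channel_labels: Sequence[str] | None = None):
        self.order = order
        self.channel_labels = channel_labels

    def fit(self, X, y=None):
        X = _check_trials_3d(X)
        if X.shape[2] <= 2 * self.order:
            raise EstimationError(
                f"trials of {X.shape[2]} samples too short for Burg order {self.order}"
            )
        self.n_channels_ = X.shape[1]
        self.n_features_out_ = self.n_channels_ * self.order
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_channels_")
        X = _check_trials_3d(X)
        out = np.empty((X.shape[0], self.n_features_out_))
        for t in range(X.shape[0]):
            cols = []
            for c in range(X.shape[1]):
                try:
                    cols.append(fit_ar_burg(X[t, c], self.order).coeffs)
                except EstimationError as exc:
                    raise EstimationError(f"Burg failed on trial {t}, channel {c}: {exc}") from exc
            out[t] = np.concatenate(cols)
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_channels_")
        labels = self.channel_labels or [f"ch{i}" for i in range(self.n_channels_)]
        return np.asarray(
            [f"ar:{ch}:a{k}" for ch in labels for k in range(1, self.order + 1)], dtype=object
        )


class DTFFeatureExtractor(TransformerMixin, BaseEstimator):
    """Directed-transfer-function network flows as per-trial features.

    For each trial one MVAR model is fitted over *all* channels, its DTF
    gamma^2 is evaluated at the requested frequencies, and the off-diagonal
    entries (directed channel pairs) are vectorised. The diagonal self-flow
    can be included with ``include_diagonal=True``.

    Parameters
    ----------
    freqs : sequence of float, default (10, 15, 20, 25, 30) Hz
        Discrete frequency components at which gamma^2 is read out.
    order : int or "aic", default "aic"
        MVAR order. ``"aic"`` selects it once, on a calibration subset of
        the first ``min(calibration_trials, n_trials)`` trials seen by
        ``fit``, then keeps it fixed so all trials share a feature space.
    p_max : int, default 20
        Order-search ceiling when ``order="aic"``.
    method : str
        MVAR estimator ("least-squares" or "multichannel-burg").
    fs : float, default 500
        Sampling rate in Hz.
    """

    def __init__(
        self,
        freqs: Sequence[float] = READOUT_FREQS_HZ,
        order: int | str = "aic",
        p_max: int = 20,
        method: str = LEAST_SQUARES,
        include_diagonal: bool = False,
        fs: float = 500.0,
        channel_labels: Sequence[str] | None = None,
        calibration_trials: int = 10,
    ):
        self.freqs = freqs
        self.order = order
        self.p_max = p_max
        self.method = method
        self.include_diagonal = include_diagonal
        self.fs = fs
        self.channel_labels = channel_labels
        self.calibration_trials = calibration_trials

    def fit(self, X, y=None):
        X = _check_trials_3d(X)
        self.n_channels_ = X.shape[1]
        if str(self.order) == "aic":
            n_cal = min(self.calibration_trials, X.shape[0])
            # cap the search so short trials never make every order infeasible
            p_cap = max(1, min(self.p_max, (X.shape[2] - 2) // (2 * self.n_channels_)))
            sel = select_order_aic(
                TrialSet(
                    data=X[:n_cal],
                    fs=self.fs,
                    channel_labels=[f"ch{i}" for i in range(self.n_channels_)],
                    class_labels=np.ones(n_cal, dtype=np.int64),
                )
                if n_cal > 1
                else X[0],
                p_max=p_cap,
                method=self.method,
            )
            self.order_ = sel.order
            self.order_selection_ = sel
        else:
            self.order_ = int(self.order)
        n_pairs = self.n_channels_**2 if self.include_diagonal else self.n_channels_ * (self.n_channels_ - 1)
        self.n_features_out_ = len(tuple(self.freqs)) * n_pairs
        return self

    def _pair_indices(self):
        n = self.n_channels_
        return [(i, j) for i in range(n) for j in range(n) if self.include_diagonal or i != j]

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "order_")
        X = _check_trials_3d(X)
        freqs = tuple(self.freqs)
        pairs = self._pair_indices()
        out = np.empty((X.shape[0], len(freqs) * len(pairs)))
        for t in range(X.shape[0]):
            try:
                model = fit_mvar(X[t], self.order_, fs=self.fs, method=self.method)
                gamma2 = dtf_matrix(model, freqs).gamma2
            except EstimationError as exc:
                raise EstimationError(f"MVAR/DTF failed on trial {t}: {exc}") from exc
            out[t] = np.concatenate([[g[i, j] for i, j in pairs] for g in gamma2])
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "order_")
        labels = self.channel_labels or [f"ch{i}" for i in range(self.n_channels_)]
        names = []
        for f in tuple(self.freqs):
            tag = f"dtf{f:g}"
            for i, j in self._pair_indices():
                names.append(f"{tag}:{labels[j]}->{labels[i]}")
        return np.asarray(names, dtype=object)


# ---------------------------------------------------------------------------
# TrialSet-level wrappers
# ---------------------------------------------------------------------------


def ar_features(ts: TrialSet, order: int = 6) -> FeatureTable:
    """Burg AR coefficient features of every channel of every trial."""
    ext = ARFeatureExtractor(order=order, channel_labels=ts.channel_labels).fit(ts.data)
    return FeatureTable(
        X=ext.transform(ts.data),
        feature_names=tuple(ext.get_feature_names_out()),
        class_labels=ts.class_labels,
        provenance={"kind": "ar", "order": order},
    )


def dtf_features(
    ts: TrialSet,
    freqs: Sequence[float] = READOUT_FREQS_HZ,
    mvar_order: int | str = "aic",
    p_max: int = 20,
    method: str = LEAST_SQUARES,
    include_diagonal: bool = False,
) -> FeatureTable:
    """DTF gamma^2 flow features at the given frequencies, one MVAR per trial."""
    ext = DTFFeatureExtractor(
        freqs=tuple(freqs),
        order=mvar_order,
        p_max=p_max,
        method=method,
        include_diagonal=include_diagonal,
        fs=ts.fs,
        channel_labels=ts.channel_labels,
    ).fit(ts.data)
    return FeatureTable(
        X=ext.transform(ts.data),
        feature_names=tuple(ext.get_feature_names_out()),
        class_labels=ts.class_labels,
        provenance={
            "kind": "dtf",
            "freqs": list(map(float, freqs)),
            "mvar_order": ext.order_,
            "method": method,
            "include_diagonal": include_diagonal,
        },
    )


def fuse_features(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Column-wise concatenation of two feature tables over the same trials."""
    if a.n_trials != b.n_trials or not np.array_equal(a.class_labels, b.class_labels):
        raise ValidationError("cannot fuse: trial counts or class labels differ")
    clash = set(a.feature_names) & set(b.feature_names)
    if clash:
        raise ValidationError(f"cannot fuse: duplicate feature names {sorted(clash)[:5]}")
    return FeatureTable(
        X=np.concatenate([a.X, b.X], axis=1),
        feature_names=a.feature_names + b.feature_names,
        class_labels=a.class_labels,
        provenance={"kind": "fused", "parts": [a.provenance, b.provenance]},
    )


def standardize(
    ft: FeatureTable,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[FeatureTable, tuple[np.ndarray, np.ndarray]]:
    """Centre and scale each feature; returns the table and the (mean, scale).

    Passing ``stats`` from a training fold applies those statistics instead
    of recomputing them, which is how test folds must be treated to avoid
    leakage. Zero-variance features get unit scale and a warning.
    """
    if stats is None:
        mean = ft.X.mean(axis=0)
        scale = ft.X.std(axis=0)
        degenerate = scale == 0.0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} constant feature(s) left unscaled", stacklevel=2
            )
            scale = np.where(degenerate, 1.0, scale)
    else:
        mean, scale = (np.asarray(s, dtype=np.float64) for s in stats)
        if mean.shape != (ft.n_features,) or scale.shape != (ft.n_features,):
            raise ValidationError("standardisation stats do not match the feature count")
    out = dataclasses.replace(ft, X=(ft.X - mean) / scale)
    return out, (mean, scale)
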