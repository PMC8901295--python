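"""Linear-SVM classification of trial features under resampling protocols.

The classifier is a standard maximum-margin SVM with a linear kernel
(decision function ``f(x) = sgn(w.x + b)``); it is deliberately an
off-the-shelf solver (libsvm via scikit-learn), since the method under
study is the feature construction, not the margin optimiser.

Two evaluation protocols are provided:

* ``tenfold-cv`` — stratified 10-fold cross-validation, repeated
  ``n_repeats`` times with reshuffled folds; the default.
* ``half-split`` — repeated stratified 50% train / 50% test splits.

Per-feature standardisation is fitted on the training portion of every
fold and applied to its test portion, inside the fold, so no test
statistics leak into training. Reported accuracies are percentages; the
headline quantity is their arithmetic mean over all folds and repeats.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ProtocolError, ValidationError
from .features import FeatureTable, ar_features, dtf_features, fuse_features
from .trialset import TrialSet

__all__ = [
    "EvalScheme",
    "EvalResult",
    "FeatureConfig",
    "train_eval",
    "compare_pipelines",
]

TENFOLD = "tenfold-cv"
HALF_SPLIT = "half-split-repeated"


@dataclasses.dataclass(frozen=True)
class EvalScheme:
    """Resampling protocol: kind, repetitions, seed."""

    kind: str = TENFOLD
    n_repeats: int = 10
    seed: int = 0
    shuffle: bool = True
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.kind not in (TENFOLD, HALF_SPLIT):
            raise ProtocolError(f"unknown scheme kind {self.kind!r}")
        if self.n_repeats < 1:
            raise ProtocolError("n_repeats must be >= 1")
        if self.kind == TENFOLD and self.n_folds < 2:
            raise ProtocolError("need at least two folds")


@dataclasses.dataclass(frozen=True)
class EvalResult:
    """Fold-level accuracies (percent) and their arithmetic mean."""

    per_repeat_fold_accuracy: tuple[tuple[float, ...], ...]
    mean_accuracy: float
    scheme: EvalScheme
    n_features: int
    n_trials: int

    @property
    def all_fold_accuracies(self) -> np.ndarray:
        return np.asarray([a for rep in self.per_repeat_fold_accuracy for a in rep])

    @property
    def sd_accuracy(self) -> float:
        return float(self.all_fold_accuracies.std(ddof=1)) if self.all_fold_accuracies.size > 1 else 0.0


def _make_classifier(svm_c: float) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=svm_c)),
        ]
    )


def _splits(y: np.ndarray, scheme: EvalScheme, repeat: int):
    rs = int(scheme.seed) + repeat  # distinct, reproducible folds per repeat
    if scheme.kind == TENFOLD:
        cv = StratifiedKFold(n_splits=scheme.n_folds, shuffle=scheme.shuffle, random_state=rs if scheme.shuffle else None)
        yield from cv.split(np.zeros_like(y), y)
    else:
        cv = StratifiedShuffleSplit(n_splits=1, test_size=0.5, random_state=rs)
        yield from cv.split(np.zeros_like(y), y)


def train_eval(ft: FeatureTable, scheme: EvalScheme, svm_c: float = 1.0) -> EvalResult:
    """Evaluate a linear SVM on a feature table under a resampling scheme.

    Returns fold accuracies in percent per repeat and their overall mean.
    The run is fully deterministic given the inputs and the scheme seed.
    """
    if svm_c <= 0:
        raise ValidationError("SVM regularisation C must be positive")
    y = ft.class_labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ProtocolError(f"need exactly two classes; got {classes.tolist()}")
    if scheme.kind == TENFOLD and counts.min() < scheme.n_folds:
        raise ProtocolError(
            f"tenfold CV needs >= {scheme.n_folds} trials per class; got {counts.min()}"
        )
    if scheme.kind == HALF_SPLIT and counts.min() < 2:
        raise ProtocolError("half-split needs >= 2 trials per class")
    per_repeat: list[tuple[float, ...]] = []
    for rep in range(scheme.n_repeats):
        fold_acc = []
        for train_idx, test_idx in _splits(y, scheme, rep):
            clf = _make_classifier(svm_c)
            clf.fit(ft.X[train_idx], y[train_idx])
            acc = float(np.mean(clf.predict(ft.X[test_idx]) == y[test_idx])) * 100.0
            fold_acc.append(acc)
        per_repeat.append(tuple(fold_acc))
    all_acc = [a for rep in per_repeat for a in rep]
    return EvalResult(
        per_repeat_fold_accuracy=tuple(per_repeat),
        mean_accuracy=float(np.mean(all_acc)),
        scheme=scheme,
        n_features=ft.n_features,
        n_trials=ft.n_trials,
    )


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """One feature pipeline to evaluate: AR-only, DTF-only, or fused.

    For ``kind="dtf"`` the features use ``freqs`` (typically one frequency
    at a time, mirroring a per-frequency accuracy table); for
    ``kind="fused"`` the AR features are concatenated with DTF features at
    ``fusion_freq``.
    """

    name: str
    kind: str  # "ar" | "dtf" | "fused"
    ar_order: int = 6
    freqs: tuple[float, ...] = (30.0,)
    mvar_order: int | str = "aic"
    fusion_freq: float = 30.0

    def build(self, ts: TrialSet) -> FeatureTable:
        if self.kind == "ar":
            return ar_features(ts, order=self.ar_order)
        if self.kind == "dtf":
            return dtf_features(ts, freqs=self.freqs, mvar_order=self.mvar_order)
        if self.kind == "fused":
            return fuse_features(
                ar_features(ts, order=self.ar_order),
                dtf_features(ts, freqs=(self.fusion_freq,), mvar_order=self.mvar_order),
            )
        raise ValidationError(f"unknown feature kind {self.kind!r}")


def compare_pipelines(
    ts: TrialSet,
    configs: Sequence[FeatureConfig],
    scheme: EvalScheme,
    svm_c: float = 1.0,
) -> pd.DataFrame:
    """Evaluate several feature configurations under identical folds.

    Because fold assignment depends only on the class labels and the scheme
    seed, every configuration sees the same train/test partitions and the
    accuracy differences are paired. Returns a tidy per-config table
    (config, kind, frequency, n_features, mean and sd of accuracy in %).
    """
    rows = []
    for cfg in configs:
        try:
            ft = cfg.build(ts)
            res = train_eval(ft, scheme, svm_c=svm_c)
        except Exception as exc:
            raise type(exc)(f"[config {cfg.name}] {exc}") from exc
        freq = (
            cfg.fusion_freq
            if cfg.kind == "fused"
            else (cfg.freqs[0] if cfg.kind == "dtf" and len(cfg.freqs) == 1 else np.nan)
        )
        rows.append(
            {
                "config": cfg.name,
                "kind": cfg.kind,
                "frequency_hz": freq,
                "n_features": res.n_features,
                "mean_accuracy_pct": res.mean_accuracy,
                "sd_accuracy_pct": res.sd_accuracy,
            }
        )
    return pd.DataFrame(rows)
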