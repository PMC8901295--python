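"""Autoregressive model estimation: univariate Burg and multichannel MVAR.

Conventions
-----------
All models in this package use the *regression* sign convention

.. math:: x(t) = \\sum_{k=1}^{p} \\Lambda_k\\, x(t-k) + e(t),

i.e. positive coefficients predict positively. The classical all-pole
difference-equation form with a leading minus sign is the same model with
``a_k = -Lambda_k``; the distinction cancels inside the squared transfer
magnitudes used downstream, but a single convention rules the code.

Per-channel means are removed before every fit: AR theory assumes a
zero-mean process.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from collections.abc import Sequence

import numpy as np
from scipy import linalg as _la
from statsmodels.regression.linear_model import burg as _sm_burg

from .exceptions import EstimationError, OrderSelectionError
from .trialset import TrialSet

__all__ = [
    "ARModel",
    "MVARModel",
    "fit_ar_burg",
    "fit_mvar",
    "select_order_aic",
    "OrderSelection",
]

LEAST_SQUARES = "least-squares"
MULTICHANNEL_BURG = "multichannel-burg"


@dataclasses.dataclass(frozen=True)
class ARModel:
    """Univariate all-pole model of order ``p``.

    ``coeffs`` are a_1..a_p in the regression convention
    ``x(t) = sum_k a_k x(t-k) + eps``; ``noise_var`` is the final Burg
    prediction-error power sigma^2.
    """

    order: int
    coeffs: np.ndarray
    noise_var: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=np.float64)
        object.__setattr__(self, "coeffs", coeffs)
        if self.order < 1 or coeffs.shape != (self.order,):
            raise EstimationError(f"need {self.order} coefficients, got shape {coeffs.shape}")
        if not np.isfinite(coeffs).all():
            raise EstimationError("non-finite AR coefficients")
        if not (np.isfinite(self.noise_var) and self.noise_var > 0):
            raise EstimationError(f"noise variance must be positive, got {self.noise_var}")


@dataclasses.dataclass(frozen=True)
class MVARModel:
    """Multivariate AR model ``x(t) = sum_k Lambda_k x(t-k) + e(t)``.

    Parameters
    ----------
    order
        Model order p.
    coeff_mats
        Array of shape ``(p, N, N)``; ``coeff_mats[k-1][i, j]`` is the
        influence of channel j at lag k on channel i.
    noise_cov
        N x N innovation covariance (symmetric PSD).
    fs
        Sampling rate in Hz, carried for frequency-domain evaluation.
    channel_labels
        Optional channel names; defaults to ``ch0..chN-1``.
    """

    order: int
    coeff_mats: np.ndarray
    noise_cov: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mats = np.asarray(self.coeff_mats, dtype=np.float64)
        cov = np.asarray(self.noise_cov, dtype=np.float64)
        object.__setattr__(self, "coeff_mats", mats)
        object.__setattr__(self, "noise_cov", cov)
        if self.order < 1:
            raise EstimationError("MVAR order must be >= 1")
        if mats.ndim != 3 or mats.shape[0] != self.order or mats.shape[1] != mats.shape[2]:
            raise EstimationError(f"coeff_mats must have shape (p, N, N); got {mats.shape}")
        n = mats.shape[1]
        if cov.shape != (n, n):
            raise EstimationError(f"noise_cov must be {n}x{n}; got {cov.shape}")
        if not np.isfinite(mats).all() or not np.isfinite(cov).all():
            raise EstimationError("non-finite MVAR parameters")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise EstimationError("noise covariance must be symmetric")
        eigvals = np.linalg.eigvalsh((cov + cov.T) / 2.0)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise EstimationError("noise covariance must be positive semidefinite")
        if not self.channel_labels:
            object.__setattr__(self, "channel_labels", tuple(f"ch{i}" for i in range(n)))
        elif len(self.channel_labels) != n:
            raise EstimationError("channel_labels length must equal the channel count")
        if not self.fs > 0:
            raise EstimationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.coeff_mats.shape[1]

    def companion(self) -> np.ndarray:
        """Companion matrix of the lag polynomial (Np x Np)."""
        p, n = self.order, self.n_channels
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coeff_mats), axis=1)
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self) -> bool:
        """True when the companion spectral radius is < 1 (safe to simulate)."""
        return self.spectral_radius() < 1.0

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "n_channels": self.n_channels,
            "coeff_mats": self.coeff_mats.tolist(),
            "noise_cov": self.noise_cov.tolist(),
            "fs": self.fs,
            "channel_labels": list(self.channel_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MVARModel":
        return cls(
            order=int(d["order"]),
            coeff_mats=np.asarray(d["coeff_mats"], dtype=np.float64),
            noise_cov=np.asarray(d["noise_cov"], dtype=np.float64),
            fs=float(d["fs"]),
            channel_labels=tuple(d.get("channel_labels", ())),
        )

    def save(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "MVARModel":
        return cls.from_dict(json.loads(pathlib.Path(path).read_text()))


def fit_ar_burg(signal: np.ndarray, order: int) -> ARModel:
    """Fit a univariate AR model with the Burg reflection-coefficient recursion.

    Burg minimises the summed forward and backward prediction-error power,
    which gives usable estimates from short records. The returned
    coefficients follow the regression convention (see module docstring);
    ``noise_var`` is the final prediction-error power.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if order < 1:
        raise EstimationError("AR order must be >= 1")
    if x.size <= 2 * order:
        raise EstimationError(f"need more than {2 * order} samples to fit AR({order}); got {x.size}")
    if not np.isfinite(x).all():
        raise EstimationError("signal contains non-finite values")
    if np.ptp(x) == 0.0:
        raise EstimationError("constant signal: AR model is degenerate")
    coeffs, sigma2 = _sm_burg(x, order=order, demean=True)
    return ARModel(order=order, coeffs=coeffs, noise_var=float(sigma2))


def _as_channel_matrix(trial: np.ndarray) -> np.ndarray:
    x = np.asarray(trial, dtype=np.float64)
    if x.ndim != 2:
        raise EstimationError(f"a trial must be 2-D (channels, samples); got shape {x.shape}")
    return x - x.mean(axis=1, keepdims=True)


def _fit_mvar_ls(x: np.ndarray, order: int, start: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-step-ahead least squares. ``start`` fixes the first predicted index
    (>= order) so AIC fits at different orders share the same target window."""
    n, T = x.shape
    t0 = order if start is None else start
    n_eq = T - t0
    if n_eq < n * order + 1:
        raise EstimationError(
            f"trial too short for MVAR({order}) on {n} channels: {T} samples"
        )
    # regressors: [x(t-1); ...; x(t-p)] stacked as rows of Z
    Z = np.concatenate([x[:, t0 - k : T - k] for k in range(1, order + 1)], axis=0).T
    Y = x[:, t0:].T
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < n * order:
        raise EstimationError(
            f"rank-deficient regressor matrix (rank {rank} < {n * order}); try a lower order"
        )
    resid = Y - Z @ B
    noise_cov = resid.T @ resid / (T - order)
    coeff_mats = np.stack(
        [B[k * n : (k + 1) * n, :].T for k in range(order)], axis=0
    )
    return coeff_mats, noise_cov


def _fit_mvar_vm(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Multichannel Burg (Vieira-Morf) recursion.

    Generalises the univariate Burg lattice: at each stage the normalised
    forward/backward cross-covariance yields matrix reflection coefficients,
    and a Levinson-Whittle step updates the full coefficient set.
    """
    n, T = x.shape
    if T <= n * order + 1:
        raise EstimationError(f"trial too short for MVAR({order}) on {n} channels: {T} samples")
    f = x.copy()
    b = x.copy()
    A: list[np.ndarray] = []
    Bc: list[np.ndarray] = []
    for m in range(1, order + 1):
        ff = f[:, m:]
        bb = b[:, m - 1 : T - 1]
        Pf = ff @ ff.T
        Pb = bb @ bb.T
        Pfb = ff @ bb.T
        try:
            Sf = _la.cholesky(Pf, lower=True)
            Sb = _la.cholesky(Pb, lower=True)
        except _la.LinAlgError as exc:
            raise EstimationError(f"degenerate prediction-error covariance at stage {m}") from exc
        R = _la.solve_triangular(Sf, Pfb, lower=True)
        R = _la.solve_triangular(Sb, R.T, lower=True).T  # Sf^-1 Pfb Sb^-T
        Kf = Sf @ R @ _la.inv(Sb)
        Kb = Sb @ R.T @ _la.inv(Sf)
        A_new = [A[k] - Kf @ Bc[m - 2 - k] for k in range(m - 1)] + [Kf]
        B_new = [Bc[k] - Kb @ A[m - 2 - k] for k in range(m - 1)] + [Kb]
        A, Bc = A_new, B_new
        f_upd = ff - Kf @ bb
        b_upd = bb - Kb @ ff
        f = np.concatenate([np.zeros((n, m)), f_upd], axis=1)
        b = np.concatenate([np.zeros((n, m)), b_upd], axis=1)
    resid = f[:, order:]
    noise_cov = resid @ resid.T / (T - order)
    return np.stack(A, axis=0), noise_cov


def fit_mvar(
    trial: np.ndarray,
    order: int,
    fs: float = 1.0,
    method: str = LEAST_SQUARES,
    channel_labels: Sequence[str] = (),
) -> MVARModel:
    """Fit an MVAR(p) model to one trial (channels x samples).

    ``method`` is ``"least-squares"`` (default; one-step-ahead prediction
    error minimised over t = p+1..T) or ``"multichannel-burg"``
    (Vieira-Morf lattice). The innovation covariance uses the residuals
    with denominator ``samples - order``.
    """
    if order < 1:
        raise EstimationError("MVAR order must be >= 1")
    x = _as_channel_matrix(trial)
    if method == LEAST_SQUARES:
        coeff_mats, noise_cov = _fit_mvar_ls(x, order)
    elif method == MULTICHANNEL_BURG:
        coeff_mats, noise_cov = _fit_mvar_vm(x, order)
    else:
        raise EstimationError(f"unknown MVAR method {method!r}")
    noise_cov = (noise_cov + noise_cov.T) / 2.0
    return MVARModel(
        order=order,
        coeff_mats=coeff_mats,
        noise_cov=noise_cov,
        fs=fs,
        channel_labels=tuple(channel_labels),
    )


@dataclasses.dataclass(frozen=True)
class OrderSelection:
    """Result of AIC order selection: the chosen order and the AIC curve."""

    order: int
    orders: np.ndarray
    aic: np.ndarray


def select_order_aic(
    data: TrialSet | np.ndarray,
    p_max: int = 20,
    method: str = LEAST_SQUARES,
) -> OrderSelection:
    """Choose the MVAR order by the multichannel Akaike criterion.

    ``AIC(p) = n_eff * ln det(Sigma_p) + 2 p N^2`` where ``Sigma_p`` is the
    pooled residual covariance and ``n_eff`` counts prediction equations.
    Every candidate order is fitted on the same target window
    (t = p_max..T-1), so the residual determinants are comparable; with
    nested least-squares fits the determinant is non-increasing in p. Ties
    break toward the smaller order.

    ``data`` may be a :class:`TrialSet` (equations pooled across trials)
    or a single channels x samples trial.
    """
    if p_max < 1:
        raise OrderSelectionError("p_max must be >= 1")
    if isinstance(data, TrialSet):
        trials = [data.data[t] for t in range(data.n_trials)]
    else:
        trials = [np.asarray(data, dtype=np.float64)]
    trials = [_as_channel_matrix(tr) for tr in trials]
    n = trials[0].shape[0]
    T = trials[0].shape[1]
    n_eff = len(trials) * (T - p_max)
    if n_eff < n * p_max + 1:
        raise OrderSelectionError(
            f"not enough samples ({T}) for order selection up to p_max={p_max}"
        )
    orders = np.arange(1, p_max + 1)
    aics = np.full(p_max, np.nan)
    for i, p in enumerate(orders):
        try:
            # pool prediction equations over trials at a common target window
            resid_cov = np.zeros((n, n))
            for tr in trials:
                _, cov = _fit_mvar_ls(tr, int(p), start=p_max) if method == LEAST_SQUARES else (
                    None,
                    _vm_resid_cov(tr, int(p), p_max),
                )
                resid_cov += cov * (T - p)  # undo per-trial denominator
            resid_cov /= n_eff
            sign, logdet = np.linalg.slogdet(resid_cov)
            if sign <= 0:
                continue
            aics[i] = n_eff * logdet + 2.0 * p * n * n
        except EstimationError:
            continue
    if np.isnan(aics).all():
        raise OrderSelectionError("all candidate orders failed to fit")
    best = int(orders[np.nanargmin(aics)])
    return OrderSelection(order=best, orders=orders, aic=aics)


def _vm_resid_cov(tr: np.ndarray, p: int, p_max: int) -> np.ndarray:
    """Residual covariance of a Vieira-Morf fit evaluated on the common
    target window t >= p_max (for comparable AIC across orders)."""
    coeff_mats, _ = _fit_mvar_vm(tr, p)
    n, T = tr.shape
    pred = np.zeros((n, T - p_max))
    for k in range(1, p + 1):
        pred += coeff_mats[k - 1] @ tr[:, p_max - k : T - k]
    resid = tr[:, p_max:] - pred
    return resid @ resid.T / (T - p)
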