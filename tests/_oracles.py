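"""Independent brute-force DTF oracle used by several test modules.

Builds the characteristic matrix elementwise and inverts it via the
explicit cofactor/adjugate formula (N <= 3), sharing no code with the
implementation's linear-algebra path.
"""

import numpy as np

from dtfnet import MVARModel


def char_matrix(mats, f, fs):
    """A(f) assembled term by term from the lag polynomial."""
    p, n, _ = np.asarray(mats).shape
    A = np.eye(n, dtype=complex)
    for k in range(1, p + 1):
        A = A - np.asarray(mats)[k - 1] * np.exp(-2j * np.pi * f * k / fs)
    return A


def cofactor_inverse(A):
    """Adjugate-over-determinant inverse, written out for 1x1..3x3."""
    n = A.shape[0]
    if n == 1:
        return np.array([[1.0 / A[0, 0]]])
    if n == 2:
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        adj = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]])
        return adj / det
    minors = np.empty((3, 3), dtype=complex)
    for i in range(3):
        for j in range(3):
            sub = np.delete(np.delete(A, i, axis=0), j, axis=1)
            minors[i, j] = (-1) ** (i + j) * (sub[0, 0] * sub[1, 1] - sub[0, 1] * sub[1, 0])
    det = sum(A[0, j] * minors[0, j] for j in range(3))
    return minors.T / det


def brute_force_gamma2(mats, freqs, fs):
    """Row-normalised |H|^2 computed entirely through the cofactor path."""
    out = []
    for f in freqs:
        H = cofactor_inverse(char_matrix(mats, f, fs))
        P = np.abs(H) ** 2
        out.append(P / P.sum(axis=1, keepdims=True))
    return np.stack(out)


def random_stable_model(rng, n, p, fs=500.0):
    """Rejection-sample a stable random MVAR model at shrinking scales."""
    for scale in (0.6, 0.3, 0.15, 0.08, 0.04):
        mats = rng.uniform(-scale, scale, size=(p, n, n))
        m = MVARModel(order=p, coeff_mats=mats, noise_cov=np.eye(n), fs=fs)
        if m.is_stable():
            return m
    raise AssertionError("could not draw a stable model")
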