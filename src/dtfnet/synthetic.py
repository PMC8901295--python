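"""Synthetic MVAR trial sets with ground-truth directed connectivity.

The generator emulates the structure of a two-class motor-imagery session:
two blocks of trials (left / right imagery), a 6 s epoch at 500 Hz
(the 3-9 s imagery window), and 10-20-system channel labels. Each class is
a stable MVAR process; the classes share per-channel spectral colouring (a
damped resonance around a sensorimotor rhythm frequency) and differ only in
the *direction* of a small set of lagged couplings, so connectivity — not
single-channel spectra — is what separates them. The default coupling is a
directed three-channel ring whose orientation flips between classes: under
that symmetry every channel's marginal spectrum is identical across
classes, making univariate AR features uninformative by construction while
the DTF sees the direction reversal directly.

An optional per-class spectral override (ERD-like damping of one channel's
resonance) gives univariate features a signal too, which is what a fusion
of AR and DTF features needs to show its worth.

Because each class template is an explicit MVAR model, its *analytic* DTF
is available exactly and serves as ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np

from .dtf import DTFMatrix, READOUT_FREQS_HZ, dtf_matrix
from .exceptions import StabilityError, ValidationError
from .mvar import MVARModel
from .trialset import FULL32_LABELS, MOTOR10_LABELS, TrialSet

__all__ = [
    "SimSpec",
    "Edge",
    "simulate_mvar",
    "make_two_class_trialset",
    "build_class_model",
    "fusion_spec",
    "montage_sweep_spec",
]

#: A directed lagged coupling: (from_channel, to_channel, lag, weight).
Edge = tuple[str, str, int, float]


def _default_labels(n_channels: int) -> tuple[str, ...]:
    if n_channels == 2:
        return ("C3", "C4")
    if n_channels == 10:
        return MOTOR10_LABELS
    if n_channels == 32:
        return FULL32_LABELS
    return tuple(f"ch{i}" for i in range(n_channels))


def _default_edges(labels: Sequence[str]) -> dict[int, tuple[Edge, ...]]:
    """Directed ring C3 -> C4 -> Cz -> C3 for one class, reversed for the
    other (falls back to the first three / two channels when the canonical
    names are absent). Reversing a ring of identical nodes leaves every
    marginal spectrum unchanged, so only directionality distinguishes the
    classes."""
    norm = [c.strip().lower() for c in labels]

    def pick(name: str, fallback: int) -> str:
        return labels[norm.index(name)] if name in norm else labels[fallback]

    if len(labels) >= 3:
        a, b, c = pick("c3", 0), pick("c4", 1), pick("cz", 2)
        w = 0.4
        fwd = ((a, b, 1, w), (b, c, 1, w), (c, a, 1, w))
        rev = ((b, a, 1, w), (c, b, 1, w), (a, c, 1, w))
        return {+1: fwd, -1: rev}
    a, b = labels[0], labels[1]
    return {+1: ((a, b, 1, 0.4),), -1: ((b, a, 1, 0.4),)}


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Recipe for a two-class synthetic trial set.

    Parameters
    ----------
    seed
        Mandatory RNG seed; the whole trial set is reproducible from it.
    n_channels, fs, trial_seconds, n_trials_per_class
        Session geometry. Defaults mirror the emulated protocol: 40 trials
        per class of 6 s at 500 Hz.
    mvar_order
        Order of the class templates (>= 2 so the diagonal resonance fits).
    edges
        Per-class directed couplings ``{+1: (...), -1: (...)}``; each edge
        is ``(from, to, lag, weight)``. Defaults to the direction-flipped
        ring described in the module docstring.
    spectral_radius, spectral_freq_hz
        Shared per-channel AR(2) colouring: a pole pair at radius r and
        frequency f0, i.e. diagonal coefficients ``2 r cos(2 pi f0 / fs)``
        at lag 1 and ``-r^2`` at lag 2. Defaults: r = 0.3, f0 = 12 Hz — a
        mild alpha-band colouring. The radius is kept deliberately modest:
        at 500 Hz a sensorimotor rhythm sits at a very low normalised
        frequency, so a near-unit-root resonance would have a large
        low-frequency gain and could not coexist stably with coupling
        weights of the ~0.4 magnitude the class contrast requires.
    class_spectral
        Optional per-class overrides ``{class: {channel: (r, f0)}}`` to give
        single-channel spectra a class difference (ERD-like damping).
    noise_cov
        Innovation covariance (default identity).
    """

    seed: int
    n_channels: int = 10
    fs: float = 500.0
    trial_seconds: float = 6.0
    n_trials_per_class: int = 40
    mvar_order: int = 2
    channel_labels: tuple[str, ...] = ()
    edges: Mapping[int, tuple[Edge, ...]] | None = None
    spectral_radius: float = 0.3
    spectral_freq_hz: float = 12.0
    class_spectral: Mapping[int, Mapping[str, tuple[float, float]]] | None = None
    noise_cov: np.ndarray | None = None
    burn_in: int = 500

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimSpec requires an explicit seed")
        if self.n_channels < 2:
            raise ValidationError("need at least two channels")
        if self.fs <= 0 or self.trial_seconds <= 0:
            raise ValidationError("fs and trial_seconds must be positive")
        if self.mvar_order < 2:
            raise ValidationError("mvar_order must be >= 2 to host the spectral resonance")
        if not 0 < self.spectral_radius < 1:
            raise ValidationError("spectral_radius must lie in (0, 1)")
        labels = tuple(self.channel_labels) or _default_labels(self.n_channels)
        if len(labels) != self.n_channels:
            raise ValidationError("channel_labels length must equal n_channels")
        object.__setattr__(self, "channel_labels", labels)
        if self.edges is None:
            object.__setattr__(self, "edges", _default_edges(labels))
        if set(self.edges) != {-1, +1}:
            raise ValidationError("edges must be keyed by class labels -1 and +1")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimSpec":
        """Build a SimSpec from a flat configuration mapping (YAML-friendly).

        Edge lists are given as ``edges_pos`` / ``edges_neg``: lists of
        ``[from, to, lag, weight]``. Unknown keys are rejected.
        """
        known = {
            "seed", "n_channels", "fs", "trial_seconds", "n_trials_per_class",
            "mvar_order", "channel_labels", "edges_pos", "edges_neg",
            "spectral_radius", "spectral_freq_hz", "class_spectral", "burn_in",
        }
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown SimSpec keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in d.items() if k in known - {"edges_pos", "edges_neg", "channel_labels", "class_spectral"}}
        if "channel_labels" in d:
            kwargs["channel_labels"] = tuple(d["channel_labels"])
        if ("edges_pos" in d) != ("edges_neg" in d):
            raise ValidationError("edges_pos and edges_neg must be given together")
        if "edges_pos" in d:
            kwargs["edges"] = {
                +1: tuple((str(a), str(b), int(l), float(w)) for a, b, l, w in d["edges_pos"]),
                -1: tuple((str(a), str(b), int(l), float(w)) for a, b, l, w in d["edges_neg"]),
            }
        if "class_spectral" in d and d["class_spectral"] is not None:
            kwargs["class_spectral"] = {
                int(k): {str(ch): (float(v[0]), float(v[1])) for ch, v in m.items()}
                for k, m in d["class_spectral"].items()
            }
        return cls(**kwargs)


def build_class_model(spec: SimSpec, class_label: int) -> MVARModel:
    """Materialise the MVAR template of one class from a SimSpec."""
    if class_label not in (-1, +1):
        raise ValidationError("class_label must be -1 or +1")
    n, p, fs = spec.n_channels, spec.mvar_order, spec.fs
    labels = spec.channel_labels
    norm = [c.strip().lower() for c in labels]
    mats = np.zeros((p, n, n))
    # shared diagonal resonance, optionally overridden per class/channel
    for i, ch in enumerate(labels):
        r, f0 = spec.spectral_radius, spec.spectral_freq_hz
        if spec.class_spectral and class_label in spec.class_spectral:
            override = spec.class_spectral[class_label]
            for name, rf in override.items():
                if name.strip().lower() == ch.strip().lower():
                    r, f0 = rf
        mats[0, i, i] = 2.0 * r * np.cos(2.0 * np.pi * f0 / fs)
        mats[1, i, i] = -r * r
    for src, dst, lag, weight in spec.edges[class_label]:
        if lag < 1 or lag > p:
            raise ValidationError(f"edge lag {lag} outside 1..{p}")
        try:
            j = norm.index(src.strip().lower())
            i = norm.index(dst.strip().lower())
        except ValueError as exc:
            raise ValidationError(f"edge channel not in labels: {src}->{dst}") from exc
        mats[lag - 1, i, j] += weight
    noise_cov = np.eye(n) if spec.noise_cov is None else np.asarray(spec.noise_cov, dtype=np.float64)
    model = MVARModel(order=p, coeff_mats=mats, noise_cov=noise_cov, fs=fs, channel_labels=labels)
    if not model.is_stable():
        raise StabilityError(
            f"class {class_label:+d} template unstable "
            f"(spectral radius {model.spectral_radius():.3f}); weaken couplings"
        )
    return model


def _simulate_batch(model: MVARModel, n_samples: int, n_trials: int, rng: np.random.Generator, burn_in: int) -> np.ndarray:
    """Iterate the MVAR recursion for many independent trials at once.

    Returns an array of shape (n_trials, N, n_samples); the first
    ``burn_in`` steps (from zero initial conditions) are discarded.
    """
    n, p = model.n_channels, model.order
    total = n_samples + burn_in
    L = np.linalg.cholesky(model.noise_cov + 1e-15 * np.eye(n))
    noise = rng.standard_normal((total, n, n_trials))
    x = np.zeros((total, n, n_trials))
    mats = model.coeff_mats
    for t in range(total):
        acc = L @ noise[t]
        for k in range(1, min(p, t) + 1):
            acc += mats[k - 1] @ x[t - k]
        x[t] = acc
    return np.ascontiguousarray(np.transpose(x[burn_in:], (2, 1, 0)))


def simulate_mvar(model: MVARModel, n_samples: int, seed: int, burn_in: int = 500) -> np.ndarray:
    """Simulate one channels x samples realisation of a stable MVAR model.

    Innovations are Gaussian with the model's noise covariance; the run is
    deterministic per seed, and the initial transient (``burn_in`` samples
    from zero initial conditions) is discarded.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if not model.is_stable():
        raise StabilityError(
            f"model unstable (spectral radius {model.spectral_radius():.3f}); refusing to simulate"
        )
    rng = np.random.default_rng(seed)
    return _simulate_batch(model, n_samples, 1, rng, burn_in)[0]


def fusion_spec(seed: int) -> SimSpec:
    """Study condition where *both* feature families carry signal.

    On top of the default direction-flipped ring (connectivity signal for
    the DTF features), each class damps the resonance of one sensorimotor
    channel — C3 for right-hand trials, C4 for left-hand — an ERD-like
    lateralised spectral change that univariate AR features can see.
    A fusion of AR and DTF features should then match or beat either
    family alone.
    """
    return SimSpec(
        seed=seed,
        class_spectral={+1: {"C3": (0.25, 12.0)}, -1: {"C4": (0.25, 12.0)}},
    )


def montage_sweep_spec(seed: int) -> SimSpec:
    """Study condition for the channel-count sweep (pair2 -> motor10 -> full32).

    Three direction-flipped rings carry the class signal at graded
    strengths: a deliberately weak ring touching C3/C4 (so the two-channel
    montage sees only a faint signal), a moderate ring within the wider
    motor area, and a strong ring over parieto-occipital channels visible
    only to the full cap. Classification accuracy should therefore rise
    (or at worst stay level) as the montage grows — the distributed-
    connectivity effect the sweep is designed to demonstrate.
    """
    ring_a = [("C3", "C4", 1, 0.03), ("C4", "Cz", 1, 0.03), ("Cz", "C3", 1, 0.03)]
    ring_b = [("F3", "FC5", 1, 0.10), ("FC5", "FC6", 1, 0.10), ("FC6", "F3", 1, 0.10)]
    ring_c = [("P7", "P8", 1, 0.40), ("P8", "Oz", 1, 0.40), ("Oz", "P7", 1, 0.40)]
    fwd = tuple(ring_a + ring_b + ring_c)
    rev = tuple((dst, src, lag, w) for src, dst, lag, w in fwd)
    return SimSpec(seed=seed, n_channels=32, edges={+1: fwd, -1: rev})


def make_two_class_trialset(
    spec: SimSpec,
    gt_freqs: Sequence[float] = READOUT_FREQS_HZ,
) -> tuple[TrialSet, dict[int, DTFMatrix]]:
    """Generate the full two-class trial set plus analytic ground truth.

    Returns the TrialSet (class +1 block first, then class -1) and, per
    class, the *analytic* DTF of the generating template at ``gt_freqs`` —
    the exact connectivity any estimator should recover.
    """
    models = {c: build_class_model(spec, c) for c in (+1, -1)}
    rng = np.random.default_rng(spec.seed)
    blocks, labels = [], []
    for c in (+1, -1):
        blocks.append(_simulate_batch(models[c], spec.n_samples, spec.n_trials_per_class, rng, spec.burn_in))
        labels.extend([c] * spec.n_trials_per_class)
    ts = TrialSet(
        data=np.concatenate(blocks, axis=0),
        fs=spec.fs,
        channel_labels=spec.channel_labels,
        class_labels=np.asarray(labels, dtype=np.int64),
        epoch_window=(3.0, 3.0 + spec.trial_seconds),
    )
    ground_truth = {c: dtf_matrix(models[c], gt_freqs) for c in (+1, -1)}
    return ts, ground_truth
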