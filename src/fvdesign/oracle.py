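"""Sequence→geometry oracles.

A design run needs a differentiable map from a sequence probability matrix
to per-pair bin probabilities for the six geometry channels.  In production
that map is an ensemble of pretrained antibody structure predictors, plugged
in through the adapter registry; for development and testing this module
bundles a *toy oracle* — a seeded bilinear-softmax model with a closed-form
gradient and a constructible ground-truth optimum.

Oracle contract
---------------
An oracle must provide

``forward(seq_matrix, mask) -> GeometryPrediction``
    ``seq_matrix`` is (L, 20) with rows summing to 1 (soft or one-hot).
``vjp(seq_matrix, mask, grad_probs) -> (L, 20) array``
    Vector–Jacobian product: the gradient of any scalar loss with respect
    to ``seq_matrix``, given the loss gradient with respect to the
    predicted probabilities.
``n_bins(channel) -> int``

The analytic gradient must match central finite differences of
``forward`` composed with any smooth loss (see :func:`check_gradient`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fv import N_AA
from .geometry import CHANNELS, ContactMask, TargetGeometry, GeometryBinning


@dataclass
class GeometryPrediction:
    """Per-pair bin probability distributions, one (C, B_ch) array per channel."""

    probs: dict[str, np.ndarray]
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        C = len(self.pairs)
        for ch, p in self.probs.items():
            if p.shape[0] != C:
                raise ValueError(f"channel {ch}: {p.shape[0]} rows for {C} pairs")
            rows = p.sum(axis=1)
            if C and not np.allclose(rows, 1.0, atol=1e-6):
                raise ValueError(f"channel {ch}: probabilities do not sum to 1")
            if C and (p < 0).any():
                raise ValueError(f"channel {ch}: negative probability")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ToyOracle:
    """Seeded bilinear-softmax sequence→geometry model.

    For pair (i, j) and channel X the bin logits are the bilinear form

        z_b = Σ_{a,a'} s_i[a] · s_j[a'] · W[a, a', b]

    with a fixed weight tensor W drawn once from ``seed`` (one tensor per
    channel, shape 20×20×B), and probabilities softmax(z / temperature).
    The map is deterministic given the seed and exactly differentiable.
    """

    name = "toy"

    def __init__(self, seed: int, n_bins: int = 10, temperature: float = 1.0):
        if n_bins < 2:
            raise ValueError("toy oracle needs at least 2 bins")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.seed = int(seed)
        self.temperature = float(temperature)
        self._n_bins = int(n_bins)
        rng = np.random.default_rng(self.seed)
        self.weights: dict[str, np.ndarray] = {
            ch: rng.standard_normal((N_AA, N_AA, self._n_bins)) for ch in CHANNELS
        }

    def n_bins(self, channel: str) -> int:
        return self._n_bins

    def _check(self, seq_matrix: np.ndarray, mask: ContactMask, validate: bool = True) -> np.ndarray:
        seq_matrix = np.asarray(seq_matrix, dtype=float)
        if seq_matrix.ndim != 2 or seq_matrix.shape[1] != N_AA:
            raise ValueError("sequence matrix must have shape (L, 20)")
        if mask.pairs:
            top = max(max(i, j) for i, j in mask.pairs)
            if top >= seq_matrix.shape[0]:
                raise ValueError("contact mask refers to positions beyond the sequence")
        if validate and not np.allclose(seq_matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("sequence matrix rows must sum to 1")
        return seq_matrix

    def forward(
        self, seq_matrix: np.ndarray, mask: ContactMask, validate: bool = True
    ) -> GeometryPrediction:
        # validate=False admits off-simplex inputs, needed by finite-difference probes
        seq_matrix = self._check(seq_matrix, mask, validate)
        ii, jj = mask.as_arrays()
        si, sj = seq_matrix[ii], seq_matrix[jj]  # (C, 20)
        probs = {}
        for ch, W in self.weights.items():
            # z[k, b] = Σ_{a,a'} si[k,a] sj[k,a'] W[a,a',b]
            z = np.einsum("ka,kc,acb->kb", si, sj, W, optimize=True)
            probs[ch] = _softmax(z / self.temperature)
        return GeometryPrediction(probs, mask.pairs)

    def vjp(
        self, seq_matrix: np.ndarray, mask: ContactMask, grad_probs: dict[str, np.ndarray]
    ) -> np.ndarray:
        """Gradient of a scalar loss w.r.t. ``seq_matrix`` given ∂loss/∂probs."""
        seq_matrix = self._check(seq_matrix, mask)
        L = seq_matrix.shape[0]
        ii, jj = mask.as_arrays()
        si, sj = seq_matrix[ii], seq_matrix[jj]
        grad = np.zeros((L, N_AA))
        for ch, W in self.weights.items():
            z = np.einsum("ka,kc,acb->kb", si, sj, W, optimize=True)
            p = _softmax(z / self.temperature)
            g = grad_probs[ch]  # (C, B)
            # softmax backward then scale by 1/T
            gz = p * (g - (g * p).sum(axis=1, keepdims=True)) / self.temperature
            gi = np.einsum("kb,kc,acb->ka", gz, sj, W, optimize=True)
            gj = np.einsum("kb,ka,acb->kc", gz, si, W, optimize=True)
            np.add.at(grad, ii, gi)
            np.add.at(grad, jj, gj)
        return grad


def toy_target(oracle: ToyOracle, reference_matrix: np.ndarray, mask: ContactMask) -> TargetGeometry:
    """Target labels = argmax bins of the oracle's prediction for a reference.

    Feeding a one-hot reference back through the geometric loss then makes
    the reference a strong (verifiable) optimum candidate.  Labels are set
    only on the mask's pairs; everything else is invalid.
    """
    L = np.asarray(reference_matrix).shape[0]
    labels = {ch: -np.ones((L, L), dtype=np.int64) for ch in CHANNELS}
    valid = {ch: np.zeros((L, L), dtype=bool) for ch in CHANNELS}
    if mask.pairs:
        pred = oracle.forward(reference_matrix, mask)
        ii, jj = mask.as_arrays()
        for ch in CHANNELS:
            best = pred.probs[ch].argmax(axis=1)
            labels[ch][ii, jj] = best
            valid[ch][ii, jj] = True
    binning = GeometryBinning.uniform(oracle.n_bins("d_ca"))
    return TargetGeometry(labels, valid, binning)


class EnsembleOracle:
    """Mean-probability ensemble over oracles with identical bin layouts."""

    name = "ensemble"

    def __init__(self, models):
        models = list(models)
        if not models:
            raise ValueError("ensemble needs at least one model")
        b0 = {ch: models[0].n_bins(ch) for ch in CHANNELS}
        for m in models[1:]:
            if any(m.n_bins(ch) != b0[ch] for ch in CHANNELS):
                raise ValueError("ensemble members disagree on bin counts")
        self.models = models

    def n_bins(self, channel: str) -> int:
        return self.models[0].n_bins(channel)

    def forward(self, seq_matrix, mask, validate: bool = True) -> GeometryPrediction:
        preds = [m.forward(seq_matrix, mask, validate) for m in self.models]
        probs = {}
        for ch in CHANNELS:
            mean = np.mean([p.probs[ch] for p in preds], axis=0)
            s = mean.sum(axis=1, keepdims=True)
            probs[ch] = mean / np.where(s == 0, 1.0, s)
        return GeometryPrediction(probs, mask.pairs)

    def vjp(self, seq_matrix, mask, grad_probs) -> np.ndarray:
        # mean of k probability tensors: each member sees grad/k
        k = len(self.models)
        scaled = {ch: g / k for ch, g in grad_probs.items()}
        return sum(m.vjp(seq_matrix, mask, scaled) for m in self.models)


def ensemble_forward(models, seq_matrix, mask) -> GeometryPrediction:
    """Average per-pair probabilities across models and renormalize."""
    return EnsembleOracle(models).forward(seq_matrix, mask)


#: adapter registry: config key -> factory(seed, **kwargs) -> oracle
ORACLE_REGISTRY: dict[str, type] = {"toy": ToyOracle}


def register_oracle(name: str, factory) -> None:
    """Register an external oracle adapter; it must satisfy the oracle contract."""
    ORACLE_REGISTRY[name] = factory


def make_oracle(name: str, **kwargs):
    try:
        factory = ORACLE_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown oracle {name!r}; registered: {sorted(ORACLE_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def check_gradient(
    oracle,
    seq_matrix: np.ndarray,
    mask: ContactMask,
    loss_fn,
    grad_fn,
    n_probes: int = 20,
    eps: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> float:
    """Max relative error of the analytic gradient vs central finite differences.

    ``loss_fn(prediction) -> float`` and ``grad_fn(prediction) -> grad_probs``
    define the scalar functional; probes are random coordinate directions of
    the sequence matrix.
    """
    rng = rng or np.random.default_rng(0)
    analytic = oracle.vjp(seq_matrix, mask, grad_fn(oracle.forward(seq_matrix, mask)))
    worst = 0.0
    L, A = seq_matrix.shape
    scale = max(np.abs(analytic).max(), 1e-8)
    for _ in range(n_probes):
        i, a = rng.integers(L), rng.integers(A)
        plus = seq_matrix.copy()
        plus[i, a] += eps
        minus = seq_matrix.copy()
        minus[i, a] -= eps
        fd = (
            loss_fn(oracle.forward(plus, mask, validate=False))
            - loss_fn(oracle.forward(minus, mask, validate=False))
        ) / (2 * eps)
        rel = abs(fd - analytic[i, a]) / scale
        worst = max(worst, rel)
    return worst
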