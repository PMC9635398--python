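"""The design objective: geometric, sequence and motif losses.

Design is framed as maximizing P(S | T) ∝ P(T | S)·P(S) over the designable
subsequence.  −log P(T | S) becomes the geometric cross-entropy ``L_G``;
the sequence prior P(S) becomes either a cross-entropy pull toward a known
sequence (``L_S``) or a KL pull toward per-position target distributions
(``L_M``).  The total is the weighted sum

    L = w_G · L_G + w_S · L_S + w_M · L_M,     all weights 1 by default.

Natural logarithms throughout.  Probabilities inside logs are floored at
1e−12; each loss is nonnegative and attains 0 exactly at its ideal argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fv import AA_TO_INDEX, N_AA, DesignRegion, FvSequence
from .geometry import CHANNELS, ContactMask, TargetGeometry
from .oracle import GeometryPrediction

logger = logging.getLogger(__name__)

P_FLOOR = 1e-12


@dataclass(frozen=True)
class LossWeights:
    w_g: float = 1.0
    w_s: float = 1.0
    w_m: float = 1.0

    def __post_init__(self):
        if min(self.w_g, self.w_s, self.w_m) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class MotifSpec:
    """Target amino-acid distributions at a subset ℳ of design positions.

    ``positions`` are linear Fv indices (must lie in the design region);
    ``q0`` has one row per motif position, rows sum to 1.
    """

    positions: tuple[int, ...]
    q0: np.ndarray

    def __post_init__(self):
        self.positions = tuple(self.positions)
        self.q0 = np.asarray(self.q0, dtype=float)
        if self.q0.shape != (len(self.positions), N_AA):
            raise ValueError("q0 must have shape (n_motif_positions, 20)")
        if (self.q0 < 0).any() or not np.allclose(self.q0.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must be distributions")

    def validate_region(self, region: DesignRegion) -> None:
        extra = set(self.positions) - set(region.design_positions)
        if extra:
            raise ValueError(f"motif positions {sorted(extra)} are not designable")

    @classmethod
    def one_hot(cls, positions_letters: dict[int, str]) -> "MotifSpec":
        """Motif forcing a single letter at each given linear index."""
        positions = tuple(positions_letters)
        q0 = np.zeros((len(positions), N_AA))
        for row, pos in enumerate(positions):
            q0[row, AA_TO_INDEX[positions_letters[pos]]] = 1.0
        return cls(positions, q0)


@dataclass(frozen=True)
class LossValue:
    total: float
    geometric: float
    sequence: float
    motif: float


def geometric_loss(
    pred: GeometryPrediction, target: TargetGeometry, mask: ContactMask
) -> float:
    """Categorical cross entropy of the target bin labels over contact pairs.

        L_G = −(1/2C) Σ_X Σ_{k=1..C} log p_{X = target}(pair_k)

    C is the ordered-pair contact count; pair-channels whose target label is
    invalid (e.g. glycine CB channels) are skipped.
    """
    C = mask.n_contacts
    if C == 0:
        raise ValueError("geometric loss undefined for an empty contact mask")
    ii, jj = mask.as_arrays()
    total = 0.0
    for ch in CHANNELS:
        labels = target.labels[ch][ii, jj]
        valid = target.valid[ch][ii, jj]
        if not valid.any():
            continue
        p = pred.probs[ch][valid, labels[valid]]
        total -= np.log(np.maximum(p, P_FLOOR)).sum()
    return total / (2 * C)


def geometric_loss_grad(
    pred: GeometryPrediction, target: TargetGeometry, mask: ContactMask
) -> dict[str, np.ndarray]:
    """∂L_G/∂probs, shaped like the prediction (C, B) per channel."""
    C = mask.n_contacts
    ii, jj = mask.as_arrays()
    grads = {}
    for ch in CHANNELS:
        p = pred.probs[ch]
        g = np.zeros_like(p)
        labels = target.labels[ch][ii, jj]
        valid = target.valid[ch][ii, jj]
        rows = np.where(valid)[0]
        cols = labels[valid]
        g[rows, cols] = -1.0 / np.maximum(p[rows, cols], P_FLOOR) / (2 * C)
        grads[ch] = g
    return grads


def sequence_loss(
    seq_matrix: np.ndarray, wildtype: FvSequence, region: DesignRegion
) -> float:
    """Negative log-likelihood of the wildtype letters under the design rows.

        L_S = −Σ_{i∈D} log p_i(wildtype_i)

    ``seq_matrix`` is the full (L, 20) probability matrix; only design rows
    contribute.  Zero probability at a wildtype letter is floored at 1e−12
    with a warning.
    """
    total = 0.0
    for i in region.design_positions:
        p = seq_matrix[i, AA_TO_INDEX[wildtype.letter(i)]]
        if p < P_FLOOR:
            logger.warning("sequence loss: probability floor hit at position %d", i)
            p = P_FLOOR
        total -= np.log(p)
    return total


def sequence_loss_grad(
    seq_matrix: np.ndarray, wildtype: FvSequence, region: DesignRegion
) -> np.ndarray:
    grad = np.zeros_like(seq_matrix)
    for i in region.design_positions:
        a = AA_TO_INDEX[wildtype.letter(i)]
        grad[i, a] = -1.0 / max(seq_matrix[i, a], P_FLOOR)
    return grad


def motif_loss(seq_matrix: np.ndarray, motif: MotifSpec) -> float:
    """KL divergence from the design rows to the motif targets.

        L_M = Σ_{i∈ℳ} Σ_AA q⁰ log(q⁰ / p),   0·log(0/·) := 0, p floored.
    """
    total = 0.0
    for row, i in enumerate(motif.positions):
        q = motif.q0[row]
        p = np.maximum(seq_matrix[i], P_FLOOR)
        nz = q > 0
        total += (q[nz] * np.log(q[nz] / p[nz])).sum()
    return total


def motif_loss_grad(seq_matrix: np.ndarray, motif: MotifSpec) -> np.ndarray:
    grad = np.zeros_like(seq_matrix)
    for row, i in enumerate(motif.positions):
        q = motif.q0[row]
        p = np.maximum(seq_matrix[i], P_FLOOR)
        grad[i] = -q / p
    return grad


def total_loss(
    geometric: float, sequence: float, motif: float, weights: LossWeights
) -> LossValue:
    """Weighted sum with components retained for logging."""
    total = weights.w_g * geometric + weights.w_s * sequence + weights.w_m * motif
    return LossValue(total, geometric, sequence, motif)
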