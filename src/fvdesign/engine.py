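"""The hallucination loop: initialize → decode → forward → loss → update.

A continuous design matrix (|D| × 20) is optimized by normalized gradient
descent through a fixed geometry oracle.  Each iteration decodes the matrix
to a discrete sequence (row-wise argmax of the softmax), feeds the decoded
one-hot forward for the geometric loss, and backpropagates with a
straight-through estimator (the one-hot is treated as identity in the
backward pass).  Sequence and motif losses are evaluated on the softmax
rows — they compare the design *distribution* to a target sequence or
motif — and their gradients are added before the update.

The gradient is globally ℓ2-normalized, so every step moves the matrix by
exactly the learning rate; columns of disallowed letters receive zero
gradient and a −∞-like sentinel value, so they can never be decoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fv import ALPHABET, AA_TO_INDEX, N_AA, AlphabetMask, DesignRegion, FvSequence
from .losses import (
    LossValue,
    LossWeights,
    MotifSpec,
    geometric_loss,
    geometric_loss_grad,
    motif_loss,
    motif_loss_grad,
    sequence_loss,
    sequence_loss_grad,
    total_loss,
)

SENTINEL = -1e9  # effectively −∞ under softmax

MODES = ("unrestricted", "seqrestricted", "motif")


@dataclass
class DesignMatrix:
    """The optimization variable a_{i,AA}: one real row per design position."""

    values: np.ndarray
    region: DesignRegion
    allowed: np.ndarray  # bool (|D|, 20)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.region.n_design, N_AA):
            raise ValueError("design matrix shape must be (|D|, 20)")

    def softmax_rows(self) -> np.ndarray:
        z = self.values - self.values.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class HallucinationConfig:
    """Run settings; defaults follow the library's reference configuration.

    ``mode`` selects which sequence-prior loss is active: ``unrestricted``
    uses the geometric loss only, ``seqrestricted`` adds the wildtype
    cross-entropy, ``motif`` adds the motif KL.  Convergence is declared
    when the total loss changes by less than ``loss_tolerance`` over 5
    consecutive iterations.  Cysteine is disallowed at all design
    positions by default.
    """

    learning_rate: float = 0.05
    max_iterations: int = 60
    loss_tolerance: float = 1e-3
    seed: int = 0
    seeding: str = "none"  # "none" | "wildtype"
    mode: str = "unrestricted"
    weights: LossWeights = field(default_factory=LossWeights)
    disallow: str = "C"
    alphabet_mask: AlphabetMask | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.seeding not in ("none", "wildtype"):
            raise ValueError("seeding must be 'none' or 'wildtype'")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def effective_weights(self, motif: MotifSpec | None) -> LossWeights:
        w = self.weights
        return LossWeights(
            w.w_g,
            w.w_s if self.mode == "seqrestricted" else 0.0,
            w.w_m if (self.mode == "motif" and motif is not None) else 0.0,
        )

    def resolve_mask(self, n_design: int) -> AlphabetMask:
        if self.alphabet_mask is not None:
            if self.alphabet_mask.allowed.shape[0] != n_design:
                raise ValueError("alphabet mask size does not match design region")
            return self.alphabet_mask
        return AlphabetMask.disallowing(n_design, self.disallow)


@dataclass
class DesignRecord:
    """One completed design: final sequence, loss trajectory, provenance."""

    sequence: FvSequence
    designed_subsequence: str
    trajectory: list[LossValue]
    iterations_run: int
    seed: int
    converged: bool


def initialize_design(
    config: HallucinationConfig,
    wildtype: FvSequence,
    region: DesignRegion,
    rng: np.random.Generator,
) -> DesignMatrix:
    """Draw a_{i,AA} ~ U(0,1); wildtype seeding adds 0.5 to the wildtype letter.

    Disallowed letters are pinned at a −∞-like sentinel so they are never
    decoded.  Seeding a wildtype letter that is itself disallowed at its
    position is an error.
    """
    mask = config.resolve_mask(region.n_design)
    values = rng.uniform(0.0, 1.0, size=(region.n_design, N_AA))
    if config.seeding == "wildtype":
        for row, i in enumerate(region.design_positions):
            a = AA_TO_INDEX[wildtype.letter(i)]
            if not mask.allowed[row, a]:
                raise ValueError(
                    f"wildtype letter {wildtype.letter(i)!r} disallowed at design "
                    f"position {i} under wildtype seeding"
                )
            values[row, a] += 0.5
    values[~mask.allowed] = SENTINEL
    return DesignMatrix(values, region, mask.allowed.copy())


def decode(matrix: DesignMatrix) -> str:
    """Row-wise argmax of the softmax; ties break to the lowest alphabet index."""
    probs = matrix.softmax_rows()
    return "".join(ALPHABET[a] for a in probs.argmax(axis=1))


def _full_matrix(design_rows: np.ndarray, wildtype: FvSequence, region: DesignRegion) -> np.ndarray:
    """Assemble the (L, 20) matrix: fixed rows one-hot wildtype, design rows given."""
    L = len(wildtype)
    M = np.zeros((L, N_AA))
    for i in region.fixed_positions:
        M[i, AA_TO_INDEX[wildtype.letter(i)]] = 1.0
    M[list(region.design_positions)] = design_rows
    return M


def _one_hot(sub: str) -> np.ndarray:
    M = np.zeros((len(sub), N_AA))
    for r, aa in enumerate(sub):
        M[r, AA_TO_INDEX[aa]] = 1.0
    return M


def step(
    matrix: DesignMatrix,
    oracle,
    target,
    mask,
    wildtype: FvSequence,
    motif: MotifSpec | None,
    config: HallucinationConfig,
) -> tuple[DesignMatrix, LossValue, float]:
    """One normalized-SGD update.

    Returns the new matrix, the losses of the decoded sequence, and the
    total loss evaluated on the soft (softmax) rows.  The decoded loss is
    piecewise constant in the matrix, so the *soft* total is the quantity
    the convergence check watches: it keeps moving while the optimizer is
    still making progress between argmax flips.
    """
    region = matrix.region
    weights = config.effective_weights(motif)
    p_soft = matrix.softmax_rows()
    decoded = decode(matrix)
    hard_rows = _one_hot(decoded)

    M_hard = _full_matrix(hard_rows, wildtype, region)
    M_soft = _full_matrix(p_soft, wildtype, region)

    pred = oracle.forward(M_hard, mask)
    l_g = geometric_loss(pred, target, mask)

    # geometric gradient (straight-through: d one-hot / d softmax := identity)
    g_probs = geometric_loss_grad(pred, target, mask)
    g_geo_full = oracle.vjp(M_hard, mask, g_probs)

    l_s = l_m = 0.0
    g_seq_full = np.zeros_like(M_soft)
    g_mot_full = np.zeros_like(M_soft)
    if weights.w_s > 0:
        l_s = sequence_loss(M_soft, wildtype, region)
        g_seq_full = sequence_loss_grad(M_soft, wildtype, region)
    if weights.w_m > 0:
        motif.validate_region(region)
        l_m = motif_loss(M_soft, motif)
        g_mot_full = motif_loss_grad(M_soft, motif)

    loss = total_loss(l_g, l_s, l_m, weights)
    soft_l_g = geometric_loss(oracle.forward(M_soft, mask), target, mask)
    soft_total = total_loss(soft_l_g, l_s, l_m, weights).total

    design_idx = list(region.design_positions)
    g_p = (
        weights.w_g * g_geo_full[design_idx]
        + weights.w_s * g_seq_full[design_idx]
        + weights.w_m * g_mot_full[design_idx]
    )
    # softmax backward on each design row
    g_a = p_soft * (g_p - (g_p * p_soft).sum(axis=1, keepdims=True))
    g_a[~matrix.allowed] = 0.0

    if not np.isfinite(g_a).all():
        raise FloatingPointError("non-finite gradient in design update")

    norm = np.linalg.norm(g_a)
    new_values = matrix.values.copy()
    if norm >= 1e-12:
        new_values -= config.learning_rate * (g_a / norm)
        new_values[~matrix.allowed] = SENTINEL
    return DesignMatrix(new_values, region, matrix.allowed), loss, soft_total


def hallucinate(
    config: HallucinationConfig,
    oracle,
    target,
    mask,
    wildtype: FvSequence,
    region: DesignRegion,
    motif: MotifSpec | None = None,
) -> DesignRecord:
    """Run the full design loop and return the decoded design with its trajectory."""
    rng = np.random.default_rng(config.seed)
    matrix = initialize_design(config, wildtype, region, rng)
    trajectory: list[LossValue] = []
    soft_history: list[float] = []
    converged = False
    for it in range(config.max_iterations):
        matrix, loss, soft_total = step(
            matrix, oracle, target, mask, wildtype, motif, config
        )
        trajectory.append(loss)
        soft_history.append(soft_total)
        if config.loss_tolerance > 0 and len(soft_history) >= 6:
            window = soft_history[-6:]
            if max(window) - min(window) < config.loss_tolerance:
                converged = True
                break
    designed = decode(matrix)
    sequence = wildtype.with_substitution(region.design_positions, designed)
    return DesignRecord(
        sequence=sequence,
        designed_subsequence=designed,
        trajectory=trajectory,
        iterations_run=len(trajectory),
        seed=config.seed,
        converged=converged,
    )


def generate_library(
    config: HallucinationConfig,
    oracle,
    target,
    mask,
    wildtype: FvSequence,
    region: DesignRegion,
    n_designs: int,
    seed_base: int | None = None,
    motif: MotifSpec | None = None,
    deduplicate: bool = False,
) -> list[DesignRecord]:
    """n independent runs with seeds seed_base + k (seed_base defaults to config.seed)."""
    if n_designs < 1:
        raise ValueError("n_designs must be >= 1")
    base = config.seed if seed_base is None else seed_base
    records = []
    seen: set[str] = set()
    for k in range(n_designs):
        cfg = replace(config, seed=base + k)
        rec = hallucinate(cfg, oracle, target, mask, wildtype, region, motif)
        if deduplicate and rec.designed_subsequence in seen:
            continue
        seen.add(rec.designed_subsequence)
        records.append(rec)
    return records
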