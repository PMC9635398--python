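"""Sequence-library comparison metrics.

Covers amino-acid recovery (AAR), empirical PSSM construction, Bhattacharyya
coefficient/distance between profiles, per-position perplexity, Levenshtein
distance profiles against a reference set, and framework-region (FR)
enrichment scoring from a supplied score table.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .fv import AA_TO_INDEX, ALPHABET, N_AA, DesignRegion, FvSequence

#: floor applied to Bhattacharyya coefficients before taking the log
BD_FLOOR = 1e-6


@dataclass
class SequenceProfile:
    """A positions × 20 probability matrix (PSSM) over the fixed alphabet."""

    probs: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != N_AA:
            raise ValueError("profile must have shape (positions, 20)")
        if (self.probs < 0).any() or not np.allclose(
            self.probs.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("profile rows must be probability distributions")
        if self.labels is not None and len(self.labels) != self.probs.shape[0]:
            raise ValueError("label count must match position count")

    def __len__(self) -> int:
        return self.probs.shape[0]


def aar(designs, wildtype: FvSequence, region: DesignRegion) -> float:
    """Amino-acid recovery: % of design positions matching the wildtype,
    averaged over the library.

    ``designs`` are designed subsequences (aligned to the design region) or
    full-length Fv strings, mixed freely.
    """
    if not designs:
        raise ValueError("empty design list")
    d_idx = region.design_positions
    wt_sub = "".join(wildtype.letter(i) for i in d_idx)
    total = 0.0
    for seq in designs:
        sub = _design_subsequence(seq, region, wildtype)
        total += sum(a == b for a, b in zip(sub, wt_sub)) / len(d_idx)
    return 100.0 * total / len(designs)


def _design_subsequence(seq: str, region: DesignRegion, wildtype: FvSequence) -> str:
    if len(seq) == region.n_design:
        return seq
    if len(seq) == len(wildtype):
        return "".join(seq[i] for i in region.design_positions)
    raise ValueError(
        f"design of length {len(seq)} matches neither the design region "
        f"({region.n_design}) nor the full Fv ({len(wildtype)})"
    )


def build_pssm(seqs, labels=None) -> SequenceProfile:
    """Empirical per-position letter frequencies; no pseudo-counts."""
    if not seqs:
        raise ValueError("cannot build a PSSM from zero sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((n, N_AA))
    for s in seqs:
        for i, aa in enumerate(s):
            counts[i, AA_TO_INDEX[aa]] += 1
    return SequenceProfile(counts / len(seqs), tuple(labels) if labels else None)


def bhattacharyya(p: SequenceProfile, q: SequenceProfile):
    """Per-position and mean Bhattacharyya coefficient and distance.

    BC_i = Σ_AA √(p_i,AA · q_i,AA) ∈ [0, 1];  BD_i = −ln(max(BC_i, 1e−6)).
    Returns ``(bc, mean_bc, bd, mean_bd)``.
    """
    if len(p) != len(q):
        raise ValueError("profiles must cover the same positions")
    bc = np.sqrt(p.probs * q.probs).sum(axis=1)
    bd = -np.log(np.maximum(bc, BD_FLOOR))
    return bc, float(bc.mean()), bd, float(bd.mean())


def perplexity(profile: SequenceProfile) -> np.ndarray:
    """Per-position perplexity PP_i = 2^(−Σ p log₂ p), with 0·log 0 := 0.

    1 for a one-hot row (full conservation), 20 for a uniform row.
    """
    p = profile.probs
    plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return np.power(2.0, -plogp.sum(axis=1))


def levenshtein(a: str, b: str) -> int:
    """Exact edit distance (unit insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


def levenshtein_profile(designs, wildtype_sub: str, reference_set):
    """Per-design (LD to wildtype, min LD over a reference set) + joint histogram.

    Returns ``(ld_wt, ld_min_ref, histogram)`` where the histogram is a 2-D
    count table indexed [LD to wildtype, min LD to reference set].
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    ld_wt = np.array([levenshtein(d, wildtype_sub) for d in designs], dtype=int)
    ld_ref = np.array(
        [min(levenshtein(d, r) for r in reference_set) for d in designs], dtype=int
    )
    if len(designs):
        hist = np.zeros((ld_wt.max() + 1, ld_ref.max() + 1), dtype=int)
        np.add.at(hist, (ld_wt, ld_ref), 1)
    else:
        hist = np.zeros((1, 1), dtype=int)
    return ld_wt, ld_ref, hist


@dataclass
class FRScoreTable:
    """Framework-region enrichment scores: position label → letter → score."""

    scores: dict[str, dict[str, float]]

    def lookup(self, label: str, letter: str) -> float:
        try:
            return self.scores[label][letter]
        except KeyError:
            raise KeyError(f"no FR score for letter {letter!r} at position {label!r}") from None


def fr_score(
    design: str, region: DesignRegion, wildtype: FvSequence, table: FRScoreTable
) -> float:
    """Net FR score: sum of per-position scores of the designed letters."""
    sub = _design_subsequence(design, region, wildtype)
    labels = [wildtype.numbering[i].tag for i in region.design_positions]
    return float(sum(table.lookup(lab, aa) for lab, aa in zip(labels, sub)))
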