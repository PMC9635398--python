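"""Core value types for antibody Fv sequences, numbering and design regions.

The Fv (variable fragment) is the paired heavy (VH) and light (VL) domain of
an antibody.  Residues are addressed two ways throughout the package:

* by *chain + Chothia-style label* (e.g. ``H100A``) — the field convention,
  stable across antibodies, used in every file format we read or write;
* by *linear index* — 0-based position in the concatenated heavy+light
  sequence, heavy chain first, used internally by matrices and masks.

Numbering is consumed, never computed: annotation in the Chothia scheme (or
any scheme with per-chain labels and optional insertion codes) is an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 20-letter amino-acid alphabet in fixed alphabetical order.
#: Every probability matrix / PSSM in the package uses this column order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

N_AA: int = 20


def aa_index(letter: str) -> int:
    """Return the fixed alphabet index (0–19) of a one-letter code."""
    try:
        return AA_TO_INDEX[letter]
    except KeyError:
        raise ValueError(f"{letter!r} is not a canonical amino acid") from None


def aa_letter(index: int) -> str:
    """Inverse of :func:`aa_index`."""
    if not 0 <= index < N_AA:
        raise ValueError(f"amino-acid index {index} out of range 0..19")
    return ALPHABET[index]


@dataclass(frozen=True)
class ResiduePosition:
    """One residue slot in the Fv.

    Parameters
    ----------
    chain
        ``"H"`` or ``"L"``.
    label
        Chothia-style number with optional insertion code, e.g. ``"100A"``.
    linear_index
        0-based position in the concatenated H+L sequence.
    """

    chain: str
    label: str
    linear_index: int

    def __post_init__(self):
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")

    @property
    def tag(self) -> str:
        """Chain-qualified label, e.g. ``H100A``."""
        return f"{self.chain}{self.label}"


@dataclass(frozen=True)
class FvSequence:
    """An Fv amino-acid sequence with its residue numbering."""

    heavy: str
    light: str
    numbering: tuple[ResiduePosition, ...]

    @property
    def full(self) -> str:
        return self.heavy + self.light

    def __len__(self) -> int:
        return len(self.heavy) + len(self.light)

    def position(self, tag: str) -> ResiduePosition:
        """Resolve a chain-qualified label like ``H100A`` to a position."""
        for pos in self.numbering:
            if pos.tag == tag:
                return pos
        raise KeyError(f"no residue with label {tag!r} in this Fv")

    def letter(self, linear_index: int) -> str:
        return self.full[linear_index]

    def with_substitution(self, linear_indices, letters: str) -> "FvSequence":
        """Return a copy with ``letters`` substituted at ``linear_indices``."""
        chars = list(self.full)
        for idx, aa in zip(linear_indices, letters, strict=True):
            chars[idx] = aa
        nh = len(self.heavy)
        seq = "".join(chars)
        return FvSequence(seq[:nh], seq[nh:], self.numbering)


def concatenate_fv(heavy: str, light: str, numbering) -> FvSequence:
    """Build an :class:`FvSequence` from chain strings and a numbering list.

    ``numbering`` is a sequence of ``(chain, label)`` pairs (or
    :class:`ResiduePosition` objects whose linear indices are reassigned)
    covering every residue, heavy chain first.  Linear indices are assigned
    0-based, H first then L.

    Raises
    ------
    ValueError
        If a sequence is empty, contains a non-canonical letter (the error
        names the offending chain position), or the numbering length does
        not match the residue count.
    """
    if not heavy or not light:
        raise ValueError("heavy and light sequences must be non-empty")
    for chain_name, seq in (("H", heavy), ("L", light)):
        for i, aa in enumerate(seq):
            if aa not in AA_TO_INDEX:
                raise ValueError(
                    f"non-canonical amino acid {aa!r} at {chain_name} position {i + 1}"
                )
    total = len(heavy) + len(light)
    if len(numbering) != total:
        raise ValueError(
            f"numbering has {len(numbering)} entries but Fv has {total} residues"
        )
    positions = []
    for idx, entry in enumerate(numbering):
        if isinstance(entry, ResiduePosition):
            chain, label = entry.chain, entry.label
        else:
            chain, label = entry
        expected_chain = "H" if idx < len(heavy) else "L"
        if chain != expected_chain:
            raise ValueError(
                f"numbering entry {idx} has chain {chain!r}, expected {expected_chain!r}"
            )
        positions.append(ResiduePosition(chain, str(label), idx))
    tags = [p.tag for p in positions]
    if len(set(tags)) != len(tags):
        dup = next(t for t in tags if tags.count(t) > 1)
        raise ValueError(f"duplicate residue label {dup!r}")
    return FvSequence(heavy, light, tuple(positions))


def default_numbering(heavy: str, light: str) -> list[tuple[str, str]]:
    """Sequential per-chain numbering (1..n), a stand-in when no scheme is given."""
    return [("H", str(i + 1)) for i in range(len(heavy))] + [
        ("L", str(i + 1)) for i in range(len(light))
    ]


@dataclass(frozen=True)
class DesignRegion:
    """The split of the Fv into designable (D) and fixed (F) positions."""

    design_positions: tuple[int, ...]
    fixed_positions: tuple[int, ...]

    def __post_init__(self):
        d, f = set(self.design_positions), set(self.fixed_positions)
        if not self.design_positions:
            raise ValueError("design region must contain at least one position")
        if d & f:
            raise ValueError("design and fixed position sets overlap")
        if len(d) != len(self.design_positions):
            raise ValueError("duplicate design positions")

    @property
    def n_design(self) -> int:
        return len(self.design_positions)

    @property
    def all_positions(self) -> frozenset[int]:
        return frozenset(self.design_positions) | frozenset(self.fixed_positions)


def make_design_region(fv: FvSequence, labels) -> DesignRegion:
    """Resolve chain-qualified labels (e.g. ``["H95", ..., "H100A"]``) to a region.

    Order of ``labels`` is preserved in ``design_positions``; the fixed set is
    the complement in ascending linear order.
    """
    if not labels:
        raise ValueError("design region must contain at least one position")
    design = tuple(fv.position(tag).linear_index for tag in labels)
    chosen = set(design)
    fixed = tuple(i for i in range(len(fv)) if i not in chosen)
    return DesignRegion(design, fixed)


@dataclass
class AlphabetMask:
    """Per-design-position allowed amino-acid subsets.

    ``allowed`` is a boolean array of shape (n_design, 20); every row must
    keep at least one letter.  The common construction is
    :meth:`disallowing` which removes a fixed letter set (default cysteine)
    everywhere.
    """

    allowed: np.ndarray

    def __post_init__(self):
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if self.allowed.ndim != 2 or self.allowed.shape[1] != N_AA:
            raise ValueError("alphabet mask must have shape (n_design, 20)")
        if not self.allowed.any(axis=1).all():
            raise ValueError("every design position needs at least one allowed letter")

    @classmethod
    def full(cls, n_design: int) -> "AlphabetMask":
        return cls(np.ones((n_design, N_AA), dtype=bool))

    @classmethod
    def disallowing(cls, n_design: int, letters="C") -> "AlphabetMask":
        allowed = np.ones((n_design, N_AA), dtype=bool)
        for aa in letters:
            allowed[:, aa_index(aa)] = False
        return cls(allowed)

    def permits(self, position: int, letter: str) -> bool:
        return bool(self.allowed[position, aa_index(letter)])
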