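"""Synthetic study fixtures: toy Fv sequences, backbone coordinate sets, and
random CDR libraries with known statistics.

Everything here is deterministic per seed.  The toy backbone is a
self-avoiding 3-D walk with the canonical 3.8 Å Cα–Cα virtual-bond spacing,
decorated with N/C/O/CB atoms in a local frame — good enough to exercise
every geometry, binning and RMSD code path while remaining tiny.  Libraries
drawn from a specified PSSM give the evaluation metrics known expectations.
These fixtures emulate the *shape* of real inputs, not antibody physics:
they carry no secondary structure, packing or chain pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fv import ALPHABET, N_AA, FvSequence, concatenate_fv, default_numbering
from .geometry import StructureCoordinates
from .library_eval import SequenceProfile

CA_SPACING = 3.8  # Å, canonical trans-peptide Cα–Cα virtual bond


@dataclass
class FixtureSpec:
    """Sizes and randomness of a synthetic design problem."""

    n_heavy: int = 12
    n_light: int = 8
    n_design_positions: int = 3
    oracle_seed: int = 7
    library_size: int = 50
    coordinate_noise: float = 0.0  # Å, optional jitter on all atoms

    def __post_init__(self):
        if min(self.n_heavy, self.n_light, self.n_design_positions, self.library_size) < 1:
            raise ValueError("all fixture sizes must be >= 1")
        if self.n_design_positions > self.n_heavy:
            raise ValueError("design positions must fit in the heavy chain")


def random_fv(spec: FixtureSpec, rng: np.random.Generator) -> FvSequence:
    """A random Fv (no cysteines, so default design masks accept the wildtype)."""
    letters = [aa for aa in ALPHABET if aa != "C"]
    heavy = "".join(rng.choice(letters, size=spec.n_heavy))
    light = "".join(rng.choice(letters, size=spec.n_light))
    return concatenate_fv(heavy, light, default_numbering(heavy, light))


def self_avoiding_walk(n: int, rng: np.random.Generator, min_separation: float = 3.0,
                       max_tries: int = 200) -> np.ndarray:
    """Cα trace: steps of length 3.8 Å avoiding close non-neighbor approaches."""
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(1, n):
        for _ in range(max_tries):
            perturb = rng.normal(scale=0.8, size=3)
            cand_dir = direction + perturb
            cand_dir /= np.linalg.norm(cand_dir)
            cand = pts[-1] + CA_SPACING * cand_dir
            if len(pts) < 2 or min(
                np.linalg.norm(cand - p) for p in pts[:-1]
            ) >= min_separation:
                break
        pts.append(cand)
        direction = cand_dir
    return np.asarray(pts)


def toy_coordinates(
    n_residues: int,
    rng: np.random.Generator,
    glycine_at: tuple[int, ...] = (),
    noise: float = 0.0,
) -> StructureCoordinates:
    """Backbone coordinates around a self-avoiding Cα walk.

    N, C, O and CB are placed at fixed offsets in a local frame built from
    the walk direction, so all six geometry channels are well defined.
    Residues listed in ``glycine_at`` get no CB.
    """
    ca = self_avoiding_walk(n_residues, rng)
    atoms = {name: np.zeros((n_residues, 3)) for name in ("N", "CA", "C", "O", "CB")}
    atoms["CA"] = ca
    has_cb = np.ones(n_residues, dtype=bool)
    has_cb[list(glycine_at)] = False
    for i in range(n_residues):
        fwd = ca[min(i + 1, n_residues - 1)] - ca[max(i - 1, 0)]
        fwd /= np.linalg.norm(fwd)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(fwd @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        side = np.cross(fwd, helper)
        side /= np.linalg.norm(side)
        up = np.cross(fwd, side)
        atoms["N"][i] = ca[i] - 1.46 * fwd + 0.3 * side
        atoms["C"][i] = ca[i] + 1.52 * fwd + 0.2 * side
        atoms["O"][i] = atoms["C"][i] + 1.23 * up
        atoms["CB"][i] = ca[i] + 1.53 * (0.5 * side + 0.6 * up - 0.3 * fwd)
    if noise > 0:
        for name in atoms:
            atoms[name] = atoms[name] + rng.normal(scale=noise, size=(n_residues, 3))
    return StructureCoordinates(atoms, has_cb)


def library_from_pssm(
    profile: SequenceProfile, n: int, rng: np.random.Generator
) -> list[str]:
    """Draw n sequences position-independently from a PSSM."""
    out = []
    for _ in range(n):
        out.append(
            "".join(
                ALPHABET[rng.choice(N_AA, p=profile.probs[i])]
                for i in range(len(profile))
            )
        )
    return out


def generate_fixtures(spec: FixtureSpec, rng: np.random.Generator):
    """Toy Fv + coordinates + design region + reference library, all seeded.

    Returns a dict with keys ``fv``, ``coords``, ``region``,
    ``reference_profile`` and ``reference_library``.  The design region is
    a contiguous stretch in the middle of the heavy chain (a stand-in for
    a CDR loop).
    """
    from .fv import make_design_region

    fv = random_fv(spec, rng)
    n_total = len(fv)
    coords = toy_coordinates(n_total, rng, noise=spec.coordinate_noise)
    start = max(0, spec.n_heavy // 2 - spec.n_design_positions // 2)
    labels = [fv.numbering[start + k].tag for k in range(spec.n_design_positions)]
    region = make_design_region(fv, labels)

    # reference profile: Dirichlet rows, mildly concentrated
    probs = rng.dirichlet(np.full(N_AA, 0.5), size=spec.n_design_positions)
    profile = SequenceProfile(probs)
    library = library_from_pssm(profile, spec.library_size, rng)
    return {
        "fv": fv,
        "coords": coords,
        "region": region,
        "reference_profile": profile,
        "reference_library": library,
    }
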