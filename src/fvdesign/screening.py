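"""Fold/bind screening of a designed library.

Two gates turn a structure-conditioned library into a target-specific one:

* **fold gate** — each design is folded by an adapter (``sequence →
  backbone coordinates``); the design-region backbone RMSD against the
  target, after superposing on the framework (non-design) backbone, must
  not exceed a threshold (default 2.0 Å).  RMSDs use N/CA/C atoms,
  excluding O.
* **bind gate** — an adapter returns a list of decoy binding free energies
  (REU) per design; the design's ΔG is the minimum over decoys (default 5)
  and must be ≤ wildtype reference ΔG + margin.

The screened library is the intersection of the two pass sets.  External
folding/energy engines talk to the pipeline only through these adapter
callables, so everything here runs offline with the bundled mocks.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .fv import DesignRegion
from .geometry import StructureCoordinates
from .library_eval import SequenceProfile, build_pssm

logger = logging.getLogger(__name__)

RMSD_ATOMS = ("N", "CA", "C")  # backbone heavy atoms, O excluded


@dataclass
class FoldResult:
    design_id: str
    coordinates: StructureCoordinates | None
    rmsd_design_region: float
    per_residue_rmsd: np.ndarray
    failed: bool = False


@dataclass
class BindResult:
    design_id: str
    dG: float
    n_decoys: int
    failed: bool = False


@dataclass
class ScreeningThresholds:
    rmsd_max: float = 2.0
    dG_reference: float = 0.0
    dG_margin: float = 0.0


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of two matched point sets.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``moved = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matched (N, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    if np.linalg.matrix_rank(mobile - mobile.mean(axis=0)) < 2:
        raise ValueError("points are collinear; superposition is degenerate")
    sup = SVDSuperimposer()
    sup.set(reference, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    return rot.T, tran, float(sup.get_rms())


def _stack_atoms(coords: StructureCoordinates, residues, atoms=RMSD_ATOMS) -> np.ndarray:
    return np.concatenate([coords.atoms[a][list(residues)] for a in atoms], axis=0)


def design_region_rmsd(
    folded: StructureCoordinates,
    target: StructureCoordinates,
    region: DesignRegion,
):
    """Design-region backbone RMSD after framework superposition.

    The folded model is superposed onto the target using N/CA/C of all
    *non-design* residues, then the RMSD is measured over N/CA/C of the
    design residues in that frame.  Also returns per-residue RMSDs from
    the same frame.
    """
    if len(folded) != len(target):
        raise ValueError("folded and target structures differ in residue count")
    if not region.design_positions:
        raise ValueError("design region is empty")
    framework = sorted(region.fixed_positions)
    rot, tran, _ = kabsch_superpose(
        _stack_atoms(folded, framework), _stack_atoms(target, framework)
    )
    moved = folded.transformed(rot, tran)
    d_idx = list(region.design_positions)
    diff = _stack_atoms(moved, d_idx) - _stack_atoms(target, d_idx)
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    per_res = np.empty(len(d_idx))
    for k, i in enumerate(d_idx):
        dd = np.stack([moved.atoms[a][i] - target.atoms[a][i] for a in RMSD_ATOMS])
        per_res[k] = np.sqrt((dd**2).sum(axis=1).mean())
    return rmsd, per_res


def screen_folding(designs: dict, folder, target, region, thresholds: ScreeningThresholds):
    """Fold every design and keep those with design-region RMSD ≤ rmsd_max.

    ``designs`` maps design id → sequence; ``folder(sequence)`` returns
    StructureCoordinates.  Adapter failures mark the design failed and the
    run continues.
    """
    results: dict[str, FoldResult] = {}
    passed: set[str] = set()
    for did, seq in designs.items():
        try:
            coords = folder(seq)
            rmsd, per_res = design_region_rmsd(coords, target, region)
        except Exception as exc:  # adapter failure is a per-design event
            logger.warning("fold adapter failed for %s: %s", did, exc)
            results[did] = FoldResult(did, None, np.inf, np.empty(0), failed=True)
            continue
        results[did] = FoldResult(did, coords, rmsd, per_res)
        if rmsd <= thresholds.rmsd_max:
            passed.add(did)
    return passed, results


def screen_binding(
    designs: dict, binder, thresholds: ScreeningThresholds, n_decoys: int = 5
):
    """Score every design; ΔG = min over decoys; pass iff ΔG ≤ reference + margin."""
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    results: dict[str, BindResult] = {}
    passed: set[str] = set()
    for did, seq in designs.items():
        try:
            dgs = list(binder(seq, n_decoys))
            if len(dgs) != n_decoys:
                raise ValueError(f"binder returned {len(dgs)} decoys, expected {n_decoys}")
            dg = float(min(dgs))
        except Exception as exc:
            logger.warning("bind adapter failed for %s: %s", did, exc)
            results[did] = BindResult(did, np.inf, 0, failed=True)
            continue
        results[did] = BindResult(did, dg, n_decoys)
        if dg <= thresholds.dG_reference + thresholds.dG_margin:
            passed.add(did)
    return passed, results


@dataclass
class ScreeningReport:
    screened: set[str]
    fold_pass: set[str]
    bind_pass: set[str]
    fold_results: dict[str, FoldResult]
    bind_results: dict[str, BindResult]
    screened_profile: SequenceProfile | None

    @property
    def counts(self) -> dict[str, int]:
        return {
            "designs": len(self.fold_results),
            "fold_pass": len(self.fold_pass),
            "bind_pass": len(self.bind_pass),
            "screened": len(self.screened),
        }


def run_pipeline(
    designs: dict,
    folder,
    binder,
    target,
    region,
    thresholds: ScreeningThresholds,
    n_decoys: int = 5,
) -> ScreeningReport:
    """Fold gate ∩ bind gate, with per-design metrics and a screened-set PSSM."""
    fold_pass, fold_results = screen_folding(designs, folder, target, region, thresholds)
    bind_pass, bind_results = screen_binding(designs, binder, thresholds, n_decoys)
    screened = fold_pass & bind_pass
    profile = None
    if screened:
        d_idx = list(region.design_positions)
        subs = ["".join(designs[i][k] for k in d_idx) for i in sorted(screened)]
        profile = build_pssm(subs)
    return ScreeningReport(screened, fold_pass, bind_pass, fold_results, bind_results, profile)


# ---------------------------------------------------------------------------
# Mock adapters (offline stand-ins for folding / interface-energy engines)


class MockFolder:
    """Synthetic fold adapter: returns the target, optionally displacing the
    design region by a per-design seeded amount.

    ``displacement_sampler(rng) -> Å`` controls the shift applied uniformly
    to the design-region atoms; default 0 (perfect fold).
    """

    def __init__(self, target: StructureCoordinates, region: DesignRegion, seed: int = 0,
                 displacement_sampler=None):
        self.target = target
        self.region = region
        self.seed = seed
        self.displacement_sampler = displacement_sampler

    def __call__(self, sequence: str) -> StructureCoordinates:
        atoms = {k: v.copy() for k, v in self.target.atoms.items()}
        if self.displacement_sampler is not None:
            rng = np.random.default_rng((self.seed, zlib.crc32(sequence.encode())))
            shift = float(self.displacement_sampler(rng))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for name in atoms:
                atoms[name][list(self.region.design_positions)] += shift * direction
        return StructureCoordinates(atoms, self.target.has_cb.copy())


class MockBinder:
    """Synthetic interface-energy adapter with seeded per-design decoy draws."""

    def __init__(self, seed: int = 0, mean: float = -30.0, spread: float = 5.0):
        self.seed = seed
        self.mean = mean
        self.spread = spread

    def decoys(self, sequence: str, n_decoys: int) -> list[float]:
        rng = np.random.default_rng((self.seed, zlib.crc32(sequence.encode())))
        return list(self.mean + self.spread * rng.standard_normal(n_decoys))

    def __call__(self, sequence: str, n_decoys: int) -> list[float]:
        return self.decoys(sequence, n_decoys)
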