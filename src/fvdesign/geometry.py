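"""Binned inter-residue geometry of a target backbone.

The target structure enters the design objective only through six pairwise
channels — three distances and three orientations — discretized into bins:

=========  =============================  =========  ==========
channel    atoms                          symmetry   range
=========  =============================  =========  ==========
``d_ca``   CAi – CAj distance             symmetric  [0, ∞) Å
``d_cb``   CBi – CBj distance             symmetric  [0, ∞) Å
``d_no``   Ni – Oj distance               ordered    [0, ∞) Å
``omega``  CAi–CBi–CBj–CAj dihedral       symmetric  (−180, 180]°
``theta``  Ni–CAi–CBi–CBj dihedral        ordered    (−180, 180]°
``phi``    CAi–CBi–CBj planar angle       ordered    [0, 180]°
=========  =============================  =========  ==========

Orientation definitions follow the trRosetta convention.  Channels that
need a CB atom are masked invalid for glycine pairs; diagonals are always
invalid.  Distances past the last bin edge fall into a catch-all bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fv import DesignRegion

CHANNELS: tuple[str, ...] = ("d_ca", "d_cb", "d_no", "omega", "theta", "phi")

DISTANCE_CHANNELS = ("d_ca", "d_cb", "d_no")
#: channels whose L×L matrix equals its transpose
SYMMETRIC_CHANNELS = ("d_ca", "d_cb", "omega")
#: channels that require a CB atom on both residues
CB_CHANNELS = ("d_cb", "omega", "theta", "phi")

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass
class StructureCoordinates:
    """Backbone coordinates aligned to Fv linear indices.

    ``atoms`` maps atom name (N, CA, C, O, CB) to an (L, 3) float array in Å.
    ``has_cb`` flags residues with a real CB (False for glycine).
    """

    atoms: dict[str, np.ndarray]
    has_cb: np.ndarray

    def __post_init__(self):
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in self.atoms:
                raise ValueError(f"missing coordinates for atom {name}")
            self.atoms[name] = np.asarray(self.atoms[name], dtype=float)
        self.has_cb = np.asarray(self.has_cb, dtype=bool)
        L = self.atoms["CA"].shape[0]
        for name, arr in self.atoms.items():
            if arr.shape != (L, 3):
                raise ValueError(f"atom {name} has shape {arr.shape}, expected ({L}, 3)")
            finite = np.isfinite(arr).all(axis=1)
            if name == "CB":
                if not finite[self.has_cb].all():
                    bad = int(np.where(self.has_cb & ~finite)[0][0])
                    raise ValueError(f"non-finite CB coordinates at residue {bad}")
            elif not finite.all():
                bad = int(np.where(~finite)[0][0])
                raise ValueError(f"non-finite {name} coordinates at residue {bad}")

    def __len__(self) -> int:
        return self.atoms["CA"].shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureCoordinates":
        """Apply a rigid transform x ↦ xR^T + t to every atom."""
        new = {k: v @ np.asarray(rotation).T + translation for k, v in self.atoms.items()}
        return StructureCoordinates(new, self.has_cb.copy())


def _dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle in degrees, (−180, 180]; broadcastable over leading axes."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    ang = np.degrees(np.arctan2(y, x))
    # map −180 exactly onto +180 so the range is (−180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def _planar_angle(p0, p1, p2) -> np.ndarray:
    """Angle at p1 in degrees, [0, 180]."""
    v1 = p0 - p1
    v2 = p2 - p1
    cos = (v1 * v2).sum(-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def compute_pair_geometries(coords: StructureCoordinates):
    """Raw (un-binned) L×L matrices for all six channels plus validity masks.

    Returns ``(values, valid)``: two dicts keyed by channel.  Entry (i, j)
    of an ordered channel refers to the ordered pair i→j.  Diagonals and
    CB-dependent entries of glycine pairs are marked invalid; their values
    are left at 0 and must not be read.
    """
    L = len(coords)
    ca = coords.atoms["CA"]
    cb = coords.atoms["CB"]
    n = coords.atoms["N"]
    o = coords.atoms["O"]

    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}

    off_diag = ~np.eye(L, dtype=bool)
    cb_pair = coords.has_cb[:, None] & coords.has_cb[None, :]

    def pdist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    values["d_ca"] = pdist(ca, ca)
    values["d_cb"] = np.where(cb_pair, pdist(cb, cb), 0.0)
    values["d_no"] = pdist(n, o)

    i_idx, j_idx = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = _dihedral(ca[i_idx], cb[i_idx], cb[j_idx], ca[j_idx])
        theta = _dihedral(n[i_idx], ca[i_idx], cb[i_idx], cb[j_idx])
        phi = _planar_angle(ca[i_idx], cb[i_idx], cb[j_idx])
    values["omega"] = np.where(cb_pair & off_diag, omega, 0.0)
    values["theta"] = np.where(cb_pair & off_diag, theta, 0.0)
    values["phi"] = np.where(cb_pair & off_diag, phi, 0.0)

    for ch in CHANNELS:
        v = off_diag.copy()
        if ch in CB_CHANNELS:
            v &= cb_pair
        valid[ch] = v
    return values, valid


@dataclass(frozen=True)
class GeometryBinning:
    """Monotone bin edges per channel.

    Distance channels get one catch-all bin past the last edge; angular
    channels must cover their full range.  A value in [edge_k, edge_{k+1})
    gets label k (half-open convention, ties go up).
    """

    edges: dict[str, np.ndarray]

    def __post_init__(self):
        for ch in CHANNELS:
            if ch not in self.edges:
                raise ValueError(f"missing bin edges for channel {ch}")
            e = np.asarray(self.edges[ch], dtype=float)
            if e.ndim != 1 or e.size < 3:
                raise ValueError(f"channel {ch} needs >= 2 bins")
            if not (np.diff(e) > 0).all():
                raise ValueError(f"bin edges for {ch} must be strictly increasing")
            self.edges[ch] = e

    def n_bins(self, channel: str) -> int:
        base = len(self.edges[channel]) - 1
        return base + 1 if channel in DISTANCE_CHANNELS else base

    @classmethod
    def default(cls) -> "GeometryBinning":
        """0.5 Å distance bins to 20 Å (+ catch-all), 15° dihedral, 12° planar bins."""
        dist = np.arange(0.0, 20.0 + 1e-9, 0.5)
        dihedral = np.arange(-180.0, 180.0 + 1e-9, 15.0)
        planar = np.arange(0.0, 180.0 + 1e-9, 12.0)
        return cls(
            {
                "d_ca": dist.copy(),
                "d_cb": dist.copy(),
                "d_no": dist.copy(),
                "omega": dihedral.copy(),
                "theta": dihedral.copy(),
                "phi": planar.copy(),
            }
        )

    @classmethod
    def uniform(cls, n_bins: int) -> "GeometryBinning":
        """Equal bin count on every channel; handy for toy-oracle work.

        Distance channels get ``n_bins - 1`` regular bins plus the
        catch-all so every channel ends up with exactly ``n_bins`` labels.
        """
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        return cls(
            {
                "d_ca": np.linspace(0.0, 20.0, n_bins),
                "d_cb": np.linspace(0.0, 20.0, n_bins),
                "d_no": np.linspace(0.0, 20.0, n_bins),
                "omega": np.linspace(-180.0, 180.0, n_bins + 1),
                "theta": np.linspace(-180.0, 180.0, n_bins + 1),
                "phi": np.linspace(0.0, 180.0, n_bins + 1),
            }
        )


@dataclass
class TargetGeometry:
    """Binned pairwise labels of the target structure, one L×L map per channel."""

    labels: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    binning: GeometryBinning

    def __len__(self) -> int:
        return self.labels["d_ca"].shape[0]


def discretize(values: dict, valid: dict, binning: GeometryBinning) -> TargetGeometry:
    """Assign each valid raw geometry value to its bin label.

    Half-open bins [edge_k, edge_{k+1}); distances beyond the last edge go
    to the catch-all bin; a distance below 0 is an error.
    """
    labels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        e = binning.edges[ch]
        v = np.asarray(values[ch], dtype=float)
        mask = valid[ch]
        if ch in DISTANCE_CHANNELS:
            if (v[mask] < e[0]).any():
                raise ValueError(f"distance below first bin edge in channel {ch}")
            # searchsorted 'right' gives half-open [e_k, e_{k+1}); overflow -> catch-all
            lab = np.searchsorted(e, v, side="right") - 1
            lab = np.minimum(lab, len(e) - 1)  # catch-all = last regular + 1
        else:
            below = mask & (v < e[0])
            above = mask & (v > e[-1])
            if below.any() or above.any():
                raise ValueError(f"angle outside binning range in channel {ch}")
            lab = np.searchsorted(e, v, side="right") - 1
            lab = np.clip(lab, 0, len(e) - 2)  # top edge closes the last bin
        lab = np.where(mask, lab, -1)
        labels[ch] = lab.astype(np.int64)
    return TargetGeometry(labels, {ch: valid[ch].copy() for ch in CHANNELS}, binning)


def geometry_from_coords(
    coords: StructureCoordinates, binning: GeometryBinning | None = None
) -> TargetGeometry:
    """Convenience: compute raw channels then discretize."""
    if binning is None:
        binning = GeometryBinning.default()
    values, valid = compute_pair_geometries(coords)
    return discretize(values, valid, binning)


@dataclass(frozen=True)
class ContactMask:
    """Ordered contact pairs (i ∈ D, j ≠ i) with Cα–Cα distance ≤ cutoff.

    The loss normalizer C is the ordered-pair count: a contact with both
    endpoints designable contributes both (i, j) and (j, i).
    """

    pairs: tuple[tuple[int, int], ...]
    cutoff: float = 10.0

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]


def build_contact_mask(
    coords: StructureCoordinates, region: DesignRegion, cutoff: float = 10.0
) -> ContactMask:
    """Enumerate ordered pairs C = Σ_{i∈D} Σ_{j∈S, j≠i} [d_CA(i,j) ≤ cutoff]."""
    if not region.design_positions:
        raise ValueError("design region is empty")
    ca = coords.atoms["CA"]
    L = ca.shape[0]
    pairs = []
    for i in region.design_positions:
        d = np.linalg.norm(ca - ca[i], axis=1)
        for j in range(L):
            if j != i and d[j] <= cutoff:
                pairs.append((i, j))
    return ContactMask(tuple(pairs), cutoff)
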