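"""Sequence-level developability metrics.

Three liabilities computable from sequence alone, each with its own
windowing convention:

* **instability index** — Guruprasad dipeptide-weight sum over the *full
  heavy chain* (values > 40 suggest an unstable protein);
* **GRAVY** — mean Kyte–Doolittle hydropathy of the *designed region padded
  by 10 residues on either side* (clipped at chain boundaries); positive
  values are hydrophobic;
* **net charge** — Henderson–Hasselbalch sum over ionizable side chains and
  termini of the *full Fv* at a configurable pH (default 7.0, EMBOSS pKa
  values).

Dipeptide and hydropathy tables come from Biopython's published ProtParam
data.  Structure-based properties (aggregation patches, solubility) need
external tools and are deliberately not imitated here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import ProtParamData

from .fv import DesignRegion, FvSequence

#: EMBOSS pKa set; negative groups first, then positive
PKA_NEGATIVE = {"C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}
PKA_POSITIVE = {"H": 6.5, "K": 10.8, "R": 12.5}
PKA_NTERM = 8.6
PKA_CTERM = 3.6


@dataclass
class DevelopabilityReport:
    instability_index: float
    gravy: float
    net_charge: float


def instability_index(heavy: str) -> float:
    """II = (10/L) · Σ_{i=1..L−1} DIWV(x_i, x_{i+1}) over the heavy chain."""
    if len(heavy) < 2:
        raise ValueError("instability index needs at least 2 residues")
    diwv = ProtParamData.DIWV
    total = sum(diwv[heavy[i]][heavy[i + 1]] for i in range(len(heavy) - 1))
    return 10.0 / len(heavy) * total


def gravy_window(chain: str, start: int, stop: int, pad: int = 10) -> str:
    """The designed stretch [start, stop) padded ±pad, clipped to the chain."""
    lo = max(0, start - pad)
    hi = min(len(chain), stop + pad)
    return chain[lo:hi]


def gravy(window: str) -> float:
    """Grand average of Kyte–Doolittle hydropathy over a window."""
    if not window:
        raise ValueError("empty GRAVY window")
    kd = ProtParamData.kd
    return sum(kd[aa] for aa in window) / len(window)


def net_charge(sequence: str, pH: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge of a chain/Fv at the given pH.

    Each positive group contributes 1/(1+10^(pH−pKa)), each negative group
    −1/(1+10^(pKa−pH)); free N- and C-termini are included once.
    """
    pos = 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM))
    neg = -1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
    for aa in sequence:
        if aa in PKA_POSITIVE:
            pos += 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            neg -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - pH))
    return pos + neg


def developability_report(
    fv: FvSequence, region: DesignRegion, pH: float = 7.0, pad: int = 10
) -> DevelopabilityReport:
    """Apply the three windowing conventions to one designed Fv.

    The GRAVY window spans the contiguous extent of the design positions on
    their chain; design regions spanning both chains are windowed on the
    concatenated sequence (a pad never crosses a real chain boundary in the
    intended CDR / interface use).
    """
    d = sorted(region.design_positions)
    nh = len(fv.heavy)
    if max(d) < nh:  # all-heavy design region: clip inside the heavy chain
        window = gravy_window(fv.heavy, d[0], d[-1] + 1, pad)
    elif min(d) >= nh:
        window = gravy_window(fv.light, d[0] - nh, d[-1] - nh + 1, pad)
    else:
        window = gravy_window(fv.full, d[0], d[-1] + 1, pad)
    return DevelopabilityReport(
        instability_index=instability_index(fv.heavy),
        gravy=gravy(window),
        net_charge=net_charge(fv.full, pH),
    )
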