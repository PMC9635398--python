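"""Readers and writers for the formats the package touches.

FASTA (``>name|chain`` headers), PDB backbone subsets (ATOM records for
N/CA/C/O/CB), numbering maps and PSSM / FR-score tables as TSV, loss
trajectories and screening reports as CSV, and YAML/JSON run configs.
File-side residue numbering is 1-based with insertion codes; everything
internal is 0-based — the conversion happens only in this module.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fv import ALPHABET, FvSequence, ResiduePosition, concatenate_fv
from .geometry import BACKBONE_ATOMS, StructureCoordinates
from .library_eval import FRScoreTable, SequenceProfile


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Return (header, sequence) pairs; wrapping-insensitive."""
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records) -> None:
    """``records`` are (header, sequence) pairs."""
    seq_records = [
        SeqRecord(Seq(seq), id=header, description="") for header, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- numbering maps ---------------------------------------------------------

def read_numbering_map(path) -> list[tuple[str, str]]:
    """TSV with columns chain, label, sequence_index (1-based in the file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("chain", "label", "sequence_index"):
        if col not in df.columns:
            raise ValueError(f"numbering map is missing column {col!r}")
    df = df.assign(sequence_index=df.sequence_index.astype(int)).sort_values(
        "sequence_index"
    )
    if list(df.sequence_index) != list(range(1, len(df) + 1)):
        raise ValueError("numbering map sequence_index must run 1..n without gaps")
    return [(row.chain, row.label) for row in df.itertuples()]


def write_numbering_map(path, numbering) -> None:
    rows = [
        {"chain": pos.chain, "label": pos.label, "sequence_index": pos.linear_index + 1}
        for pos in numbering
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fv(fasta_path, numbering_path) -> FvSequence:
    """Assemble an FvSequence from a two-record FASTA and a numbering map."""
    chains = {}
    for header, seq in read_fasta(fasta_path):
        chain = header.rsplit("|", 1)[-1].strip()
        if chain not in ("H", "L"):
            raise ValueError(f"FASTA header {header!r} does not end in |H or |L")
        chains[chain] = seq
    if set(chains) != {"H", "L"}:
        raise ValueError("Fv FASTA must contain exactly one H and one L record")
    return concatenate_fv(chains["H"], chains["L"], read_numbering_map(numbering_path))


# -- PDB backbone -----------------------------------------------------------

def read_pdb_backbone(path, chain_map: dict[str, str] | None = None) -> tuple[
    StructureCoordinates, list[tuple[str, str]]
]:
    """Read N/CA/C/O/CB coordinates for the H then L chain of a PDB file.

    ``chain_map`` maps PDB chain ids to ``H``/``L`` (default: ``H``→H,
    ``L``→L).  Returns the coordinates plus the (chain, label) numbering
    read from residue ids (insertion codes preserved).  Glycines may lack
    CB; any other missing backbone atom is an error naming the residue.
    """
    chain_map = chain_map or {"H": "H", "L": "L"}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("fv", str(path))
    model = next(structure.get_models())
    by_fv_chain: dict[str, list] = {"H": [], "L": []}
    for pdb_chain in model:
        fv_chain = chain_map.get(pdb_chain.id)
        if fv_chain is None:
            continue
        for res in pdb_chain:
            if res.id[0] != " ":  # skip HETATM / water
                continue
            by_fv_chain[fv_chain].append(res)
    atoms = {name: [] for name in BACKBONE_ATOMS}
    has_cb = []
    numbering: list[tuple[str, str]] = []
    for fv_chain in ("H", "L"):
        for res in by_fv_chain[fv_chain]:
            label = f"{res.id[1]}{res.id[2].strip()}"
            numbering.append((fv_chain, label))
            for name in ("N", "CA", "C", "O"):
                if name not in res:
                    raise ValueError(
                        f"residue {fv_chain}{label} is missing backbone atom {name}"
                    )
                atoms[name].append(res[name].coord)
            if "CB" in res:
                atoms["CB"].append(res["CB"].coord)
                has_cb.append(True)
            else:
                atoms["CB"].append(np.zeros(3))
                has_cb.append(False)
    coords = StructureCoordinates(
        {k: np.asarray(v, dtype=float) for k, v in atoms.items()}, np.asarray(has_cb)
    )
    return coords, numbering


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{resseq:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
)


def write_pdb_backbone(path, coords: StructureCoordinates, numbering, sequence: str | None = None) -> None:
    """Write backbone ATOM records; ``numbering`` gives (chain, label) per residue."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    serial = 1
    with open(path, "w") as fh:
        for i, entry in enumerate(numbering):
            chain, label = (entry.chain, entry.label) if isinstance(entry, ResiduePosition) else entry
            icode = " "
            if label and label[-1].isalpha():
                icode, num = label[-1], int(label[:-1])
            else:
                num = int(label)
            resname = three[sequence[i]] if sequence else "GLY" if not coords.has_cb[i] else "ALA"
            atom_names = ["N", "CA", "C", "O"] + (["CB"] if coords.has_cb[i] else [])
            for name in atom_names:
                x, y, z = coords.atoms[name][i]
                fh.write(
                    _PDB_ATOM.format(
                        serial=serial, name=name, alt=" ", res=resname, chain=chain,
                        resseq=num, icode=icode, x=x, y=y, z=z, occ=1.0, b=0.0,
                        el=name[0],
                    )
                )
                serial += 1
        fh.write("END\n")


# -- PSSM / FR tables -------------------------------------------------------

def read_pssm_tsv(path) -> SequenceProfile:
    """TSV: first column position labels, then 20 letter columns in alphabet order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(ALPHABET):
        raise ValueError("PSSM columns must be the 20 letters in alphabetical order")
    return SequenceProfile(df.to_numpy(dtype=float), tuple(str(i) for i in df.index))


def write_pssm_tsv(path, profile: SequenceProfile) -> None:
    labels = profile.labels or tuple(str(i) for i in range(len(profile)))
    df = pd.DataFrame(profile.probs, index=list(labels), columns=list(ALPHABET))
    df.to_csv(path, sep="\t")


def read_fr_table(path) -> FRScoreTable:
    """TSV with the same layout as a PSSM; cells are enrichment scores."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    scores = {
        str(label): {aa: float(df.loc[label, aa]) for aa in df.columns}
        for label in df.index
    }
    return FRScoreTable(scores)


def write_trajectory_csv(path, trajectory) -> None:
    pd.DataFrame(
        [
            {
                "iteration": i,
                "total": lv.total,
                "geometric": lv.geometric,
                "sequence": lv.sequence,
                "motif": lv.motif,
            }
            for i, lv in enumerate(trajectory)
        ]
    ).to_csv(path, index=False)


# -- config -----------------------------------------------------------------

def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(config, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(config, fh, sort_keys=True)
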