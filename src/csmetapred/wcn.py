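"""Weighted contact number (WCN) from tertiary structure.

WCN is a packing-density / flexibility proxy and the only constituent score
this package derives from structure itself:

    WCN_i = sum_{j != i} 1 / r_ij**2

with ``r_ij`` the distance (in Angstrom) between the representative atoms of
residues ``i`` and ``j``.  Densely packed (typically rigid, often active-site)
residues obtain high WCN.  The representative atom is the C-alpha by default
(falling back to the heavy-atom centroid when C-alpha is missing); the
side-chain centroid variant is available for comparison since contact-number
flavours in the literature differ on the reference point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .score_io import MethodScoreTable, ResidueKey

logger = logging.getLogger(__name__)

#: Mapping from three-letter residue names to one-letter codes.
from Bio.Data.IUPACData import protein_letters_3to1 as _3to1

_THREE_TO_ONE = {k.upper(): v.upper() for k, v in _3to1.items()}


class StructureError(ValueError):
    """Problem with the input structure (missing chain, no usable residues...)."""


@dataclass
class StructureChain:
    """One protein chain reduced to a representative point per residue."""

    protein_id: str
    residues: list[tuple[ResidueKey, np.ndarray]]

    @property
    def keys(self) -> list[ResidueKey]:
        return [k for k, _ in self.residues]

    @property
    def coords(self) -> np.ndarray:
        return np.array([c for _, c in self.residues], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


def _representative_coord(residue, mode: str) -> np.ndarray | None:
    """Representative coordinate of a Bio.PDB residue, or None if unusable.

    ``calpha`` mode: C-alpha, falling back to the heavy-atom centroid.
    ``sidechain`` mode: centroid of side-chain heavy atoms, falling back to
    C-alpha (glycine has no side chain).
    """
    heavy = [a for a in residue.get_atoms() if a.element != "H"]
    if not heavy:
        return None
    backbone = {"N", "CA", "C", "O", "OXT"}
    if mode == "sidechain":
        side = [a for a in heavy if a.get_name() not in backbone]
        if side:
            return np.mean([a.get_coord() for a in side], axis=0).astype(float)
    if "CA" in residue:
        return np.asarray(residue["CA"].get_coord(), dtype=float)
    return np.mean([a.get_coord() for a in heavy], axis=0).astype(float)


def load_chain(pdb_path, chain_id: str, representative: str = "calpha") -> StructureChain:
    """Load one chain from a PDB file as representative points.

    Only ATOM records of standard residues are used (hetero residues and
    waters are excluded); altloc conformers resolve to the highest-occupancy
    one.  Residues without a usable representative atom are dropped with a
    warning.

    Raises
    ------
    StructureError
        If the chain is absent or no residue survives filtering.
    """
    from Bio.PDB import PDBParser

    if representative not in ("calpha", "sidechain"):
        raise ValueError(f"unknown representative-atom mode {representative!r}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise StructureError(f"{pdb_path}: chain {chain_id!r} not found")
    chain = model[chain_id]
    residues: list[tuple[ResidueKey, np.ndarray]] = []
    for res in chain:
        hetflag, resnum, icode = res.id
        if hetflag != " ":  # hetero residue or water
            continue
        aa = _THREE_TO_ONE.get(res.get_resname().upper(), "X")
        coord = _representative_coord(res, representative)
        if coord is None:
            logger.warning("%s: residue %s%d%s has no usable atoms; dropped",
                           pdb_path, chain_id, resnum, icode.strip())
            continue
        key = ResidueKey(chain=chain_id, resnum=resnum, icode=icode.strip(), aa=aa)
        residues.append((key, coord))
    if not residues:
        raise StructureError(f"{pdb_path}: chain {chain_id!r} has no usable residues")
    return StructureChain(protein_id=f"{Path(str(pdb_path)).stem}{chain_id}", residues=residues)


def compute_wcn(chain: StructureChain) -> MethodScoreTable:
    """Inverse-square contact sum for every residue of the chain.

    All residues obtain a score (availability is the whole chain) and all
    scores are strictly positive.  Two residues at identical coordinates are
    an error (zero distance).
    """
    n = len(chain)
    if n < 2:
        raise ValueError("WCN needs at least 2 residues")
    d = pdist(chain.coords)
    if np.any(d == 0.0):
        raise ValueError("two residues share identical representative coordinates")
    inv2 = squareform(1.0 / d**2)
    wcn = inv2.sum(axis=1)
    return MethodScoreTable(method_id="wcn", scores=dict(zip(chain.keys, wcn.tolist())))
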