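"""Geometry-only metrics on coordinate files.

Distances that report on channel conformation: the Cβ–Cβ separation of the
label-site residue pair across the lateral gate, per-pair lateral-gate widths
(Cα by default) summarised in nm, and minimum side-chain heavy-atom contact
distances.  PDB files are parsed with Bio.PDB; only the first model is used
and, for alternate locations, the highest-occupancy conformer (ties broken
towards altloc 'A').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser

from gatefret._util import LookupError_

__all__ = [
    "StructureModel", "load_structure", "residue_pair_distance",
    "lateral_gate_width", "min_sidechain_distance",
    "DEFAULT_LATERAL_GATE_PAIRS",
]

#: Lateral-gate residue pairs (channel numbering of the thermophilic
#: structure): TM2/TM7 positions flanking the gate.
DEFAULT_LATERAL_GATE_PAIRS = ((124, 275), (127, 278), (130, 282))

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class StructureModel:
    """Flat coordinate container: (chain, resnum, resname, atom) -> xyz (Å)."""

    atoms: dict[tuple[str, int, str], np.ndarray]
    resnames: dict[tuple[str, int], str]
    source: str = ""

    def atom_coord(self, chain: str, resnum: int, atom_name: str) -> np.ndarray:
        key = (chain, resnum, atom_name)
        if key not in self.atoms:
            raise LookupError_(
                f"atom {atom_name} of residue {resnum} chain {chain!r} "
                f"not found in {self.source or 'structure'}")
        return self.atoms[key]

    def residue_atoms(self, chain: str, resnum: int) -> dict[str, np.ndarray]:
        found = {name: xyz for (c, r, name), xyz in self.atoms.items()
                 if c == chain and r == resnum}
        if not found:
            raise LookupError_(f"residue {resnum} chain {chain!r} not found "
                               f"in {self.source or 'structure'}")
        return found


def load_structure(path, name: str = "structure") -> StructureModel:
    """Parse a PDB file into a StructureModel (first model; best altloc)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name, str(path))
    model = next(iter(structure))
    atoms: dict[tuple[str, int, str], np.ndarray] = {}
    resnames: dict[tuple[str, int], str] = {}
    for chain in model:
        for residue in chain:
            het, resnum, _ = residue.id
            resnames[(chain.id, resnum)] = residue.get_resname()
            for atom in residue:
                if atom.is_disordered():
                    alts = sorted(atom.disordered_get_list(),
                                  key=lambda a: (-a.get_occupancy(), a.get_altloc()))
                    atom = alts[0]
                atoms[(chain.id, resnum, atom.get_name())] = np.asarray(
                    atom.get_coord(), dtype=float)
    return StructureModel(atoms=atoms, resnames=resnames, source=str(path))


def residue_pair_distance(structure: StructureModel,
                          siteA: tuple[str, int], siteB: tuple[str, int],
                          atom_name: str = "CB") -> float:
    """Euclidean distance (Å) between the named atom of two residues.

    Glycine has no Cβ; when ``atom_name`` is CB and the residue is GLY, the
    Cα is used instead (logged via a warning).
    """
    coords = []
    for chain, resnum in (siteA, siteB):
        use_atom = atom_name
        if atom_name == "CB" and structure.resnames.get((chain, resnum)) == "GLY":
            warnings.warn(f"residue {resnum} chain {chain!r} is glycine; using CA")
            use_atom = "CA"
        coords.append(structure.atom_coord(chain, resnum, use_atom))
    return float(np.linalg.norm(coords[0] - coords[1]))


def lateral_gate_width(structure: StructureModel, chain: str,
                       pairs=DEFAULT_LATERAL_GATE_PAIRS,
                       atom_name: str = "CA"):
    """Per-pair distances across the lateral gate and their mean, in nm."""
    per_pair = {}
    for a, b in pairs:
        d = residue_pair_distance(structure, (chain, a), (chain, b), atom_name)
        per_pair[(a, b)] = d / 10.0
    return per_pair, float(np.mean(list(per_pair.values())))


def min_sidechain_distance(structure: StructureModel,
                           residueA: tuple[str, int],
                           residueB: tuple[str, int]) -> float:
    """Minimum heavy-atom side-chain distance (Å) between two residues."""
    dists = []
    side_a = _sidechain_coords(structure, residueA)
    side_b = _sidechain_coords(structure, residueB)
    for xa in side_a:
        for xb in side_b:
            dists.append(np.linalg.norm(xa - xb))
    return float(min(dists))


def _sidechain_coords(structure: StructureModel, site: tuple[str, int]):
    atoms = structure.residue_atoms(*site)
    side = [xyz for name, xyz in atoms.items()
            if name not in BACKBONE_ATOMS and not name.startswith("H")
            and name[0] not in "123"]
    if not side:
        raise LookupError_(f"residue {site[1]} chain {site[0]!r} has no "
                           "side-chain heavy atoms")
    return side
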