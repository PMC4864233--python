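"""Read and write two-chain protein complexes in PDB format.

A :class:`Structure` is an all-atom complex in which every chain is labelled
as belonging to the *receptor* or the *ligand* rigid unit.  Coordinates are
kept in Angstrom (the native PDB unit); conversion to nm happens only when a
structure is coarse-grained.

Parsing and serialisation are delegated to :mod:`biotite`; this module adds
role labels, the filtering rules used throughout the package (first model,
heavy atoms only, no HETATM, altloc by highest occupancy) and residue keys
that include insertion codes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

RECEPTOR = "receptor"
LIGAND = "ligand"

__all__ = [
    "Structure",
    "read_pdb",
    "write_pdb",
    "RECEPTOR",
    "LIGAND",
]


@dataclass(frozen=True)
class Structure:
    """All-atom two-chain(+) complex with per-chain receptor/ligand roles.

    Parameters
    ----------
    atoms : biotite.structure.AtomArray
        Heavy atoms of the complex (hydrogens and HETATM records removed).
    receptor_chains, ligand_chains : frozenset of str
        Disjoint chain-id sets covering every chain present in ``atoms``.
    """

    atoms: bts.AtomArray
    receptor_chains: frozenset = field(default_factory=frozenset)
    ligand_chains: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.atoms.array_length() == 0:
            raise ValueError("structure contains no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")
        overlap = self.receptor_chains & self.ligand_chains
        if overlap:
            raise ValueError(f"chains assigned to both roles: {sorted(overlap)}")
        present = set(np.unique(self.atoms.chain_id))
        labelled = set(self.receptor_chains) | set(self.ligand_chains)
        missing = present - labelled
        if missing:
            raise ValueError(f"chains without a role label: {sorted(missing)}")

    # -- accessors ---------------------------------------------------------

    def role_of(self, chain_id: str) -> str:
        if chain_id in self.receptor_chains:
            return RECEPTOR
        if chain_id in self.ligand_chains:
            return LIGAND
        raise KeyError(chain_id)

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask over atoms belonging to ``role``."""
        chains = {RECEPTOR: self.receptor_chains, LIGAND: self.ligand_chains}[role]
        return np.isin(self.atoms.chain_id, sorted(chains))

    def select_role(self, role: str) -> "Structure":
        """Sub-structure containing only the chains of one role."""
        mask = self.role_mask(role)
        if not mask.any():
            raise ValueError(f"no atoms with role {role!r}")
        sub = self.atoms[mask]
        if role == RECEPTOR:
            return Structure(sub, receptor_chains=self.receptor_chains,
                             ligand_chains=frozenset())
        return Structure(sub, receptor_chains=frozenset(),
                         ligand_chains=self.ligand_chains)

    def residue_keys(self) -> list[tuple]:
        """Ordered unique (chain, residue number, insertion code) keys."""
        keys, seen = [], set()
        for ch, ri, ic in zip(self.atoms.chain_id, self.atoms.res_id,
                              self.atoms.ins_code):
            k = (str(ch), int(ri), str(ic))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    def atom_keys(self) -> list[tuple]:
        """(chain, res number, insertion code, atom name) per atom, in order."""
        return [
            (str(ch), int(ri), str(ic), str(an))
            for ch, ri, ic, an in zip(self.atoms.chain_id, self.atoms.res_id,
                                      self.atoms.ins_code, self.atoms.atom_name)
        ]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    role: str | None = None) -> "Structure":
        """Apply ``x -> R x + t`` to all atoms, or only to one role's atoms."""
        atoms = self.atoms.copy()
        mask = np.ones(atoms.array_length(), bool) if role is None \
            else self.role_mask(role)
        atoms.coord[mask] = atoms.coord[mask] @ np.asarray(rotation).T \
            + np.asarray(translation)
        return replace(self, atoms=atoms)


def _clean(atoms: bts.AtomArray) -> bts.AtomArray:
    """Drop HETATM records and hydrogens."""
    mask = ~atoms.hetero & (atoms.element != "H") & (atoms.element != "D")
    return atoms[mask]


def read_pdb(path, receptor_chains, ligand_chains) -> Structure:
    """Read a PDB file and label chains as receptor or ligand.

    Only fixed-column ATOM records of the first model are used; hydrogens
    and HETATM entries are discarded and alternate locations are resolved
    to the highest-occupancy conformer (ties keep the first).

    Parameters
    ----------
    path : str or Path
        PDB file to read.
    receptor_chains, ligand_chains : iterable of str
        Chain identifiers of the two rigid units.  Every named chain must
        be present in the file.

    Returns
    -------
    Structure

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a named chain is absent or no atoms survive filtering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    receptor_chains = frozenset(receptor_chains)
    ligand_chains = frozenset(ligand_chains)
    if not receptor_chains or not ligand_chains:
        raise ValueError("both receptor and ligand chain sets must be non-empty")

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = _clean(atoms)

    wanted = receptor_chains | ligand_chains
    present = set(np.unique(atoms.chain_id))
    absent = wanted - present
    if absent:
        raise ValueError(f"chains not found in {path.name}: {sorted(absent)}")

    atoms = atoms[np.isin(atoms.chain_id, sorted(wanted))]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms left after filtering {path.name}")
    return Structure(atoms, receptor_chains=receptor_chains,
                     ligand_chains=ligand_chains)


def write_pdb(structure: Structure, path) -> None:
    """Write a :class:`Structure` as fixed-column PDB ATOM records.

    Chains appear in the order they occur in the structure.  Raises
    ``ValueError`` for an empty structure and propagates ``OSError`` for an
    unwritable path.
    """
    if structure is None or structure.atoms.array_length() == 0:
        raise ValueError("cannot write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))


def structure_to_pdb_string(structure: Structure) -> str:
    """Serialise to PDB text in memory (used for byte-determinism checks)."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()
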