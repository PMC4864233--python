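"""Coarse-grain an all-atom complex into a one-bead-per-residue model.

Each amino acid becomes a single interaction centre placed at the unweighted
centroid of its heavy atoms, carrying the summed heavy-atom mass and one of
four particle classes — polar (P), nonpolar (N), apolar (C) or charged (Q) —
assigned from the residue identity.  Charged beads carry an integer charge
(Asp/Glu −1, Lys/Arg +1) at pH 7; histidine is treated as neutral polar.

The class table is a deliberately coarse stand-in for a full MARTINI
topology: only the four classes are modelled, and it is exposed as module
data (``RESIDUE_CLASS``) so callers can swap in their own mapping.
Positions are converted from Angstrom to nm here; everything downstream of
this module works in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structio import Structure, RECEPTOR, LIGAND

A_PER_NM = 10.0

# Monoisotopic-ish average masses (amu) of the elements seen in heavy protein
# atoms; hydrogens are already filtered out upstream.
ELEMENT_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971,
    "P": 30.974,
}

# Four-class residue table: charge/hydropathy at pH 7.
# Q = charged, P = polar, N = nonpolar (intermediate), C = apolar.
RESIDUE_CLASS = {
    "ASP": ("Q", -1), "GLU": ("Q", -1), "LYS": ("Q", +1), "ARG": ("Q", +1),
    "SER": ("P", 0), "THR": ("P", 0), "ASN": ("P", 0), "GLN": ("P", 0),
    "HIS": ("P", 0), "TYR": ("P", 0), "TRP": ("P", 0), "GLY": ("P", 0),
    "ALA": ("N", 0), "CYS": ("N", 0), "MET": ("N", 0), "PRO": ("N", 0),
    "VAL": ("C", 0), "LEU": ("C", 0), "ILE": ("C", 0), "PHE": ("C", 0),
}

BEAD_TYPES = ("P", "N", "C", "Q")

__all__ = ["BeadModel", "coarse_grain", "center_of_mass", "RESIDUE_CLASS",
           "BEAD_TYPES"]


@dataclass(frozen=True)
class BeadModel:
    """Coarse-grained rigid two-body model of a complex.

    Attributes
    ----------
    positions : (n, 3) float array, nm
    masses : (n,) float array, amu
    types : (n,) str array, each in {"P", "N", "C", "Q"}
    charges : (n,) int array, each in {-1, 0, +1}
    residue_index : (n,) int array
        Index of the source residue in the structure's residue order.
    groups : (n,) str array
        Rigid-group membership, "receptor" or "ligand".
    """

    positions: np.ndarray
    masses: np.ndarray
    types: np.ndarray
    charges: np.ndarray
    residue_index: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        n = len(self.positions)
        if not (len(self.masses) == len(self.types) == len(self.charges)
                == len(self.residue_index) == len(self.groups) == n):
            raise ValueError("bead field lengths differ")
        if n == 0:
            raise ValueError("empty bead model")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead position")
        bad = set(np.unique(self.types)) - set(BEAD_TYPES)
        if bad:
            raise ValueError(f"unknown bead types {bad}")

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def translated(self, shift) -> "BeadModel":
        return replace(self, positions=self.positions + np.asarray(shift))

    def to_dict(self) -> dict:
        """JSON-serialisable form (positions in nm)."""
        return {
            "positions_nm": self.positions.tolist(),
            "masses_amu": self.masses.tolist(),
            "types": self.types.tolist(),
            "charges": self.charges.tolist(),
            "residue_index": self.residue_index.tolist(),
            "groups": self.groups.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeadModel":
        return cls(
            positions=np.asarray(d["positions_nm"], float),
            masses=np.asarray(d["masses_amu"], float),
            types=np.asarray(d["types"], dtype="U1"),
            charges=np.asarray(d["charges"], int),
            residue_index=np.asarray(d["residue_index"], int),
            groups=np.asarray(d["groups"], dtype="U8"),
        )


def coarse_grain(structure: Structure, strict: bool = True) -> BeadModel:
    """Map an all-atom :class:`Structure` to one bead per residue.

    The bead sits at the unweighted centroid of the residue's heavy atoms
    (converted to nm) and carries their summed mass; type and charge come
    from :data:`RESIDUE_CLASS`.

    Parameters
    ----------
    structure : Structure
    strict : bool
        If True (default) a residue name outside the 20 standard amino
        acids raises ``ValueError``; if False such residues are skipped.
    """
    atoms = structure.atoms
    keys = structure.atom_keys()
    res_order: list[tuple] = []
    res_atoms: dict[tuple, list[int]] = {}
    for i, (ch, ri, ic, _an) in enumerate(keys):
        k = (ch, ri, ic)
        if k not in res_atoms:
            res_atoms[k] = []
            res_order.append(k)
        res_atoms[k].append(i)

    pos, mass, types, charges, ridx, groups = [], [], [], [], [], []
    for r_i, k in enumerate(res_order):
        idx = res_atoms[k]
        res_name = str(atoms.res_name[idx[0]])
        if res_name not in RESIDUE_CLASS:
            if strict:
                raise ValueError(f"non-standard residue {res_name} at {k}")
            continue
        coords = atoms.coord[idx]
        elements = [str(e).upper() for e in atoms.element[idx]]
        masses = [ELEMENT_MASS.get(e) for e in elements]
        if any(m is None for m in masses):
            unknown = {e for e, m in zip(elements, masses) if m is None}
            raise ValueError(f"unknown element(s) {unknown} in residue {k}")
        btype, q = RESIDUE_CLASS[res_name]
        pos.append(coords.mean(axis=0) / A_PER_NM)
        mass.append(float(np.sum(masses)))
        types.append(btype)
        charges.append(q)
        ridx.append(r_i)
        groups.append(structure.role_of(k[0]))

    if not pos:
        raise ValueError("no beads produced (all residues skipped?)")
    return BeadModel(
        positions=np.asarray(pos, float),
        masses=np.asarray(mass, float),
        types=np.asarray(types, dtype="U1"),
        charges=np.asarray(charges, int),
        residue_index=np.asarray(ridx, int),
        groups=np.asarray(groups, dtype="U8"),
    )


def center_of_mass(model: BeadModel, group: str) -> np.ndarray:
    """Mass-weighted mean position (nm) of one rigid group."""
    mask = model.group_mask(group)
    if not mask.any():
        raise ValueError(f"empty group {group!r}")
    m = model.masses[mask]
    return (m[:, None] * model.positions[mask]).sum(axis=0) / m.sum()
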