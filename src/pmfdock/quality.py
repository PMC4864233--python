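"""CAPRI-style quality measures for docking decoys.

Given a decoy and the native (reference) complex with identical residue and
atom correspondence, this module computes

* ``fnat``     — fraction of native interface contacts reproduced (Recall),
* ``fnonnat``  — fraction of decoy contacts absent from the native
                 (1 - Precision),
* ``L-rms``    — ligand backbone RMSD after superposing the receptors,
* ``I-rms``    — interface backbone RMSD after superposing the interfaces,

and the four-tier classification High / Medium / Acceptable / Incorrect.
A residue-residue contact exists when any heavy-atom pair across the
interface is within 5.0 A (configurable); interface residues for I-rms are
the native residues with any heavy atom within 10.0 A of the other rigid
unit.  The backbone atom set is N, CA, C, O.

The classification rules are evaluated in order High -> Medium ->
Acceptable -> Incorrect with "and" binding tighter than "or"; the first
matching tier wins and anything unmatched is Incorrect.  Note that the
Medium and Acceptable first clauses carry no upper RMSD bounds, which
differs from the official CAPRI assessment tables in some corner regions
(e.g. high fnat with moderate L-rms and small I-rms falls through to
Incorrect); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Structure, RECEPTOR, LIGAND

CONTACT_CUTOFF = 5.0      # A, heavy-atom residue-residue contact
INTERFACE_CUTOFF = 10.0   # A, interface-residue definition for I-rms
BACKBONE_ATOMS = ("N", "CA", "C", "O")
CATEGORIES = ("High", "Medium", "Acceptable", "Incorrect")

__all__ = ["QualityRecord", "residue_contacts", "fnat", "fnonnat",
           "l_rms", "i_rms", "classify", "assess", "CATEGORIES",
           "CONTACT_CUTOFF", "INTERFACE_CUTOFF", "BACKBONE_ATOMS"]


@dataclass(frozen=True)
class QualityRecord:
    """All quality measures for one decoy."""

    fnat: float
    fnonnat: float
    l_rms: float        # A
    i_rms: float        # A
    category: str

    def __post_init__(self):
        if not (0 <= self.fnat <= 1 and 0 <= self.fnonnat <= 1):
            raise ValueError("fnat/fnonnat must be fractions")
        if self.l_rms < 0 or self.i_rms < 0:
            raise ValueError("RMSD values must be >= 0")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def acceptable_or_better(self) -> bool:
        return self.category != "Incorrect"


# -- contacts --------------------------------------------------------------

def residue_contacts(receptor: Structure, ligand: Structure,
                     cutoff: float = CONTACT_CUTOFF) -> set:
    """Residue-residue contacts across the interface.

    A (receptor residue, ligand residue) pair is a contact when any
    heavy-atom pair between the two residues is within ``cutoff`` A.
    Residue keys are (chain, residue number, insertion code).
    """
    rc = receptor.atoms.coord
    lc = ligand.atoms.coord
    d = cdist(rc, lc)
    close = d <= cutoff
    if not close.any():
        return set()
    rkeys = [(str(c), int(i), str(ic)) for c, i, ic in
             zip(receptor.atoms.chain_id, receptor.atoms.res_id,
                 receptor.atoms.ins_code)]
    lkeys = [(str(c), int(i), str(ic)) for c, i, ic in
             zip(ligand.atoms.chain_id, ligand.atoms.res_id,
                 ligand.atoms.ins_code)]
    ri, li = np.nonzero(close)
    return {(rkeys[a], lkeys[b]) for a, b in zip(ri, li)}


def complex_contacts(structure: Structure,
                     cutoff: float = CONTACT_CUTOFF) -> set:
    """Contacts of a two-role complex (receptor part vs ligand part)."""
    return residue_contacts(structure.select_role(RECEPTOR),
                            structure.select_role(LIGAND), cutoff)


def fnat(decoy_contacts: set, native_contacts: set) -> float:
    """Fraction of native contacts present in the decoy (Recall)."""
    if not native_contacts:
        raise ValueError("native contact set is empty")
    return len(decoy_contacts & native_contacts) / len(native_contacts)


def fnonnat(decoy_contacts: set, native_contacts: set) -> float:
    """Fraction of decoy contacts that are non-native (1 - Precision)."""
    if not decoy_contacts:
        return 0.0
    return len(decoy_contacts - native_contacts) / len(decoy_contacts)


# -- superposition ---------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rotation R and translation t mapping mobile onto target.

    Returns (R, t) such that ``mobile @ R.T + t`` minimises the RMSD to
    ``target`` (Kabsch, via SVD with determinant correction).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(0), target.mean(0)
    h = (mobile - cm).T @ (target - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, ct - rot @ cm


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def _paired_coords(decoy: Structure, native: Structure, keys: set | None,
                   backbone_only: bool = True):
    """Matched coordinate arrays for atoms present in both structures.

    ``keys`` restricts to a residue-key set (None = all residues); atoms are
    matched on (chain, residue number, insertion code, atom name).  Residues
    missing from either structure drop out (pairwise-complete).
    """
    def index(s: Structure):
        out = {}
        for i, (ch, ri, ic, an) in enumerate(s.atom_keys()):
            if backbone_only and an not in BACKBONE_ATOMS:
                continue
            if keys is not None and (ch, ri, ic) not in keys:
                continue
            out[(ch, ri, ic, an)] = i
        return out

    di, ni = index(decoy), index(native)
    common = [k for k in di if k in ni]
    if not common:
        raise ValueError("no matching backbone atoms between decoy and native")
    dc = decoy.atoms.coord[[di[k] for k in common]]
    nc = native.atoms.coord[[ni[k] for k in common]]
    return dc, nc


def l_rms(decoy: Structure, native: Structure) -> float:
    """Ligand backbone RMSD (A) after superposing the receptors.

    The decoy receptor backbone is fitted onto the native receptor backbone
    (Kabsch); the resulting transform is applied to the decoy ligand and the
    RMSD over ligand backbone atoms is reported without re-fitting.
    """
    rec_keys = {k[:3] for k in native.select_role(RECEPTOR).atom_keys()}
    lig_keys = {k[:3] for k in native.select_role(LIGAND).atom_keys()}
    d_rec, n_rec = _paired_coords(decoy, native, rec_keys)
    rot, t = kabsch(d_rec, n_rec)
    d_lig, n_lig = _paired_coords(decoy, native, lig_keys)
    return _rmsd(d_lig @ rot.T + t, n_lig)


def interface_residues(native: Structure,
                       cutoff: float = INTERFACE_CUTOFF) -> set:
    """Native residues with any heavy atom within ``cutoff`` A of the
    other rigid unit."""
    rec = native.select_role(RECEPTOR)
    lig = native.select_role(LIGAND)
    pairs = residue_contacts(rec, lig, cutoff)
    out = set()
    for rk, lk in pairs:
        out.add(rk)
        out.add(lk)
    return out


def i_rms(decoy: Structure, native: Structure,
          cutoff: float = INTERFACE_CUTOFF) -> float:
    """Interface backbone RMSD (A).

    Interface residues are taken from the native structure (heavy atoms of
    the two units within ``cutoff`` A); the decoy is superposed on the
    native over those residues' backbone atoms and the RMSD of the same set
    is reported.
    """
    keys = interface_residues(native, cutoff)
    if not keys:
        raise ValueError("native structure has no interface residues")
    dc, nc = _paired_coords(decoy, native, keys)
    rot, t = kabsch(dc, nc)
    return _rmsd(dc @ rot.T + t, nc)


# -- classification --------------------------------------------------------

def classify(fnat_value: float, l_rms_value: float, i_rms_value: float) -> str:
    """Four-tier quality classification from (fnat, L-rms, I-rms).

    Rules are evaluated in order; "and" binds tighter than "or"; the first
    match wins and anything unmatched is Incorrect.
    """
    f, l, i = fnat_value, l_rms_value, i_rms_value
    if f >= 0.5 and l <= 1.0 and i <= 1.0:
        return "High"
    if (f >= 0.5 and l > 1.0 and i > 1.0) \
            or (0.3 <= f < 0.5 and (l <= 5.0 or i <= 2.0)):
        return "Medium"
    if (f >= 0.3 and l > 5.0 and i > 2.0) \
            or (0.1 <= f < 0.3 and (l <= 10.0 or i <= 4.0)):
        return "Acceptable"
    return "Incorrect"


def assess(decoy: Structure, native: Structure,
           contact_cutoff: float = CONTACT_CUTOFF,
           interface_cutoff: float = INTERFACE_CUTOFF) -> QualityRecord:
    """Full quality record of a decoy against its native reference."""
    native_c = complex_contacts(native, contact_cutoff)
    decoy_c = complex_contacts(decoy, contact_cutoff)
    f = fnat(decoy_c, native_c)
    fn = fnonnat(decoy_c, native_c)
    l = l_rms(decoy, native)
    i = i_rms(decoy, native)
    return QualityRecord(fnat=f, fnonnat=fn, l_rms=l, i_rms=i,
                         category=classify(f, l, i))
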