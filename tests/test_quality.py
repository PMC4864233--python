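"""CAPRI quality measures: contacts, RMSDs, classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biotite.structure as bts
from pmfdock.quality import (classify, complex_contacts, fnat, fnonnat,
                             i_rms, kabsch, l_rms, residue_contacts,
                             CATEGORIES)
from pmfdock.structio import Structure

import pmfdock as pk


def _structure(res_specs, receptor=("A",), ligand=("B",)):
    n = sum(len(atoms) for *_x, atoms in res_specs)
    arr = bts.AtomArray(n)
    i = 0
    for ch, ri, rn, atoms in res_specs:
        for an, el, xyz in atoms:
            arr.chain_id[i] = ch
            arr.res_id[i] = ri
            arr.ins_code[i] = ""
            arr.res_name[i] = rn
            arr.hetero[i] = False
            arr.atom_name[i] = an
            arr.element[i] = el
            arr.coord[i] = xyz
            i += 1
    return Structure(arr, receptor_chains=frozenset(receptor),
                     ligand_chains=frozenset(ligand))


def _single_atom_pair(dist):
    return _structure([
        ("A", 1, "GLY", [("CA", "C", (0, 0, 0))]),
        ("B", 1, "GLY", [("CA", "C", (dist, 0, 0))]),
    ])


# -- contacts --------------------------------------------------------------

def test_contact_cutoff_boundary():
    s = _single_atom_pair(4.9)
    assert len(complex_contacts(s)) == 1
    s = _single_atom_pair(5.1)
    assert len(complex_contacts(s)) == 0


def test_distant_ligand_has_no_contacts(native):
    far = native.transformed(np.eye(3), np.array([100.0, 0, 0]),
                             role="ligand")
    assert complex_contacts(far) == set()


def test_contacts_match_all_pairs_brute_force(native):
    rec = native.select_role("receptor")
    lig = native.select_role("ligand")
    got = residue_contacts(rec, lig, cutoff=5.0)
    # O(n^2) scan over residue pairs and their atoms
    expected = set()
    rk = rec.atom_keys()
    lk = lig.atom_keys()
    for i, (rc_, rr, ric, _a) in enumerate(rk):
        for j, (lc_, lr, lic, _b) in enumerate(lk):
            d = np.linalg.norm(rec.atoms.coord[i] - lig.atoms.coord[j])
            if d <= 5.0:
                expected.add(((rc_, rr, ric), (lc_, lr, lic)))
    assert got == expected


def test_fnat_fnonnat_set_arithmetic():
    native = {(i, 0) for i in range(10)}
    assert fnat(native, native) == 1.0
    assert fnonnat(native, native) == 0.0
    disjoint = {(i, 1) for i in range(4)}
    assert fnat(disjoint, native) == 0.0
    assert fnonnat(disjoint, native) == 1.0
    decoy = {(i, 0) for i in range(6)} | {(i, 2) for i in range(2)}
    assert fnat(decoy, native) == pytest.approx(0.6)
    assert fnonnat(decoy, native) == pytest.approx(0.25)
    # integer coverage: fnat * |native| counts shared contacts
    assert fnat(decoy, native) * len(native) == pytest.approx(6)
    with pytest.raises(ValueError):
        fnat(decoy, set())
    assert fnonnat(set(), native) == 0.0


# -- RMSD ------------------------------------------------------------------

def test_lrms_identity_translation_rotation(native):
    assert l_rms(native, native) == pytest.approx(0.0, abs=1e-9)
    shifted = native.transformed(np.eye(3), np.array([2.0, 0, 0]),
                                 role="ligand")
    assert l_rms(shifted, native) == pytest.approx(2.0, abs=1e-6)
    rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
    whole = native.transformed(rot, np.array([3.0, -1.0, 7.0]))
    assert l_rms(whole, native) == pytest.approx(0.0, abs=1e-6)
    assert i_rms(whole, native) == pytest.approx(0.0, abs=1e-6)


def test_irms_matches_independent_superposition_oracle(native):
    rot = Rotation.from_euler("zyx", [4, -7, 3], degrees=True).as_matrix()
    decoy = native.transformed(rot, np.array([1.5, -0.5, 0.8]),
                               role="ligand")
    got = i_rms(decoy, native)

    # oracle: interface selection + scipy align_vectors superposition
    from pmfdock.quality import interface_residues, BACKBONE_ATOMS
    keys = interface_residues(native)

    def backbone(s):
        out = {}
        for idx, (ch, ri, ic, an) in enumerate(s.atom_keys()):
            if an in BACKBONE_ATOMS and (ch, ri, ic) in keys:
                out[(ch, ri, ic, an)] = s.atoms.coord[idx]
        return out

    d, n = backbone(decoy), backbone(native)
    common = sorted(set(d) & set(n))
    P = np.array([d[k] for k in common])
    Q = np.array([n[k] for k in common])
    rot_o, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    expected = rssd / np.sqrt(len(common))
    assert got == pytest.approx(expected, abs=1e-6)


def test_kabsch_agrees_with_scipy():
    rng = np.random.default_rng(8)
    for _ in range(10):
        P = rng.normal(size=(12, 3))
        true_rot = Rotation.random(random_state=rng)
        Q = P @ true_rot.as_matrix().T + rng.normal(0, 0.05, (12, 3)) + 5.0
        rot, t = kabsch(P, Q)
        moved = P @ rot.T + t
        rot_s, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        moved_s = (P - P.mean(0)) @ rot_s.as_matrix().T + Q.mean(0)
        np.testing.assert_allclose(moved, moved_s, atol=1e-8)


def test_rmsd_invariant_under_global_motion(native):
    rng = np.random.default_rng(4)
    decoy = native.transformed(np.eye(3), np.array([1.0, 2.0, 0.5]),
                               role="ligand")
    base_l, base_i = l_rms(decoy, native), i_rms(decoy, native)
    for _ in range(5):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = decoy.transformed(rot, t)
        assert l_rms(moved, native) == pytest.approx(base_l, abs=1e-6)
        assert i_rms(moved, native) == pytest.approx(base_i, abs=1e-6)


# -- classification --------------------------------------------------------

@pytest.mark.parametrize("fn, lr, ir, cat", [
    (0.5, 1.0, 1.0, "High"),
    (0.4, 8.0, 1.5, "Medium"),
    (0.05, 0.0, 0.0, "Incorrect"),
    (0.6, 2.0, 2.0, "Medium"),
    (0.35, 6.0, 3.0, "Acceptable"),
    (0.2, 9.0, 5.0, "Acceptable"),
    (0.2, 11.0, 5.0, "Incorrect"),
    (1.0, 0.0, 0.0, "High"),
])
def test_classification_examples(fn, lr, ir, cat):
    assert classify(fn, lr, ir) == cat


def _truth_table(f, l, i):
    """Independently coded ordered rules (and binds tighter than or)."""
    high = f >= 0.5 and l <= 1.0 and i <= 1.0
    medium = (f >= 0.5 and l > 1.0 and i > 1.0) or \
             (0.3 <= f < 0.5 and (l <= 5.0 or i <= 2.0))
    acceptable = (f >= 0.3 and l > 5.0 and i > 2.0) or \
                 (0.1 <= f < 0.3 and (l <= 10.0 or i <= 4.0))
    for flag, name in ((high, "High"), (medium, "Medium"),
                       (acceptable, "Acceptable")):
        if flag:
            return name
    return "Incorrect"


def test_classifier_total_and_matches_truth_table_on_grid():
    fs = np.arange(0.0, 1.0001, 0.05)
    ls = np.arange(0.0, 12.001, 0.5)
    irs = np.arange(0.0, 5.001, 0.25)
    for f in fs:
        for l in ls:
            for i in irs:
                got = classify(float(f), float(l), float(i))
                assert got in CATEGORIES
                assert got == _truth_table(float(f), float(l), float(i))


def test_category_never_worsens_with_fnat_at_perfect_geometry():
    order = {c: k for k, c in enumerate(
        ["Incorrect", "Acceptable", "Medium", "High"])}
    prev = -1
    for f in np.arange(0.0, 1.0001, 0.01):
        rank = order[classify(float(f), 0.0, 0.0)]
        assert rank >= prev
        prev = rank


def test_assess_on_identical_structures_is_high(native):
    rec = pk.assess(native, native)
    assert rec.category == "High"
    assert rec.fnat == 1.0 and rec.fnonnat == 0.0
    assert rec.l_rms == pytest.approx(0.0, abs=1e-9)
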