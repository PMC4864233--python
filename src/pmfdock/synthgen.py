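"""Synthetic native complexes, tiered decoy sets and analytic force profiles.

Real docking benchmarks are large and externally hosted, so every test and
demonstration in this package runs on structures built here from scratch:

* :func:`make_native` builds a toy two-chain complex of backbone-only
  residues (N, CA, C, O at ideal-ish local geometry) arranged as two
  parallel strands with a defined contact interface;
* :func:`make_decoys` perturbs the ligand rigid body per quality *tier*
  (translation + rotation magnitudes chosen so the tiers span the four
  classification categories).  Tier labels are generative hints only — the
  quality module's classification is the truth;
* :func:`make_force_profiles` emits mean-force window samples from an
  analytically known radial potential plus Gaussian noise, which gives the
  PMF machinery a closed-form oracle without running any dynamics.

Everything is deterministic under a fixed seed, down to the PDB bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bts

from .structio import Structure
from .cgmap import coarse_grain, center_of_mass
from .dynamics import RadialPotential, WindowSample, KB
from .pmfcalc import WindowSchedule
from .protocol import DecoySet
from . import quality

# residue names cycling through all four bead classes
_RESNAMES = ("ALA", "SER", "ASP", "LYS", "LEU", "GLY", "GLU", "ARG",
             "VAL", "THR")

# per-tier rigid perturbation bounds: (translation A lo/hi, rotation deg
# lo/hi); chosen so generated decoys span the four categories
DEFAULT_TIERS = {
    "high": (0.0, 0.5, 0.0, 2.0),
    "medium": (1.5, 3.5, 4.0, 12.0),
    "acceptable": (3.0, 8.0, 10.0, 30.0),
    "incorrect": (15.0, 40.0, 90.0, 180.0),
}

__all__ = ["SynthConfig", "make_native", "make_decoys",
           "make_force_profiles", "DEFAULT_TIERS"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic benchmark generator."""

    residues_per_chain: int = 12
    interface_size: int = 10          # minimum native contacts at 5 A
    tiers: dict = field(default_factory=lambda: dict(DEFAULT_TIERS))
    decoys_per_tier: int = 5
    seed: int = 0
    potential: RadialPotential = RadialPotential()

    def __post_init__(self):
        if self.residues_per_chain < 1 or self.decoys_per_tier < 1:
            raise ValueError("counts must be >= 1")
        if self.interface_size < 1:
            raise ValueError("interface size must be >= 1")
        for name, (t0, t1, r0, r1) in self.tiers.items():
            if min(t0, t1, r0, r1) < 0:
                raise ValueError(f"negative magnitude in tier {name!r}")


def _backbone_chain(chain_id: str, n_res: int, origin, direction,
                    side) -> list:
    """Backbone-stub residues along ``direction``; N/C/O offset toward
    ``side`` (unit vector)."""
    direction = np.asarray(direction, float)
    side = np.asarray(side, float)
    atoms = []
    for i in range(n_res):
        ca = np.asarray(origin, float) + 3.8 * i * direction
        res = _RESNAMES[i % len(_RESNAMES)]
        atoms.append((chain_id, i + 1, res, "N", "N",
                      ca - 1.23 * direction + 0.75 * side))
        atoms.append((chain_id, i + 1, res, "CA", "C", ca))
        atoms.append((chain_id, i + 1, res, "C", "C",
                      ca + 1.23 * direction + 0.75 * side))
        atoms.append((chain_id, i + 1, res, "O", "O",
                      ca + 1.45 * direction + 1.90 * side))
    return atoms


def _to_structure(atom_rows, receptor_chains, ligand_chains) -> Structure:
    arr = bts.AtomArray(len(atom_rows))
    for i, (ch, ri, res, an, el, xyz) in enumerate(atom_rows):
        arr.chain_id[i] = ch
        arr.res_id[i] = ri
        arr.ins_code[i] = ""
        arr.res_name[i] = res
        arr.hetero[i] = False
        arr.atom_name[i] = an
        arr.element[i] = el
        arr.coord[i] = xyz
    return Structure(arr, receptor_chains=frozenset(receptor_chains),
                     ligand_chains=frozenset(ligand_chains))


def make_native(config: SynthConfig) -> Structure:
    """Toy native complex: two parallel backbone strands in contact.

    Chain A (receptor) runs along x at y=0 with its N/C/O atoms pointing
    +y; chain B (ligand) runs antiparallel at y=5 A pointing -y, staggered
    by half a rise, so facing heavy atoms sit ~3.5-4.5 A apart and every
    residue pair across the groove is a 5 A contact.  Raises ``ValueError``
    when the requested interface size cannot be realised.
    """
    n = config.residues_per_chain
    rows = _backbone_chain("A", n, (0.0, 0.0, 0.0), (1, 0, 0), (0, 1, 0))
    rows += _backbone_chain("B", n, (3.8 * (n - 1) - 1.9, 5.0, 0.0),
                            (-1, 0, 0), (0, -1, 0))
    native = _to_structure(rows, {"A"}, {"B"})
    n_contacts = len(quality.complex_contacts(native))
    if n_contacts < config.interface_size:
        raise ValueError(
            f"geometry yields {n_contacts} contacts < requested interface "
            f"size {config.interface_size}; increase residues_per_chain")
    return native


def _random_rotation_matrix(rng, max_angle_deg, min_angle_deg=0.0):
    angle = np.deg2rad(rng.uniform(min_angle_deg, max_angle_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    kx, ky, kz = axis
    k = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_decoys(native: Structure, config: SynthConfig) -> DecoySet:
    """Rigid-body ligand perturbations of the native, one batch per tier.

    Each decoy rotates the ligand about its centroid (random axis, angle in
    the tier's range) and translates it by a random vector with magnitude
    in the tier's range.  The decoy's ``dock_com`` (coarse-grained COM
    distance, nm) is stored alongside the structure.
    """
    rng = np.random.default_rng(config.seed)
    lig_mask = native.role_mask("ligand")
    centroid = native.atoms.coord[lig_mask].mean(axis=0)

    decoys = DecoySet()
    min_dock_com = 0.15  # nm; bodies closer than this are clash artefacts
    for tier in sorted(config.tiers):
        t_lo, t_hi, r_lo, r_hi = config.tiers[tier]
        for j in range(config.decoys_per_tier):
            for _attempt in range(100):
                rot = _random_rotation_matrix(rng, r_hi, r_lo)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = rng.uniform(t_lo, t_hi) * direction
                # rotate about the ligand centroid, then translate
                t = centroid - rot @ centroid + shift
                decoy = native.transformed(rot, t, role="ligand")
                model = coarse_grain(decoy)
                dock_com = float(np.linalg.norm(
                    center_of_mass(model, "ligand")
                    - center_of_mass(model, "receptor")))
                # docking programs clash-filter their output; resample
                # perturbations that bury one body inside the other
                if dock_com > min_dock_com:
                    break
            else:
                raise ValueError(
                    f"tier {tier!r}: no clash-free decoy in 100 attempts")
            decoys.add(f"{tier}_{j:03d}", structure=decoy, dock_com=dock_com)
    return decoys


def make_force_profiles(schedule: WindowSchedule,
                        potential: RadialPotential,
                        noise_sd: float = 0.0, seed: int = 0,
                        temperature: float = 300.0,
                        jacobian_term: bool = False,
                        replicate: int = 0) -> list[WindowSample]:
    """Window samples with analytically known mean forces.

    The noiseless mean force at distance r is ``dU/dr`` (minus the
    entropic term ``2 k_B T / r`` when ``jacobian_term`` is on, mimicking
    what the dynamics engine records); Gaussian noise of standard
    deviation ``noise_sd`` is added per window.
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in schedule.distances:
        f = float(potential.du(r))
        if jacobian_term:
            f -= 2.0 * KB * temperature / r
        if noise_sd > 0:
            f += float(rng.normal(0.0, noise_sd))
        out.append(WindowSample(r=float(r), replicate=replicate,
                                mean_force=f, stderr=float(noise_sd),
                                n_samples=1, seed=seed))
    return out
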