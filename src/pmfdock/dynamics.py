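"""Rigid-body overdamped Langevin dynamics with a COM-distance constraint.

The receptor and ligand of a coarse-grained :class:`~pmfdock.cgmap.BeadModel`
are treated as two rigid bodies (6 degrees of freedom each).  At every step
each body receives a deterministic drift from the inter-body forces plus
isotropic translational and rotational Brownian noise, after which the
centre-of-mass separation is projected back to the constrained distance ``r``
exactly (mass-weighted moves of both bodies along the inter-COM axis).

The recorded constraint force is the Lagrange-multiplier force the
constraint exerts along the *outward* inter-COM axis, obtained by converting
the restoring displacement back to a force through the relative friction:

    f_c = -(d_unconstrained - r) * mu * zeta / dt,      mu = m1 m2 / (m1+m2)

With this sign, two non-interacting bodies give <f_c> = -2 k_B T / r (the
entropic pull of the growing spherical shell), a radial potential U at low
temperature gives <f_c> -> dU/dr, and subtracting the Jacobian term
2 k_B T / r during PMF integration makes free bodies exactly flat — which is
the convention the PMF module assumes.

Interactions between beads of opposite bodies are a shifted-truncated
Lennard-Jones term with per-class-pair well depths plus a screened Coulomb
term between charged beads.  A purely radial test potential can be injected
in place of the bead sums, which is how analytic oracles drive the engine.
Units: nm, ps, amu, kJ/mol; k_B = 0.008314 kJ/mol/K.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cgmap import BeadModel, center_of_mass, BEAD_TYPES

KB = 0.008314462618  # kJ/mol/K

# MARTINI-flavoured class-pair well depths (kJ/mol): like prefers like,
# apolar-polar and apolar-charged contacts are penalised.  Config, not a
# physics claim.
DEFAULT_EPSILON = {
    ("Q", "Q"): 5.0, ("P", "P"): 4.0, ("P", "Q"): 4.5,
    ("N", "N"): 3.5, ("C", "C"): 4.5, ("C", "P"): 2.0,
    ("C", "Q"): 1.8, ("N", "P"): 3.0, ("N", "Q"): 2.8, ("N", "C"): 3.2,
}

__all__ = ["SimParams", "WindowSample", "RadialPotential",
            "simulate_window", "run_replicate", "derive_window_seed", "KB"]


def _sym_eps(table: dict) -> dict:
    out = {}
    for (a, b), v in table.items():
        out[(a, b)] = v
        out[(b, a)] = v
    return out


@dataclass(frozen=True)
class RadialPotential:
    """Radial test potential U(r) injected in place of the bead sums.

    kind "harmonic":  U = 0.5 * k * (r - r0)^2 with k = depth / width^2
    kind "gaussian":  U = -depth * exp(-(r - r0)^2 / (2 width^2))

    depth in kJ/mol (well depth, positive number), r0 and width in nm.
    """

    kind: str = "gaussian"
    depth: float = 30.0
    r0: float = 3.0
    width: float = 0.3

    def u(self, r):
        r = np.asarray(r, float)
        if self.kind == "harmonic":
            k = self.depth / self.width ** 2
            return 0.5 * k * (r - self.r0) ** 2
        if self.kind == "gaussian":
            return -self.depth * np.exp(-((r - self.r0) ** 2)
                                        / (2 * self.width ** 2))
        raise ValueError(f"unknown potential kind {self.kind!r}")

    def du(self, r):
        r = np.asarray(r, float)
        if self.kind == "harmonic":
            k = self.depth / self.width ** 2
            return k * (r - self.r0)
        if self.kind == "gaussian":
            return self.depth * (r - self.r0) / self.width ** 2 \
                * np.exp(-((r - self.r0) ** 2) / (2 * self.width ** 2))
        raise ValueError(f"unknown potential kind {self.kind!r}")

    def du_scalar(self, r: float) -> float:
        """Scalar fast path of :meth:`du` (inner simulation loop)."""
        if self.kind == "harmonic":
            return self.depth / self.width ** 2 * (r - self.r0)
        return self.depth * (r - self.r0) / self.width ** 2 \
            * math.exp(-((r - self.r0) ** 2) / (2 * self.width ** 2))


@dataclass(frozen=True)
class SimParams:
    """Parameters of one constrained-window simulation.

    ``n_steps`` is the total step count; the first
    ``round(equil_fraction * n_steps)`` steps are discarded as
    equilibration, so the default 62500 steps yield 5e4 production samples.
    """

    temperature: float = 300.0        # K
    dt_fs: float = 20.0               # fs
    n_steps: int = 62500
    equil_fraction: float = 0.2
    friction: float = 10.0            # 1/ps
    epsilon: dict = field(default_factory=lambda: dict(DEFAULT_EPSILON))
    sigma: float = 0.47               # nm, LJ radius
    lj_cutoff: float = 1.2            # nm, potential shifted to zero here
    coulomb_prefactor: float = 138.935458 / 15.0  # kJ nm / mol e^2, eps_r=15
    debye_length: float = 1.0         # nm
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not (0 <= self.equil_fraction < 1):
            raise ValueError("equilibration fraction must be in [0, 1)")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def dt_ps(self) -> float:
        return self.dt_fs * 1e-3

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass(frozen=True)
class WindowSample:
    """Mean constraint force at one constrained COM distance."""

    r: float                  # nm
    replicate: int
    mean_force: float         # kJ/mol/nm, outward-axis convention
    stderr: float             # kJ/mol/nm
    n_samples: int            # effective (block) sample count
    seed: int = 0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("window distance must be > 0")
        if self.n_samples < 1:
            raise ValueError("need at least one effective sample")
        if self.stderr < 0:
            raise ValueError("standard error must be >= 0")


class _RigidBody:
    """Body-frame bead cloud plus mobility coefficients."""

    def __init__(self, positions: np.ndarray, masses: np.ndarray,
                 friction: float):
        self.masses = masses
        self.mass = float(masses.sum())
        com = (masses[:, None] * positions).sum(0) / self.mass
        self.body_coords = positions - com
        r2 = (self.body_coords ** 2).sum(1)
        # isotropic (sphere-equivalent) moment of inertia, amu nm^2
        self.inertia = float((2.0 / 3.0) * (masses * r2).sum())
        self.gamma_t = self.mass * friction       # amu/ps
        self.gamma_r = self.inertia * friction    # amu nm^2 / ps
        self.radius = float(np.sqrt(r2).max()) if len(r2) else 0.0


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_from_rotvec(v):
    angle = np.linalg.norm(v)
    if angle < 1e-14:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / angle
    s = np.sin(angle / 2.0)
    return np.array([np.cos(angle / 2.0), *(axis * s)])


def _quat_to_matrix(q):
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _random_quat(rng):
    v = rng.normal(size=4)
    return v / np.linalg.norm(v)


def _pair_forces(pos1, pos2, eps_mat, qq, params):
    """Per-bead forces between the two groups.

    ``eps_mat`` is the (n2, n1) class-pair well-depth matrix and ``qq`` the
    (n2, n1) charge-product matrix (or None when all zero), both
    precomputed once per window.  Returns (f1, f2): forces on each bead of
    group 1 and group 2."""
    diff = pos2[:, None, :] - pos1[None, :, :]          # (n2, n1, 3)
    d2 = (diff ** 2).sum(-1)
    d = np.sqrt(d2)
    np.maximum(d, 1e-6, out=d)

    sr6 = (params.sigma ** 2 / d2) ** 3
    f_lj = 24.0 * eps_mat * (2.0 * sr6 ** 2 - sr6) / d
    f_lj[d >= params.lj_cutoff] = 0.0

    fmag = f_lj                                         # >0 = repulsive
    if qq is not None:
        lam = params.debye_length
        fmag = fmag + params.coulomb_prefactor * qq * np.exp(-d / lam) \
            * (1.0 / d2 + 1.0 / (lam * d))

    fvec = (fmag / d)[:, :, None] * diff                # force on bead of g2
    f2 = fvec.sum(axis=1)                               # (n2, 3)
    f1 = -fvec.sum(axis=0)                              # (n1, 3)
    return f1, f2


def simulate_window(model: BeadModel, r: float, params: SimParams,
                    seed: int, potential: RadialPotential | None = None,
                    trace: dict | None = None) -> WindowSample:
    """Sample the mean constraint force at COM distance ``r``.

    The two rigid groups are placed at separation ``r`` along their original
    inter-COM axis (random ligand reorientations are tried if beads overlap)
    and propagated with overdamped Langevin dynamics; after each step the
    COM distance is projected back to ``r`` and the projection is recorded
    as the constraint force.  Identical ``(model, r, params, seed)`` give
    bit-identical output.

    Parameters
    ----------
    potential : RadialPotential, optional
        If given, replaces the bead-bead interactions with a radial
        potential acting between the two COMs (analytic-oracle mode).
    trace : dict, optional
        If an (empty) dict is passed, per-step post-projection state is
        appended under keys "com1", "com2", "quat1", "quat2" (inspection
        and invariant testing; slows the run down).
    """
    if r <= 0:
        raise ValueError("window distance must be > 0")
    rng = np.random.default_rng(seed)

    rec_mask = model.group_mask("receptor")
    lig_mask = model.group_mask("ligand")
    if not rec_mask.any() or not lig_mask.any():
        raise ValueError("model must contain two non-empty rigid groups")

    body1 = _RigidBody(model.positions[rec_mask], model.masses[rec_mask],
                       params.friction)
    body2 = _RigidBody(model.positions[lig_mask], model.masses[lig_mask],
                       params.friction)
    t1, t2 = model.types[rec_mask], model.types[lig_mask]
    q1, q2 = model.charges[rec_mask], model.charges[lig_mask]
    eps_table = _sym_eps(params.epsilon)

    # initial placement along the model's own COM axis
    axis = center_of_mass(model, "ligand") - center_of_mass(model, "receptor")
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])

    com1 = np.zeros(3)
    quat1 = np.array([1.0, 0.0, 0.0, 0.0])
    com2 = r * axis
    quat2 = np.array([1.0, 0.0, 0.0, 0.0])

    if potential is None:
        min_gap = 0.5 * params.sigma
        for attempt in range(1001):
            rot2 = _quat_to_matrix(quat2)
            p2 = com2 + body2.body_coords @ rot2.T
            p1 = com1 + body1.body_coords
            dmin = np.sqrt(
                (((p2[:, None, :] - p1[None, :, :]) ** 2).sum(-1)).min())
            if dmin >= min_gap:
                break
            quat2 = _random_quat(rng)
        else:
            raise ValueError(
                f"no overlap-free placement at r={r} nm after 1000 attempts")

    dt = params.dt_ps
    kt = params.kt
    mu = body1.mass * body2.mass / (body1.mass + body2.mass)
    mu_gamma = mu * params.friction
    w1 = body2.mass / (body1.mass + body2.mass)
    w2 = body1.mass / (body1.mass + body2.mass)

    sd_t1 = np.sqrt(2.0 * kt * dt / body1.gamma_t)
    sd_t2 = np.sqrt(2.0 * kt * dt / body2.gamma_t)
    sd_r1 = np.sqrt(2.0 * kt * dt / body1.gamma_r) if body1.inertia > 1e-12 \
        else 0.0
    sd_r2 = np.sqrt(2.0 * kt * dt / body2.gamma_r) if body2.inertia > 1e-12 \
        else 0.0

    n_equil = int(round(params.equil_fraction * params.n_steps))
    forces = np.empty(params.n_steps - n_equil)

    # When the bead sums are replaced by a radial COM-COM potential (or are
    # identically zero) rotations carry no force and are skipped, which
    # leaves the recorded constraint forces untouched.
    present_pairs = {(a, b) for a in set(t1) for b in set(t2)}
    has_lj = any(eps_table.get(p, 0.0) != 0.0 for p in present_pairs)
    has_coulomb = np.any(q1 != 0) and np.any(q2 != 0)
    radial_only = potential is not None or not (has_lj or has_coulomb)

    c1, c2 = dt / body1.gamma_t, dt / body2.gamma_t
    drift_cap = 0.05  # nm per step; stability guard against clashed starts

    if trace is not None:
        for key in ("com1", "com2", "quat1", "quat2"):
            trace.setdefault(key, [])

    def record():
        if trace is not None:
            trace["com1"].append(com1.copy())
            trace["com2"].append(com2.copy())
            trace["quat1"].append(quat1.copy())
            trace["quat2"].append(quat2.copy())

    if radial_only:
        du = potential.du_scalar if potential is not None else None
        noise = rng.normal(size=(params.n_steps, 6))
        for step in range(params.n_steps):
            sep = com2 - com1
            dist = math.sqrt(sep[0] ** 2 + sep[1] ** 2 + sep[2] ** 2)
            if du is not None:
                fmag = -du(dist)              # >0 pushes bodies apart
                if not math.isfinite(fmag):
                    raise RuntimeError(f"non-finite force at step {step}")
                fvec = (fmag / dist) * sep
                com1 = com1 - fvec * c1 + sd_t1 * noise[step, 0:3]
                com2 = com2 + fvec * c2 + sd_t2 * noise[step, 3:6]
            else:
                com1 = com1 + sd_t1 * noise[step, 0:3]
                com2 = com2 + sd_t2 * noise[step, 3:6]

            sep = com2 - com1
            dist = math.sqrt(sep[0] ** 2 + sep[1] ** 2 + sep[2] ** 2)
            if not math.isfinite(dist) or dist < 1e-12:
                raise RuntimeError(f"degenerate separation at step {step}")
            excess = dist - r
            shift = (excess / dist) * sep
            com1 = com1 + w1 * shift
            com2 = com2 - w2 * shift
            record()
            if step >= n_equil:
                forces[step - n_equil] = -excess * mu_gamma / dt
    else:
        eps_mat = np.array([[eps_table.get((a, b), 0.0) for a in t1]
                            for b in t2])
        qq = np.outer(q2, q1).astype(float)
        if not np.any(qq):
            qq = None
        noise = rng.normal(size=(params.n_steps, 12))
        for step in range(params.n_steps):
            rot1 = _quat_to_matrix(quat1)
            rot2 = _quat_to_matrix(quat2)
            p1 = com1 + body1.body_coords @ rot1.T
            p2 = com2 + body2.body_coords @ rot2.T

            f1, f2 = _pair_forces(p1, p2, eps_mat, qq, params)
            force1 = f1.sum(axis=0)
            force2 = f2.sum(axis=0)
            torque1 = np.cross(p1 - com1, f1).sum(axis=0)
            torque2 = np.cross(p2 - com2, f2).sum(axis=0)

            if not (np.all(np.isfinite(force1))
                    and np.all(np.isfinite(force2))):
                raise RuntimeError(f"non-finite force at step {step}")

            d1 = force1 * c1
            d2 = force2 * c2
            for d in (d1, d2):                # clash guard: cap the drift
                nd = np.linalg.norm(d)
                if nd > drift_cap:
                    d *= drift_cap / nd
            com1 = com1 + d1 + sd_t1 * noise[step, 0:3]
            com2 = com2 + d2 + sd_t2 * noise[step, 3:6]
            if sd_r1 > 0:
                rv1 = torque1 * (dt / body1.gamma_r) + sd_r1 * noise[step, 6:9]
                quat1 = _quat_mul(_quat_from_rotvec(rv1), quat1)
                quat1 = quat1 / np.linalg.norm(quat1)
            if sd_r2 > 0:
                rv2 = torque2 * (dt / body2.gamma_r) \
                    + sd_r2 * noise[step, 9:12]
                quat2 = _quat_mul(_quat_from_rotvec(rv2), quat2)
                quat2 = quat2 / np.linalg.norm(quat2)

            # exact holonomic projection of the COM distance back to r
            sep = com2 - com1
            dist = np.linalg.norm(sep)
            if not np.isfinite(dist) or dist < 1e-12:
                raise RuntimeError(f"degenerate separation at step {step}")
            excess = dist - r
            shift = (excess / dist) * sep
            com1 = com1 + w1 * shift
            com2 = com2 - w2 * shift
            record()
            if step >= n_equil:
                forces[step - n_equil] = -excess * mu_gamma / dt

    mean = float(forces.mean())
    n_prod = len(forces)
    n_blocks = min(50, n_prod)
    if n_blocks >= 2:
        usable = n_prod - n_prod % n_blocks
        blocks = forces[:usable].reshape(n_blocks, -1).mean(axis=1)
        stderr = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
        n_eff = n_blocks
    else:
        stderr = 0.0
        n_eff = 1
    return WindowSample(r=float(r), replicate=0, mean_force=mean,
                        stderr=stderr, n_samples=n_eff, seed=int(seed))


def derive_window_seed(base_seed: int, decoy_id: str, window_index: int,
                       replicate: int) -> int:
    """Deterministic per-window seed from (base seed, decoy, window, rep)."""
    key = (zlib.crc32(str(decoy_id).encode()), int(window_index),
           int(replicate))
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_replicate(model: BeadModel, schedule, params: SimParams,
                  replicate: int, decoy_id: str = "",
                  potential: RadialPotential | None = None
                  ) -> list[WindowSample]:
    """Simulate every window of a schedule for one replicate.

    ``schedule`` is a :class:`~pmfdock.pmfcalc.WindowSchedule` or any object
    with a ``distances`` attribute (ascending, nm).  Each window gets its
    own seed derived from ``(params.seed, decoy_id, window index,
    replicate)``, so replicates and windows are statistically independent
    yet fully reproducible.
    """
    distances = np.asarray(schedule.distances, float)
    if distances.size == 0:
        raise ValueError("empty window schedule")
    out = []
    for i, r in enumerate(distances):
        seed = derive_window_seed(params.seed, decoy_id, i, replicate)
        try:
            s = simulate_window(model, float(r), params, seed,
                                potential=potential)
        except Exception as exc:
            raise RuntimeError(
                f"window {i} (r={r:.3f} nm, replicate {replicate}) failed: "
                f"{exc}") from exc
        out.append(WindowSample(r=s.r, replicate=replicate,
                                mean_force=s.mean_force, stderr=s.stderr,
                                n_samples=s.n_samples, seed=seed))
    return out
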