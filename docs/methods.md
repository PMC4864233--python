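# Methods

## Scope and model

`pmfdock` estimates the binding strength of a docked receptor–ligand
orientation as the depth of the potential of mean force (PMF) along the
centre-of-mass (COM) separation, sampled by constrained simulations, and
uses that estimate to rank docking decoys. The package deliberately
replaces an all-atom/coarse-grained MD engine with a *toy* rigid-body
stochastic dynamics model so that the complete scoring pipeline — window
scheduling, constraint-force sampling, thermodynamic integration, staged
replicate ranking, CAPRI-style quality assessment — runs in minutes on one
core. The pipeline stages and their statistical logic are the object of
interest; the bead-level energetics are a configurable stand-in, not a
validated force field.

## Coarse-graining

Each residue becomes one bead at the unweighted centroid of its heavy
atoms, carrying their summed mass and one of four classes:

* Q (charged): Asp(−), Glu(−), Lys(+), Arg(+)
* P (polar): Ser, Thr, Asn, Gln, His, Tyr, Trp, Gly
* N (nonpolar): Ala, Cys, Met, Pro
* C (apolar): Val, Leu, Ile, Phe

The table encodes hydropathy and charge at pH 7 (histidine neutral, its
dominant state) and is module data (`cgmap.RESIDUE_CLASS`) that callers can
replace. Only these four classes are modelled; finer bead subtypes,
backbone/side-chain splits, bonded terms and elastic networks are out of
scope because the two binding partners are treated as rigid bodies — the
decoy's orientation, which is what is being scored, is frozen by
construction. Coordinates enter in Å (PDB native) and are converted to nm
at this boundary; everything downstream works in nm, ps, amu, kJ/mol.

## Constrained rigid-body dynamics

Each partner is a rigid body with 6 degrees of freedom propagated by
overdamped (Brownian) Langevin dynamics: translational mobility
`1/(M ζ)` and an isotropic rotational mobility from a sphere-equivalent
moment of inertia, with matching thermal noise; orientations are
quaternions renormalised every step. Defaults: T = 300 K, time step
20 fs, friction ζ = 10 ps⁻¹, 62 500 steps per window of which the first
20 % are discarded (50 000 production samples).

Inter-body forces are shifted-truncated Lennard-Jones terms between beads
of opposite bodies (σ = 0.47 nm, cutoff 1.2 nm) with class-pair well
depths ordered "like prefers like" (Q–Q 5.0 … C–Q 1.8 kJ/mol), plus
screened Coulomb between charged beads (prefactor 138.935/15 kJ·nm/mol,
Debye length 1 nm). These numbers are configuration, chosen once for
plausible ordering, and make no quantitative physical claim. A purely
radial test potential U(r) can be injected in place of the bead sums;
every quantitative oracle in the test suite uses this mode.

**Constraint and recorded force.** After each unconstrained step the COM
separation d is projected back to the window distance r exactly by moving
both bodies along the inter-COM axis with mass-weighted shares (an exact
holonomic constraint for this single coordinate). The recorded constraint
force converts the restoring displacement back through the relative
friction:

    f_c = −(d − r) · μ ζ / Δt,      μ = M₁M₂/(M₁+M₂).

Its expectation is `dU/dr − 2k_BT/r`: the first term is the potential's
radial gradient, the second the entropic pull of the growing spherical
shell that any distance constraint in 3-D feels. Consequences used as
oracles: free bodies give ⟨f_c⟩ = −2k_BT/r; at low temperature
⟨f_c⟩ → dU/dr; and after the Jacobian correction below, free bodies give
an exactly flat PMF — the latter is the operational definition of the
sign convention. Note that at finite temperature a window at a potential
minimum does *not* give zero mean force; the entropic −2k_BT/r remains.

Per-window seeds derive deterministically from (base seed, decoy id,
window index, replicate id) via a seed sequence, so identical inputs are
bit-identical, replicates are independent, and results are reproducible
across processes.

Numerical guards: the starting pose places the bodies at separation r
along the model's own COM axis, retrying up to 1000 random ligand
orientations if beads of opposite bodies come closer than σ/2; the
deterministic drift per body per step is capped at 0.05 nm so clashed
configurations relax instead of diverging; non-finite forces abort with
the step index. The per-window standard error comes from 50-block
averaging of the production samples.

## Window schedule, PMF and ΔG_off

For a decoy whose COM distance is `dock_com`, the schedule is 23 windows
spaced 0.05 nm starting at `dock_com − 0.1` (dense coverage of the well)
plus 9 windows spaced 0.1 nm starting at `dock_com + 1.15` (dissociated
tail) — 32 windows, a 0.15 nm gap between the series. `dock_com` must
exceed 0.1 nm so all windows are positive.

The PMF is the trapezoidal integral from each window to the outermost
one of `−⟨f_c⟩(s) − 2k_BT/s`, anchored at PMF = 0 at the largest
distance. The Jacobian term is a flag, default on: only then do
non-interacting bodies yield a flat profile, making ΔG_off = 0 for
non-binders. Trapezoidal quadrature suffices because the windows are
dense where curvature lives; for a harmonic well the force is linear and
the rule is essentially exact (the 2 % test tolerance covers schedule
discretisation, not quadrature error).

ΔG_off is extracted as PMF(r_min) − PMF(r_max) with r_min the global PMF
minimum (ties → smallest r, the most bound state) and r_max the highest
PMF at any larger distance (ties → largest r). If the minimum falls on
the last window the profile has no later barrier and ΔG_off is 0,
flagged degenerate. ΔG_off ≤ 0 always, is invariant to the PMF reference
offset, and changes continuously under force perturbations. Replicates
are averaged at the ΔG_off level — the mean of per-replicate ΔG_off
values, not the ΔG_off of averaged forces — because each replicate's
profile is an independent estimate of the same free-energy difference.

## Staged ranking protocol

Stage 1 scores every decoy with a single replicate and sorts ascending
(ties broken lexicographically by decoy id, making the order total and
reproducible). The best ⌈N/2⌉ decoys survive — ceiling, so the median
decoy is never discarded on odd N. Survivors receive four more
replicates and are re-ranked on the mean over all five (the stage-1
replicate included). Cut decoys keep their stage-1 score and follow the
survivors in stage-1 order, so set-level statistics over the full decoy
set remain computable; a `cut_after` index marks the boundary. A
crystal-reference helper scores the native structure with 20 replicates
for comparison against decoy distributions.

## Quality assessment

A residue–residue contact is any heavy-atom pair across the interface
within 5.0 Å (configurable). fnat is the fraction of native contacts
reproduced by the decoy (Recall); fnonnat the fraction of decoy contacts
that are non-native (Precision = 1 − fnonnat; a decoy with no contacts
has fnonnat = 0 and enters Recall averages with fnat = 0). L-rms
superposes the decoy receptor on the native receptor over backbone atoms
(N, CA, C, O; Kabsch/SVD) and reports the ligand backbone RMSD without
re-fitting. I-rms takes the native residues with any heavy atom within
10.0 Å of the other body, superposes decoy on native over their backbone
atoms and reports the RMSD of the same set. Atoms are matched on
(chain, residue number, insertion code, atom name); residues missing
from either structure drop out of both.

Classification evaluates the four tier rules in order High → Medium →
Acceptable → Incorrect, "and" binding tighter than "or", first match
wins, anything unmatched Incorrect:

* High: fnat ≥ 0.5 and L-rms ≤ 1.0 and I-rms ≤ 1.0
* Medium: (fnat ≥ 0.5 and L-rms > 1.0 and I-rms > 1.0) or
  (0.3 ≤ fnat < 0.5 and (L-rms ≤ 5.0 or I-rms ≤ 2.0))
* Acceptable: (fnat ≥ 0.3 and L-rms > 5.0 and I-rms > 2.0) or
  (0.1 ≤ fnat < 0.3 and (L-rms ≤ 10.0 or I-rms ≤ 4.0))
* Incorrect: fnat < 0.1 or (L-rms > 10.0 and I-rms > 4.0)

**Known discrepancy with official CAPRI tables:** the Medium and
Acceptable first clauses above carry no upper RMSD bounds, so some corner
regions classify differently from the official criteria — e.g. fnat = 0.75
with L-rms = 3 Å and I-rms = 0.8 Å falls through every rule to Incorrect,
where the official tables would call it Medium. The rules are implemented
as written here by design; swap in a different `classify` if official
behaviour is needed.

## Synthetic benchmark generator

`synthgen` emulates a docking benchmark: a native complex of two
backbone-only (N, CA, C, O) antiparallel strands 5 Å apart (12 residues
per chain by default, ≥ 44 contacts at 5 Å, residue names cycling through
all four bead classes), and decoys made by rigid ligand perturbations
drawn per tier — translation/rotation bounds of (≤0.5 Å, ≤2°) for the
high tier, (1.5–3.5 Å, 4–12°) medium, (3–8 Å, 10–30°) acceptable and
(15–40 Å, 90–180°) incorrect, five decoys per tier by default.
Perturbations that bury one body inside the other (COM distance
≤ 0.15 nm) are resampled, as a docking program's clash filter would
reject such poses. Tier names are generative hints only; the classifier
is the ground truth, and with the default tiers all four categories are
realised (the tier→category map is intentionally loose near the
classification boundaries). Everything is deterministic to the PDB byte
under a fixed seed.

What the generator does *not* emulate: side chains and packing, chain
flexibility, realistic interface chemistry, globular shapes (the toy
COM distance is ~0.4 nm, an order of magnitude below real complexes),
and score noise with realistic structure. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and statistics
on known ground truth — not docking accuracy on real proteins.

`make_force_profiles` emits window samples with analytically known means
(dU/dr of a harmonic or Gaussian radial potential, optionally minus the
entropic 2k_BT/r term to mimic what the engine records) plus Gaussian
noise, providing closed-form oracles for the integration and ranking
machinery without any dynamics.

## Problem sizes and numerical choices in the test battery

The engine oracles use two single-bead bodies of mass 1 amu, which makes
the force noise per step small enough for tight assertions: the
free-body entropic force is checked against 2k_BT/r within 3 standard
errors at 2×10⁵ steps, and the full free-body schedule integrates to a
PMF within 3 propagated standard errors of zero at 3×10⁴ steps per
window. The low-temperature gradient check runs at 10 K where the
entropic term (≈0.06 kJ/mol/nm) is 3 orders below the potential
gradient. Staged-protocol recovery uses injected Gaussian wells of depth
60/40/20/5 kJ/mol at 50 K and 1 500 steps per window — the resulting
ΔG_off standard error (~0.1 kJ/mol) is far below the 15 kJ/mol depth
gaps, so the depth order is recovered in 10/10 seeds. Enrichment checks
run the staged protocol over 100-decoy synthetic sets with an analytic
engine whose well depth decays with the decoy's measured I-rms
(5 + 60·e^(−I-rms/4 Å) kJ/mol, window noise 3 kJ/mol/nm). The
demonstration pipeline defaults to 2 000 steps per window, enough to
separate the quality tiers of the toy benchmark but not converged in any
physical sense.

## Known limitations

* The bead energetics are ordinal, not calibrated; ΔG_off values are not
  comparable to experimental binding free energies.
* Rigid bodies cannot report induced fit; decoys whose quality depends on
  conformational change are outside the model.
* The overdamped integrator ignores hydrodynamic coupling and uses an
  isotropic rotational mobility; these affect kinetics, not the
  constrained equilibrium averages used here, but only to leading order
  in the time step.
* `extract_dgoff` reads the global PMF minimum; for profiles with
  multiple wells the reported r_min may jump between replicates, and the
  replicate average mixes estimates of different wells.
* The printed classification rules differ from the official CAPRI tables
  in the corner regions noted above.
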