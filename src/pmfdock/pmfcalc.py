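"""Window schedules, PMF integration and binding free-energy extraction.

The reaction coordinate is the receptor-ligand centre-of-mass distance r.
Starting from a decoy's own COM distance ``dock_com``, a fixed two-series
window schedule is laid out: 23 distances spaced 0.05 nm starting 0.1 nm
below ``dock_com`` (the binding well, densely sampled) and 9 distances
spaced 0.1 nm starting 1.15 nm beyond it (the dissociated tail).

Mean constraint forces per window are integrated inward from the largest
distance with the trapezoidal rule to give the potential of mean force
(PMF), optionally removing the entropic Jacobian term 2 k_B T / r that a
distance constraint in 3-D acquires; with the correction on, two
non-interacting bodies yield a flat profile.  The binding free energy
proxy dG_off is the depth of the PMF minimum relative to the highest PMF
at any larger distance: more negative means stronger predicted binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .dynamics import KB, WindowSample

INNER_COUNT = 23
INNER_SPACING = 0.05   # nm
INNER_OFFSET = -0.1    # nm relative to dock_com
OUTER_COUNT = 9
OUTER_SPACING = 0.1    # nm
OUTER_OFFSET = 1.15    # nm relative to dock_com

__all__ = ["WindowSchedule", "PMFProfile", "DGoff", "make_schedule",
           "integrate_pmf", "extract_dgoff", "average_dgoff"]


@dataclass(frozen=True)
class WindowSchedule:
    """Ordered constrained distances for one decoy."""

    dock_com: float                 # nm
    distances: tuple                # nm, strictly increasing

    def __post_init__(self):
        d = np.asarray(self.distances, float)
        if d.size == 0:
            raise ValueError("empty schedule")
        if np.any(d <= 0):
            raise ValueError("all window distances must be > 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("window distances must be strictly increasing")


@dataclass(frozen=True)
class PMFProfile:
    """PMF values over the window distances; zero at the largest distance."""

    distances: tuple                # nm
    values: tuple                   # kJ/mol
    temperature: float              # K
    jacobian_correction: bool

    def __post_init__(self):
        if len(self.distances) != len(self.values):
            raise ValueError("distances and values differ in length")
        if abs(self.values[-1]) > 1e-9:
            raise ValueError("PMF must be zero at the largest distance")


@dataclass(frozen=True)
class DGoff:
    """Binding free energy proxy extracted from a PMF profile.

    ``value`` = PMF(r_min) - PMF(r_max) <= 0 where r_min is the location of
    the PMF minimum and r_max the highest PMF at a larger distance.
    ``replicate`` is an integer id or the string "mean"; in the latter case
    ``per_replicate`` carries the individual values averaged over.
    """

    value: float                    # kJ/mol
    r_min: float                    # nm
    r_max: float                    # nm
    replicate: object = 0
    per_replicate: tuple = field(default_factory=tuple)
    degenerate: bool = False

    def __post_init__(self):
        if self.value > 1e-9:
            raise ValueError("dG_off must be <= 0")
        if not self.degenerate and self.r_min > self.r_max:
            raise ValueError("r_min must not exceed r_max")


def make_schedule(dock_com: float) -> WindowSchedule:
    """Build the 23+9 window schedule around a decoy's COM distance.

    Inner series: ``dock_com - 0.1 + i*0.05`` for i = 0..22 (well region);
    outer series: ``dock_com + 1.15 + j*0.1`` for j = 0..8 (tail).  Raises
    ``ValueError`` when ``dock_com`` <= 0.1 nm, which would place a window
    at a non-positive distance.
    """
    if dock_com <= 0.1:
        raise ValueError("dock_com must exceed 0.1 nm")
    inner = dock_com + INNER_OFFSET + INNER_SPACING * np.arange(INNER_COUNT)
    outer = dock_com + OUTER_OFFSET + OUTER_SPACING * np.arange(OUTER_COUNT)
    distances = np.concatenate([inner, outer])
    return WindowSchedule(dock_com=float(dock_com),
                          distances=tuple(float(x) for x in distances))


def integrate_pmf(samples: list[WindowSample], temperature: float,
                  jacobian_correction: bool = True) -> PMFProfile:
    """Integrate mean constraint forces into a PMF profile.

    The integrand at distance s is ``-<f_c>(s) - 2 k_B T / s`` (the second
    term only with the correction on); the PMF at r_i is its trapezoidal
    integral from r_i to the largest window, so the profile is anchored at
    zero there and attraction (negative recorded forces beyond the entropic
    baseline) lowers the PMF in the well.
    """
    if len(samples) < 2:
        raise ValueError("need at least two windows")
    r = np.array([s.r for s in samples], float)
    f = np.array([s.mean_force for s in samples], float)
    if np.any(np.diff(r) < 0):
        raise ValueError("samples must be sorted ascending in r")
    if np.any(np.diff(r) == 0):
        raise ValueError("duplicate window distances")

    integrand = -f
    if jacobian_correction:
        integrand = integrand - 2.0 * KB * temperature / r
    cum = cumulative_trapezoid(integrand, r, initial=0.0)
    pmf = cum[-1] - cum          # integral from r_i to r_N
    return PMFProfile(distances=tuple(r), values=tuple(pmf),
                      temperature=float(temperature),
                      jacobian_correction=bool(jacobian_correction))


def extract_dgoff(profile: PMFProfile, replicate=0) -> DGoff:
    """Locate the PMF minimum and the highest later PMF; return their gap.

    Ties for the minimum go to the smallest distance (most bound state),
    ties for the maximum to the largest (most separated).  When the minimum
    sits at the last window there is no later maximum; the result is the
    degenerate ``value = 0`` with ``r_max = r_min``.
    """
    pmf = np.asarray(profile.values, float)
    r = np.asarray(profile.distances, float)
    i_min = int(np.argmin(pmf))                       # first occurrence
    if i_min == len(pmf) - 1:
        return DGoff(value=0.0, r_min=float(r[i_min]), r_max=float(r[i_min]),
                     replicate=replicate, degenerate=True)
    later = pmf[i_min + 1:]
    # last occurrence of the maximum among later points
    j_rel = len(later) - 1 - int(np.argmax(later[::-1]))
    i_max = i_min + 1 + j_rel
    return DGoff(value=float(pmf[i_min] - pmf[i_max]),
                 r_min=float(r[i_min]), r_max=float(r[i_max]),
                 replicate=replicate)


def average_dgoff(per_replicate: list[DGoff]) -> DGoff:
    """Arithmetic mean of per-replicate dG_off values.

    Averaging happens at the dG_off level (not at the force level); the
    returned record carries the individual values and the means of the
    per-replicate r_min / r_max locations.
    """
    if not per_replicate:
        raise ValueError("no replicate values to average")
    values = [d.value for d in per_replicate]
    return DGoff(value=float(np.mean(values)),
                 r_min=float(np.mean([d.r_min for d in per_replicate])),
                 r_max=float(np.mean([d.r_max for d in per_replicate])),
                 replicate="mean",
                 per_replicate=tuple(values),
                 degenerate=all(d.degenerate for d in per_replicate))
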