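"""Window schedules, PMF integration, dG_off extraction and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmfdock.dynamics import KB, RadialPotential, WindowSample
from pmfdock.pmfcalc import (DGoff, PMFProfile, average_dgoff, extract_dgoff,
                             integrate_pmf, make_schedule)
from pmfdock.synthgen import make_force_profiles


def profile_from(distances, values):
    v = np.asarray(values, float) - values[-1]
    return PMFProfile(distances=tuple(distances), values=tuple(v),
                      temperature=300.0, jacobian_correction=True)


# -- schedule --------------------------------------------------------------

def test_schedule_counts_and_printed_anchors():
    s = make_schedule(3.0)
    d = np.asarray(s.distances)
    assert len(d) == 32
    assert d[0] == pytest.approx(2.90)
    assert d[22] == pytest.approx(4.00)    # last inner
    assert d[23] == pytest.approx(4.15)    # first outer
    assert d[-1] == pytest.approx(4.95)


def test_schedule_rejects_tiny_dock_com():
    with pytest.raises(ValueError):
        make_schedule(0.05)


@settings(deadline=None, max_examples=50)
@given(st.floats(0.11, 50.0))
def test_schedule_structure_for_any_dock_com(d):
    s = make_schedule(d)
    dist = np.asarray(s.distances)
    assert len(dist) == 32
    gaps = np.diff(dist)
    assert gaps.min() == pytest.approx(0.05)
    # gap between the two series is exactly 0.15 nm
    assert gaps[22] == pytest.approx(0.15)
    assert np.all(dist > 0)


# -- integration -----------------------------------------------------------

def _samples(r, f, sd=0.0):
    return [WindowSample(r=float(ri), replicate=1, mean_force=float(fi),
                         stderr=sd, n_samples=1) for ri, fi in zip(r, f)]


def test_zero_forces_give_zero_pmf():
    r = np.linspace(2.0, 4.0, 20)
    p = integrate_pmf(_samples(r, np.zeros(20)), 300.0,
                      jacobian_correction=False)
    np.testing.assert_allclose(p.values, 0.0, atol=1e-12)


def test_harmonic_forces_integrate_to_closed_form():
    """Noise-free harmonic mean forces reproduce U(r) - U(r_N) within 2 %
    of the well depth at 0.05 nm spacing."""
    pot = RadialPotential(kind="harmonic", depth=25.0, r0=3.0, width=0.3)
    sched = make_schedule(3.0)
    samples = make_force_profiles(sched, pot, noise_sd=0.0)
    p = integrate_pmf(samples, 300.0, jacobian_correction=False)
    r = np.asarray(p.distances)
    expected = pot.u(r) - pot.u(r[-1])
    depth = float(pot.u(r[-1]) - pot.u(3.0))
    assert np.max(np.abs(np.asarray(p.values) - expected)) < 0.02 * depth


def test_jacobian_corrected_generator_forces_are_flat():
    """Forces carrying only the entropic term integrate to zero PMF when
    the correction is on (this fixes the sign convention)."""
    sched = make_schedule(3.0)
    zero = RadialPotential(kind="harmonic", depth=0.0, r0=3.0, width=0.3)
    samples = make_force_profiles(sched, zero, noise_sd=0.0,
                                  temperature=300.0, jacobian_term=True)
    p = integrate_pmf(samples, 300.0, jacobian_correction=True)
    np.testing.assert_allclose(p.values, 0.0, atol=1e-9)


def test_unsorted_or_duplicate_windows_rejected():
    r = [2.0, 3.0, 2.5]
    with pytest.raises(ValueError):
        integrate_pmf(_samples(r, [0, 0, 0]), 300.0)
    with pytest.raises(ValueError):
        integrate_pmf(_samples([2.0, 2.0, 3.0], [0, 0, 0]), 300.0)


def test_constant_force_offset_shifts_pmf_affinely():
    rng = np.random.default_rng(5)
    r = np.linspace(2.0, 4.0, 15)
    f = rng.normal(0, 5, 15)
    base = np.asarray(integrate_pmf(_samples(r, f), 300.0).values)
    for c in (0.01, 0.1, 1.0):
        shifted = np.asarray(
            integrate_pmf(_samples(r, f + c), 300.0).values)
        np.testing.assert_allclose(shifted, base - c * (r[-1] - r),
                                   atol=1e-9)
        # dG_off moves continuously with the force offset
        d0 = extract_dgoff(profile_from(r, base)).value
        d1 = extract_dgoff(profile_from(r, shifted)).value
        assert abs(d1 - d0) <= c * (r[-1] - r[0]) + 1e-9


# -- extraction ------------------------------------------------------------

def test_flat_profile_is_degenerate_zero():
    d = extract_dgoff(profile_from([1, 2, 3], [0, 0, 0]))
    assert d.value == 0.0
    # min ties break to the smallest distance
    assert d.r_min == 1.0


def test_monotone_profile_takes_full_depth():
    d = extract_dgoff(profile_from([1, 2, 3, 4], [-50, -30, -10, 0]))
    assert d.value == -50.0
    assert d.r_min == 1.0 and d.r_max == 4.0


def test_interior_minimum_and_later_barrier():
    d = extract_dgoff(profile_from([1, 2, 3, 4, 5], [-10, -30, -5, 5, 0]))
    assert d.value == pytest.approx(-35.0)
    assert d.r_min == 2.0 and d.r_max == 4.0


def test_extraction_matches_brute_force_over_pairs():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = rng.integers(3, 20)
        r = np.sort(rng.uniform(1, 5, n))
        r += np.arange(n) * 1e-6  # ensure strictly increasing
        v = rng.normal(0, 10, n)
        d = extract_dgoff(profile_from(r, v))
        v0 = v - v[-1]
        # independent scan: lowest PMF first, then the highest PMF beyond it
        i_min = 0
        for i in range(n):
            if v0[i] < v0[i_min]:
                i_min = i
        if i_min == n - 1:
            expected = 0.0
        else:
            expected = v0[i_min] - max(v0[i_min + 1:])
        assert d.value == pytest.approx(expected, abs=1e-9)
        assert d.r_min == pytest.approx(r[i_min])


def test_dgoff_invariant_to_reference_offset():
    rng = np.random.default_rng(3)
    r = np.sort(rng.uniform(1, 5, 12))
    v = rng.normal(0, 10, 12)
    a = extract_dgoff(profile_from(r, v)).value
    b = extract_dgoff(profile_from(r, v + 123.4)).value
    assert a == pytest.approx(b, abs=1e-9)


def test_min_at_last_point_is_degenerate():
    d = extract_dgoff(profile_from([1, 2, 3], [5, 2, 0]))
    assert d.value == 0.0 and d.degenerate
    assert d.r_max == d.r_min == 3.0


# -- averaging -------------------------------------------------------------

def _dg(v):
    return DGoff(value=v, r_min=1.0, r_max=2.0)


def test_average_examples_and_oracle():
    assert average_dgoff([_dg(-50.0)]).value == -50.0
    avg = average_dgoff([_dg(v) for v in (-40, -60, -50, -45, -55)])
    assert avg.value == pytest.approx(-50.0)
    assert avg.replicate == "mean"
    assert avg.per_replicate == (-40, -60, -50, -45, -55)
    rng = np.random.default_rng(2)
    for _ in range(20):
        vals = -rng.uniform(0, 100, 5)
        got = average_dgoff([_dg(v) for v in vals]).value
        assert got == pytest.approx(sum(vals) / 5)


def test_average_requires_values():
    with pytest.raises(ValueError):
        average_dgoff([])


def test_positive_dgoff_rejected():
    with pytest.raises(ValueError):
        DGoff(value=1.0, r_min=1.0, r_max=2.0)
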