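"""Deterministic dynamics: fixed points, reductions, dichotomy, integrals."""

import numpy as np
import pytest

from ydrive import (
    ModelParams,
    GenotypeSystem,
    cumulative_birth_integrals,
    derivatives,
    initial_state,
    simulate_trajectory,
    m_crit,
    suppressed_equilibrium_N1,
)


def test_baseline_equilibrium_is_fixed_point():
    """M = F = N0/2 zeroes the pre-release derivatives to machine precision."""
    p = ModelParams(R_m=6.0)
    system = GenotypeSystem.build("baseline", p)
    d = derivatives(np.array([0.5, 0.5]), 0.0, p, system)
    assert np.allclose(d, 0.0, atol=1e-14)


def test_drive_reduces_to_baseline_when_h_zero():
    """With no driving-Y males the drive system's M and F rates equal the
    pre-release model's."""
    p = ModelParams(R_m=6.0, m=0.95)
    drive = GenotypeSystem.build("drive", p)
    base = GenotypeSystem.build("baseline", p)
    state = np.array([0.0, 0.31, 0.42])
    d_drive = derivatives(state, 0.0, p, drive)
    d_base = derivatives(np.array([0.31, 0.42]), 0.0, p, base)
    assert d_drive[0] == pytest.approx(0.0, abs=1e-15)
    assert d_drive[1:] == pytest.approx(d_base)


def test_neutral_y_fraction_is_conserved():
    """At m = 0.5 the driving Y is a neutral marker: H/(H+M) stays constant
    along any trajectory."""
    p = ModelParams(m=0.5, h0=0.2)
    system = GenotypeSystem.build("drive", p)
    traj = simulate_trajectory(initial_state(p, system), p, system,
                               horizon=50.0)
    H, M = traj.states[:, 0], traj.states[:, 1]
    frac = H / (H + M)
    assert np.max(np.abs(frac - frac[0])) < 1e-8


def test_state_validation():
    p = ModelParams()
    system = GenotypeSystem.build("drive", p)
    with pytest.raises(ValueError):
        derivatives(np.array([-0.1, 0.5, 0.5]), 0.0, p, system)
    with pytest.raises(ValueError):
        derivatives(np.array([0.1, 0.5]), 0.0, p, system)
    with pytest.raises(ValueError):
        # u is a Model I parameter; rejected for the drive system
        derivatives(np.array([0.1, 0.5, 0.5]), 0.0, ModelParams(u=0.1), system)
    with pytest.raises(ValueError):
        ModelParams(m=0.3)
    with pytest.raises(ValueError):
        ModelParams(R_m=0.9)


def test_trajectory_nonnegative_and_eliminated(baseline_traj):
    assert np.all(baseline_traj.states >= 0.0)
    assert baseline_traj.outcome == "eliminated"


def test_outcome_dichotomy_without_mutation():
    """u = v = 0: elimination iff m > m_crit(R_m); below threshold the
    population converges to N1 = [2(1-m)R_m - 1]/[2(1-m)γ] within 1%."""
    for m, expect_elim in ((0.93, True), (0.9, False)):
        p = ModelParams(R_m=6.0, m=m)
        assert (m > m_crit(6.0)) == expect_elim
        system = GenotypeSystem.build("drive", p)
        traj = simulate_trajectory(initial_state(p, system), p, system,
                                   horizon=200.0)
        if expect_elim:
            assert traj.outcome == "eliminated"
        else:
            assert traj.outcome == "persisted"
            N1, flag = suppressed_equilibrium_N1(6.0, m, p.gamma)
            assert not flag
            assert traj.N[-1] == pytest.approx(N1, rel=1e-2)


def test_suppressed_equilibrium_cases():
    gamma = 5.0
    # neutral Y: N1 equals the wild-type equilibrium
    N1, _ = suppressed_equilibrium_N1(6.0, 0.5, gamma)
    assert N1 == pytest.approx(1.0)
    # at m_crit the suppressed equilibrium vanishes
    N1, _ = suppressed_equilibrium_N1(6.0, m_crit(6.0) - 1e-12, gamma)
    assert N1 == pytest.approx(0.0, abs=1e-9)
    # above m_crit: elimination flag
    _, flag = suppressed_equilibrium_N1(6.0, 0.95, gamma)
    assert flag


@pytest.mark.parametrize("variant", ["modelI", "modelII"])
def test_mutant_systems_reduce_to_drive(variant, baseline_traj):
    """With zero mutation rate the 7- and 9-class systems restricted to
    non-mutant classes reproduce the 3-class drive trajectory."""
    p = ModelParams(R_m=6.0, m=0.95, h0=0.05)
    system = GenotypeSystem.build(variant, p)
    traj = simulate_trajectory(initial_state(p, system), p, system)
    for t in (5.0, 10.0, 20.0, 40.0):
        s = traj.state_at(t)
        ref = baseline_traj.state_at(t)
        for lab in ("H", "M", "F"):
            assert s[system.index(lab)] == pytest.approx(
                ref[baseline_traj.system.index(lab)], rel=1e-4, abs=1e-9)
        # mutant classes stay identically zero
        mut = [k for k, c in enumerate(system.classes)
               if c not in ("H", "M", "F")]
        assert np.all(s[mut] == 0.0)


def test_birth_integrals_converged_and_m1_limit(baseline_traj):
    """Birth integrals are horizon-independent once the trajectory has
    eliminated, and a perfect drive (m = 1) sires no daughters."""
    ints = cumulative_birth_integrals(baseline_traj)
    assert not ints["truncated"]
    p = baseline_traj.params
    system = baseline_traj.system
    long_traj = simulate_trajectory(initial_state(p, system), p, system,
                                    horizon=800.0)
    ints2 = cumulative_birth_integrals(long_traj)
    for key in ("drivingY_males_born", "daughters_of_drivingY", "total_births"):
        assert ints[key] == pytest.approx(ints2[key], abs=1e-6)

    p1 = ModelParams(R_m=6.0, m=1.0, h0=0.05)
    sys1 = GenotypeSystem.build("drive", p1)
    traj1 = simulate_trajectory(initial_state(p1, sys1), p1, sys1)
    ints1 = cumulative_birth_integrals(traj1)
    assert ints1["daughters_of_drivingY"] == pytest.approx(0.0, abs=1e-12)


def test_trajectory_frame_roundtrip(baseline_traj):
    df = baseline_traj.to_frame()
    assert list(df.columns) == ["time", "H", "M", "F", "N_total"]
    assert np.allclose(df["N_total"], df[["H", "M", "F"]].sum(axis=1))
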