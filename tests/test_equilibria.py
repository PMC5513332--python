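"""Thresholds and long-run classification of the mutant systems."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ydrive import (
    ModelParams,
    GenotypeSystem,
    m_crit,
    no_spread_condition,
    simulate_trajectory,
    suppressed_equilibrium_N1,
    suppression_grid,
)
from ydrive.equilibria import classify_long_run, fitness_thresholds, rm_max_for_elimination


def test_m_crit_closed_form():
    assert m_crit(6.0) == pytest.approx(0.916667, abs=5e-7)
    assert m_crit(12.0) == pytest.approx(0.9583333, abs=5e-8)
    with pytest.raises(ValueError):
        m_crit(1.0)
    # the mutation-corrected elimination boundary inverts m_crit at u=0
    assert rm_max_for_elimination(m_crit(6.0)) == pytest.approx(6.0)


def test_suppressed_equilibrium_against_ode():
    """N1 closed form cross-checked by long-time integration at m=0.9."""
    p = ModelParams(R_m=6.0, m=0.9, h0=0.05)
    N1, flag = suppressed_equilibrium_N1(6.0, 0.9, p.gamma)
    assert not flag
    assert N1 == pytest.approx(0.2)
    system = GenotypeSystem.build("drive", p)
    from ydrive import initial_state
    traj = simulate_trajectory(initial_state(p, system), p, system,
                               horizon=300.0)
    assert traj.N[-1] == pytest.approx(N1, rel=1e-3)


def test_no_spread_condition_values():
    # cost-free resistance spreads for any m > 1/2
    assert not no_spread_condition(0.6, 1.0, 1.0)
    assert no_spread_condition(0.49, 1.0, 1.0)
    # lethal resistance never spreads
    assert no_spread_condition(0.999, 0.0, 0.0)
    # hand-computed threshold at w_FR=0.9, w_HR=0.81
    thr = 1.0 - 0.9 * 0.81 / (2.0 * (2.0 - 0.9))
    assert thr == pytest.approx(0.66864, abs=5e-6)
    assert no_spread_condition(thr - 1e-3, 0.9, 0.81)
    assert not no_spread_condition(thr + 1e-3, 0.9, 0.81)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(w=st.floats(0.05, 1.0))
def test_no_spread_threshold_monotone_in_fitness(w):
    """Costlier resistance (lower w) raises the no-spread threshold."""
    thr = 1.0 - (w * w**2) / (2.0 * (2.0 - w))
    assert 0.5 <= thr <= 1.0
    thr_costlier = 1.0 - (0.9 * w * (0.9 * w)**2) / (2.0 * (2.0 - 0.9 * w))
    assert thr_costlier >= thr - 1e-12


def test_no_spread_agrees_with_ode_invasion():
    """Just above the threshold a rare resistant X invades the
    drive-fixed suppressed equilibrium; just below it declines.

    The invasion background is the m < m_crit equilibrium (drive fixed,
    H = m/(1-m) F, N = N1) with one rare resistant heterozygous female.
    """
    w = 0.9          # w_FR = w, w_HR = w^2 in the single-parameter model
    thr = 1.0 - (w * w**2) / (2.0 * (2.0 - w))
    for m, expect_spread in ((thr + 0.03, True), (thr - 0.03, False)):
        p = ModelParams(R_m=6.0, m=m, w=w, u=0.0)
        system = GenotypeSystem.build("modelI", p)
        N1, _ = suppressed_equilibrium_N1(6.0, m, p.gamma)
        F = N1 * (1.0 - m)
        y0 = np.zeros(7)
        y0[system.index("H")] = N1 - F
        y0[system.index("F")] = F
        y0[system.index("F_R")] = 1e-9
        traj = simulate_trajectory(y0, p, system, horizon=400.0)
        growth = traj.state_at(traj.t_end)[system.index("F_R")] / 1e-9
        assert (growth > 10.0) == expect_spread
        assert (growth < 0.5) == (not expect_spread)


def test_threshold_anchors_well_ordered(thresholds_modelI, thresholds_modelII):
    """w_ex <= w1 wherever both exist, and the trans-acting suppressor is
    less tolerant of fitness costs than target-site resistance."""
    w1 = thresholds_modelI["w1"].value
    w_ex = thresholds_modelI["w_ex"].value
    assert 0.0 <= w_ex <= w1 <= 1.0
    assert thresholds_modelII["w_ex"].value >= w_ex


def test_w_ex_decreases_with_drive_strength():
    """Stronger drive tolerates a higher resistance cost: w_ex falls as m
    rises (Model I, R_m = 6)."""
    vals = [fitness_thresholds(6.0, m, 1e-6, "modelI")["w_ex"].value
            for m in (0.93, 0.95, 0.98)]
    assert vals[0] > vals[1] > vals[2]


def test_thresholds_insensitive_to_mutation_rate():
    """w1 moves by < 1e-3 across u in [1e-8, 1e-5]."""
    lo = fitness_thresholds(6.0, 0.95, 1e-8, "modelI")
    hi = fitness_thresholds(6.0, 0.95, 1e-5, "modelI")
    assert abs(lo["w1"].value - hi["w1"].value) < 1e-3
    assert abs(lo["w_ex"].value - hi["w_ex"].value) < 1e-3


def test_invasion_consistency_around_w_ex(thresholds_modelI):
    """Long-run female population is positive just above w_ex and zero
    just below."""
    w_ex = thresholds_modelI["w_ex"].value
    above = classify_long_run(ModelParams(R_m=6.0, m=0.95, w=w_ex + 0.01,
                                          u=1e-6), "modelI")
    below = classify_long_run(ModelParams(R_m=6.0, m=0.95, w=w_ex - 0.01,
                                          u=1e-6), "modelI")
    assert not above["eliminated"] and above["F_final"] > 0.0
    assert below["eliminated"]


def test_suppression_grid_structure():
    """Eliminated cells lie below the w_ex boundary; in the fixed-allele
    region the rescued population equals (w²R_m - 1)/(w²γ); for
    R_m >= 10.0001 at m = 0.95 the drive cannot eliminate at all."""
    df = suppression_grid([0.45, 0.7, 0.9], [6.0, 10.5], 0.95, 1e-6,
                          "modelI", horizon=1500.0)
    cell = df.set_index(["R_m", "w"])
    assert cell.loc[(6.0, 0.45), "eliminated"]
    assert not cell.loc[(6.0, 0.7), "eliminated"]
    assert not cell.loc[(10.5, 0.45), "eliminated"]  # m < m_crit(10.5)
    # fixed-allele rescued equilibrium, Model I: N = (w²R_m - 1)/(w²γ)
    res = classify_long_run(ModelParams(R_m=6.0, m=0.95, w=0.9, u=1e-6),
                            "modelI")
    assert res["fate"] == "fixed"
    w2 = 0.9**2
    assert res["N_final"] == pytest.approx((w2 * 6.0 - 1.0) / (w2 * 5.0),
                                           rel=1e-3)
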