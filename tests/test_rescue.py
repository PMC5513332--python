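"""Branching-process rescue probabilities: oracles, identities, monotonicity."""

from types import SimpleNamespace

import numpy as np
import pytest

from ydrive import (
    ModelParams,
    build_mutant_rates,
    calibrate_gamma0,
    establishment_curves,
    probability_mutation_arises,
    probability_rescue,
    release_time_scan,
    rescue_summary,
    small_mutation_limit,
)


def constant_rate_table(beta, horizon=60.0, n_types=1):
    """Stub rate table with time-constant rates (duck-typed for the solver)."""
    B = np.full((n_types, n_types), 0.0)
    np.fill_diagonal(B, beta)
    return SimpleNamespace(
        types=tuple(f"T{i}" for i in range(n_types)),
        rates_inf=B,
        rates=lambda t: B,
        traj=SimpleNamespace(t_end=horizon),
    )


def test_constant_rate_closed_form():
    """Single-type birth-death with constant birth rate β and death rate 1:
    p_est = 1 - 1/β, reproduced to 1e-6 by the backward solver."""
    for beta in (1.5, 2.0, 6.0):
        curves = establishment_curves(constant_rate_table(beta))
        p = curves.p(np.array([0.0, 10.0, 30.0]), "T0")
        assert np.allclose(p, 1.0 - 1.0 / beta, atol=1e-6)


def test_subcritical_constant_rate_is_zero():
    """β < 1 (subcritical): every lineage dies out, p_est ≡ 0 with flag."""
    curves = establishment_curves(constant_rate_table(0.8))
    assert curves.subcritical
    assert np.all(curves.p(np.linspace(0.0, 50.0, 7)) == 0.0)


def test_zero_fitness_kills_establishment(baseline_traj):
    """w = 0: all mutant birth rates vanish and p_est ≡ 0, P1 = 0."""
    params = ModelParams(R_m=6.0, m=0.95, h0=0.05, u=1.0, w=0.0)
    rates = build_mutant_rates(baseline_traj, params, "modelI")
    for t in (0.0, 5.0, 20.0):
        assert np.all(rates.rates(t) == 0.0)
    curves = establishment_curves(rates)
    assert curves.subcritical
    summary = probability_rescue(baseline_traj, curves, params, "modelI")
    assert summary.P1 == 0.0
    assert summary.subcritical


def test_male_mutant_rate_identity(baseline_traj):
    """Model I: hemizygous resistant males with wild vs driving Y have
    identical rate tables (both sire resistant daughters only)."""
    params = ModelParams(R_m=6.0, m=0.95, h0=0.05, u=1.0, w=0.9)
    rates = build_mutant_rates(baseline_traj, params, "modelI")
    for t in (0.0, 2.5, 10.0, 25.0, 60.0):
        B = rates.rates(t)
        assert B[1, :] == pytest.approx(B[2, :], abs=1e-15)
        # male types produce only females
        assert B[1, 1] == B[1, 2] == B[2, 1] == B[2, 2] == 0.0


def test_female_establishment_exceeds_male(modelI_pipeline):
    """A resistant daughter is more likely to establish than a resistant
    male at every arrival time (males transmit only via daughters)."""
    curves = modelI_pipeline["curves"]
    t = np.linspace(0.0, 40.0, 81)
    p = curves.p(t)
    assert np.all(p[:, 0] > p[:, 1])
    assert np.all(p[:, 0] > p[:, 2])


def test_probability_bounds_and_ordering(modelI_pipeline, modelII_pipeline):
    for pipe in (modelI_pipeline, modelII_pipeline):
        s = pipe["summary"]
        assert 0.0 <= s.P1 <= s.P_Mut <= 1.0
        assert s.P_Con == pytest.approx(s.P1 / s.P_Mut)


def test_perfect_drive_prevents_target_site_mutation(baseline_traj):
    """m = 1: driving-Y males sire no daughters, so no resistant X can
    ever arise (Model I)."""
    params = ModelParams(R_m=6.0, m=1.0, h0=0.05, u=1.0)
    from ydrive import GenotypeSystem, initial_state, simulate_trajectory
    system = GenotypeSystem.build("drive", params.with_(u=0.0))
    traj = simulate_trajectory(initial_state(params, system),
                               params.with_(u=0.0), system)
    res = probability_mutation_arises(traj, params, "modelI")
    assert res["P_Mut"] == pytest.approx(0.0, abs=1e-12)


def test_small_mutation_limit(baseline_traj):
    """P1 and P_Mut are linear in uN0 for small uN0 (Taylor remainder of
    1 - exp(-x)), and their ratio is supply-independent."""
    params = ModelParams(R_m=6.0, m=0.95, h0=0.05, u=1e-3)
    rates = build_mutant_rates(baseline_traj, params, "modelI")
    curves = establishment_curves(rates)
    s = probability_rescue(baseline_traj, curves, params, "modelI")
    lin = small_mutation_limit(baseline_traj, curves, params, "modelI")
    assert abs(lin["P1_linear"] - s.P1) / s.P1 < 1e-3
    assert abs(lin["P_Mut_linear"] - s.P_Mut) / s.P_Mut < 1e-3
    # ratio of the linear forms equals the conditional probability limit
    params10 = params.with_(u=1e-2)
    lin10 = small_mutation_limit(baseline_traj, curves, params10, "modelI")
    assert (lin["P1_linear"] / lin["P_Mut_linear"]
            == pytest.approx(lin10["P1_linear"] / lin10["P_Mut_linear"]))
    assert s.P_Con == pytest.approx(lin["P1_linear"] / lin["P_Mut_linear"],
                                    rel=2e-3)


@pytest.mark.parametrize("variant,mut_field", [("modelI", "u"),
                                               ("modelII", "v")])
def test_monotonicity_in_parameters(variant, mut_field):
    """P1 increases with mutation supply, R_m and w; decreases with m."""
    base = {"R_m": 6.0, "m": 0.95, "h0": 0.05, mut_field: 1.0}

    def p1(**over):
        kw = dict(base)
        kw.update(over)
        return rescue_summary(ModelParams(**kw), variant).P1

    supply = [p1(**{mut_field: x}) for x in (0.1, 0.3, 1.0)]
    assert supply[0] < supply[1] < supply[2]
    growth = [p1(R_m=x) for x in (4.0, 6.0, 8.0)]
    assert growth[0] < growth[1] < growth[2]
    fitness = [p1(w=x) for x in (0.8, 0.9, 1.0)]
    assert fitness[0] < fitness[1] < fitness[2]
    drive = [p1(m=x) for x in (0.93, 0.95, 0.97)]
    assert drive[0] > drive[1] > drive[2]


def test_release_scan_flat_without_seasonality():
    """a = 0: the release-time scan is flat and equals the non-seasonal
    probabilities."""
    params = ModelParams(R_m=6.0, m=0.95, h0=0.05, u=1.0)
    forcing = calibrate_gamma0(0.0, 18.25, params)
    df = release_time_scan(params, forcing, n_release=4)
    s0 = rescue_summary(params, "modelI")
    assert np.allclose(df["P1"], s0.P1, rtol=1e-8)
    assert np.allclose(df["P_Mut"], s0.P_Mut, rtol=1e-8)
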