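"""Deterministic dynamics: ODE right-hand sides, trajectories, birth integrals.

The governing equations generalize the logistic two-sex model.  Writing
``r(t) = R_m - γ(t) N(t)`` for the per-female density-dependent recruitment
rate, each female of class ``i`` (fitness ``f_i``) produces offspring at
total rate ``2 r f_i``; every birth draws a father from the male pool
weighted by count × male fitness, and the offspring class follows the
variant's birth tensor (see :mod:`ydrive.genotypes`).  Every class dies at
rate 1, so time is measured in generations.

For the ``drive`` variant this reduces exactly to

    dH/dt = 2 r m H/(H+M) F - H
    dM/dt =   r   M/(H+M) F - M
    dF/dt =   r [M + 2(1-m) H]/(H+M) F - F

and for ``baseline`` (H = 0) to the pre-release model dM/dt = r F - M,
dF/dt = r F - F with equilibrium N0 = (R_m - 1)/γ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .genotypes import GenotypeSystem
from .params import ModelParams, SeasonalForcing

__all__ = [
    "derivatives",
    "simulate_trajectory",
    "cumulative_birth_integrals",
    "Trajectory",
    "ELIMINATION_THRESHOLD",
]

# normalized population below which a deterministic run counts as eliminated
ELIMINATION_THRESHOLD = 1e-8


def _gamma_fn(params: ModelParams, forcing: SeasonalForcing | None):
    if forcing is None or forcing.a == 0.0:
        g0 = params.gamma if forcing is None else forcing.gamma0_calibrated
        return lambda t: g0
    return forcing.gamma


def _rhs_factory(params: ModelParams, system: GenotypeSystem,
                 forcing: SeasonalForcing | None):
    gamma = _gamma_fn(params, forcing)
    R_m = params.R_m
    T = system.birth_tensor
    f_idx, m_idx = system.female_idx, system.male_idx
    f_fit, m_fit = system.female_fitness, system.male_fitness
    n = system.n_classes

    def rhs(t, y):
        state = y[:n]
        N = state.sum()
        r = R_m - gamma(t) * N
        males = state[m_idx]
        weights = males * m_fit
        wsum = weights.sum()
        dy = -state.copy()
        if wsum > 0.0:
            pi = weights / wsum
            mothers = 2.0 * r * f_fit * state[f_idx]
            births = np.einsum("f,a,fak->k", mothers, pi, T)
            dy += births
        return dy

    return rhs


def derivatives(state, t: float, params: ModelParams, system: GenotypeSystem,
                forcing: SeasonalForcing | None = None) -> np.ndarray:
    """Instantaneous class rates at ``state`` and time ``t``.

    Rejects negative abundances and parameters inconsistent with the
    variant (``u`` is meaningful only for Model I, ``v`` only for Model II).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (system.n_classes,):
        raise ValueError(
            f"state must have length {system.n_classes} for {system.variant}")
    if np.any(state < 0.0):
        raise ValueError("state components must be nonnegative")
    if system.variant != "modelI" and params.u != 0.0:
        raise ValueError("u is only meaningful for variant 'modelI'")
    if system.variant != "modelII" and params.v != 0.0:
        raise ValueError("v is only meaningful for variant 'modelII'")
    return _rhs_factory(params, system, forcing)(t, state)


@dataclass
class Trajectory:
    """Deterministic trajectory with dense output.

    Abundances are in the same units as the initial condition (normalized
    by ``N0`` in the default workflow).  ``outcome`` is ``"eliminated"``
    when the total population fell below ``ELIMINATION_THRESHOLD * N0``
    before the horizon, else ``"persisted"``.
    """

    t: np.ndarray
    states: np.ndarray            # shape (n_times, n_classes)
    params: ModelParams
    system: GenotypeSystem
    forcing: SeasonalForcing | None
    outcome: str
    t_end: float
    _dense: object                # scipy OdeSolution over [0, t_end]

    @property
    def N(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def F_total(self) -> np.ndarray:
        return self.states[:, self.system.female_idx].sum(axis=1)

    def state_at(self, t) -> np.ndarray:
        """Dense-output state, clipped at the trajectory end time."""
        t = np.minimum(np.asarray(t, dtype=float), self.t_end)
        return np.maximum(self._dense(t), 0.0)

    def class_at(self, t, label: str):
        return self.state_at(t)[self.system.index(label)]

    def drive_fraction(self, t):
        """Driving-Y fraction among the (fitness-weighted) father pool."""
        s = self.state_at(t)
        males = s[self.system.male_idx] * self.system.male_fitness
        tot = males.sum(axis=0)
        drive = s[self.system.drive_male_idx].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, drive / tot, 0.0)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.system.classes))
        df.insert(0, "time", self.t)
        df["N_total"] = self.N
        return df


def initial_state(params: ModelParams, system: GenotypeSystem,
                  forcing: SeasonalForcing | None = None,
                  t_release: float = 0.0) -> np.ndarray:
    """Wild-type equilibrium plus the driving-Y release ``H(0) = h0·N0``.

    In seasonal mode the wild-type population starts on the pre-release
    attractor evaluated at seasonal time ``t_release``, while the number
    released is still ``h0`` times the *time-averaged* population ``N0``.
    """
    y0 = np.zeros(system.n_classes)
    if forcing is not None and forcing.a > 0.0:
        F0 = forcing.prerelease_female(t_release)
    else:
        F0 = params.N0 / 2.0
    y0[system.index("F")] = F0
    y0[system.index("M")] = F0
    if "H" in system.classes:
        y0[system.index("H")] = params.h0 * params.N0
    elif params.h0 != 0.0:
        raise ValueError("baseline variant has no driving-Y class to release")
    return y0


def simulate_trajectory(initial, params: ModelParams, system: GenotypeSystem,
                        forcing: SeasonalForcing | None = None,
                        horizon: float = 400.0,
                        n_out: int = 2001,
                        rtol: float = 1e-9, atol: float = 1e-12,
                        method: str = "LSODA") -> Trajectory:
    """Integrate the genotype ODE system from ``initial`` up to ``horizon``.

    Integration stops early (terminal event) once the total population
    drops below ``ELIMINATION_THRESHOLD`` times its scale ``N0``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    initial = np.asarray(initial, dtype=float)
    if np.any(initial < 0.0):
        raise ValueError("initial state must be nonnegative")
    rhs = _rhs_factory(params, system, forcing)
    eps = ELIMINATION_THRESHOLD * params.N0

    def eliminated(t, y):
        return y.sum() - eps

    eliminated.terminal = True
    eliminated.direction = -1

    sol = solve_ivp(rhs, (0.0, horizon), initial, method=method, rtol=rtol,
                    atol=atol * params.N0, dense_output=True,
                    events=eliminated)
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(
            f"ODE solver failed for variant={system.variant}, "
            f"params={params}: {sol.message}")
    t_end = sol.t[-1]
    outcome = "eliminated" if sol.t_events[0].size else "persisted"
    t_out = np.linspace(0.0, t_end, n_out)
    states = np.maximum(sol.sol(t_out).T, 0.0)
    return Trajectory(t=t_out, states=states, params=params, system=system,
                      forcing=forcing, outcome=outcome, t_end=t_end,
                      _dense=sol.sol)


def _birth_terms(traj: Trajectory, t):
    """Per-time birth-rate components of the drive system (per Eq-2 terms):
    driving-Y male births, daughters of driving-Y males, total births."""
    params, system = traj.params, traj.system
    gamma = _gamma_fn(params, traj.forcing)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s = traj.state_at(t)
    N = s.sum(axis=0)
    g = np.asarray([gamma(tt) for tt in t])
    r = params.R_m - g * N
    males = s[system.male_idx] * system.male_fitness[:, None]
    wsum = males.sum(axis=0)
    drive = s[system.drive_male_idx].sum(axis=0)
    # driving-Y male fitness is 1 in all variants, so counts equal weights
    mothers = (system.female_fitness[:, None] * s[system.female_idx]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_drive = np.where(wsum > 0, drive / wsum, 0.0)
    total = 2.0 * r * mothers
    m = params.m
    drive_sons = total * m * frac_drive
    drive_daughters = total * (1.0 - m) * frac_drive
    return drive_sons, drive_daughters, total


def cumulative_birth_integrals(traj: Trajectory, n_points: int = 4001) -> dict:
    """Time integrals of birth rates from release to elimination.

    Returns ``drivingY_males_born``, ``daughters_of_drivingY`` and
    ``total_births`` in multiples of ``N0``.  ``truncated`` flags a
    trajectory that never reached effective elimination, in which case the
    integrals only cover the integrated horizon.
    """
    t = np.linspace(0.0, traj.t_end, n_points)
    sons, daughters, total = _birth_terms(traj, t)
    from scipy.integrate import simpson

    out = {
        "drivingY_males_born": float(simpson(sons, x=t)) / traj.params.N0,
        "daughters_of_drivingY": float(simpson(daughters, x=t)) / traj.params.N0,
        "total_births": float(simpson(total, x=t)) / traj.params.N0,
        "truncated": traj.outcome != "eliminated",
    }
    return out
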