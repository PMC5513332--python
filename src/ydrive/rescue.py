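"""Rescue probabilities from a time-inhomogeneous multi-type branching process.

While the driving Y eliminates the (deterministic, non-mutant) background
population, rare mutant lineages experience time-varying birth rates built
from that background.  For each mutant type ``n`` the extinction
probability ``q_n(t_a)`` of a lineage founded at time ``t_a`` solves the
backward system

    dq_n/dt = (q_n - 1) + q_n * sum_k beta_nk(t) * (1 - q_k),

integrated backwards from the stable fixed point of the late-time
autonomous system (every lineage member also dies at rate 1).  The
establishment probability is ``p_est,n = 1 - q_n``.  Integrating the
establishment-weighted rate at which mutants are created along the
background trajectory yields ``P1`` (at least one mutation arises *and*
establishes); dropping the establishment weight yields ``P_Mut``; their
ratio is the conditional establishment probability ``P_Con``.

Mutant types: Model I — ``F_R`` (resistant heterozygous female), ``M_R``
and ``H_R`` (hemizygous resistant males with wild/driving Y).  Model II —
``F_S``, ``M_S``, ``H_S`` (suppressor heterozygotes).  Homozygotes are
products of two rare lineages and are excluded from the linearization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .genotypes import GenotypeSystem
from .model_core import Trajectory, initial_state, simulate_trajectory
from .params import ModelParams, SeasonalForcing

__all__ = [
    "MutantRateTable",
    "EstablishmentCurve",
    "RescueSummary",
    "build_mutant_rates",
    "establishment_curves",
    "probability_mutation_arises",
    "probability_rescue",
    "rescue_summary",
    "small_mutation_limit",
    "release_time_scan",
]

#: generations of buffer past background elimination before the terminal
#: fixed point of the autonomous late-time process is applied
TERMINAL_BUFFER = 20.0

MUTANT_TYPES = {"modelI": ("F_R", "M_R", "H_R"),
                "modelII": ("F_S", "M_S", "H_S")}


@dataclass
class MutantRateTable:
    """Time-varying linearized birth rates ``beta[n, k](t)`` per mutant type.

    ``rates(t)`` returns the matrix ``beta_nk`` (births of type ``k`` to a
    lineage member of type ``n``); the common death rate is 1.  Beyond the
    background's elimination time the analytic late-time limits
    ``rates_inf`` apply.
    """

    variant: str
    types: tuple[str, ...]
    params: ModelParams
    traj: Trajectory
    rates_inf: np.ndarray

    def _background(self, t):
        traj = self.traj
        s = traj.state_at(t)
        sys = traj.system
        H = s[sys.index("H")]
        M = s[sys.index("M")]
        F = s[sys.index("F")]
        N = s.sum(axis=0) if s.ndim > 1 else s.sum()
        gamma = (self.params.gamma if traj.forcing is None or traj.forcing.a == 0.0
                 else None)
        if gamma is None:
            r = self.params.R_m - np.asarray(traj.forcing.gamma(t)) * N
        else:
            r = self.params.R_m - gamma * N
        return H, M, F, r

    def rates(self, t: float) -> np.ndarray:
        if t >= self.traj.t_end:
            return self.rates_inf
        H, M, F, r = self._background(t)
        HM = H + M
        if HM <= 0.0:
            return self.rates_inf
        m, w = self.params.m, self.params.w
        beta = np.zeros((3, 3))
        if self.variant == "modelI":
            # F_R -> (F_R, M_R, H_R): daughters/sons carrying the maternal R
            beta[0, 0] = w * r * 0.5 * (M + 2.0 * (1.0 - m) * H) / HM
            beta[0, 2] = w * r * 0.5 * 2.0 * m * H / HM
            beta[0, 1] = w * r * 0.5 * M / HM
            # hemizygous males sire resistant daughters only
            beta[1, 0] = beta[2, 0] = w * w * r * F / HM
        else:
            beta[0, 0] = w * r * 0.5 * (M + 2.0 * (1.0 - m) * H) / HM
            beta[0, 2] = w * r * 0.5 * 2.0 * m * H / HM
            beta[0, 1] = w * r * 0.5 * M / HM
            # suppressor males transmit to both sexes at Mendelian rates
            beta[1, 1] = beta[1, 0] = 0.5 * w * r * F / HM
            beta[2, 2] = beta[2, 0] = 0.5 * w * r * F / HM
        return np.maximum(beta, 0.0)


def _late_time_rates(variant: str, params: ModelParams) -> np.ndarray:
    """Autonomous rate matrix of the eliminated background (t -> infinity).

    In the eliminating regime the driving Y fixes among fathers
    (H/(H+M) -> 1, M/(H+M) -> 0), recruitment tends to R_m, and
    F/(H+M) -> (1-m)/m.
    """
    m, w, R_m = params.m, params.w, params.R_m
    beta = np.zeros((3, 3))
    f_over_hm = (1.0 - m) / m
    if variant == "modelI":
        beta[0, 0] = w * R_m * (1.0 - m)
        beta[0, 2] = w * R_m * m
        beta[1, 0] = beta[2, 0] = w * w * R_m * f_over_hm
    else:
        beta[0, 0] = w * R_m * (1.0 - m)
        beta[0, 2] = w * R_m * m
        beta[1, 1] = beta[1, 0] = 0.5 * w * R_m * f_over_hm
        beta[2, 2] = beta[2, 0] = 0.5 * w * R_m * f_over_hm
    return beta


def build_mutant_rates(traj: Trajectory, params: ModelParams,
                       variant: str) -> MutantRateTable:
    """Linearized mutant birth rates along a non-mutant background trajectory.

    The background must be the ``drive`` system with ``u = v = 0``; the
    mutation parameters enter only through the creation-rate integrals,
    not the per-lineage rates.
    """
    if variant not in MUTANT_TYPES:
        raise ValueError(f"variant must be modelI or modelII, got {variant!r}")
    for label in ("H", "M", "F"):
        if label not in traj.system.classes:
            raise ValueError("background trajectory must contain H, M, F classes")
    return MutantRateTable(variant=variant, types=MUTANT_TYPES[variant],
                           params=params, traj=traj,
                           rates_inf=_late_time_rates(variant, params))


def _terminal_fixed_point(beta: np.ndarray, tol: float = 1e-14,
                          max_iter: int = 100000) -> np.ndarray:
    """Minimal fixed point of q_n = 1/(1 + sum_k beta_nk (1 - q_k)).

    Iterating from q = 0 converges monotonically to the extinction
    probability of the autonomous process; q = 1 when subcritical.
    """
    q = np.zeros(beta.shape[0])
    for _ in range(max_iter):
        q_new = 1.0 / (1.0 + beta @ (1.0 - q))
        if np.max(np.abs(q_new - q)) < tol:
            return q_new
        q = q_new
    return q  # pragma: no cover - convergence is geometric


@dataclass
class EstablishmentCurve:
    """Establishment probabilities ``p_est,n(t_a)`` on an arrival-time grid."""

    types: tuple[str, ...]
    t: np.ndarray
    p_est: np.ndarray            # shape (n_times, n_types)
    terminal_extinction: np.ndarray
    subcritical: bool
    _dense: object = field(default=None, repr=False)

    def p(self, t, type_name: str | None = None):
        """Dense establishment probability at arrival time(s) ``t``."""
        t = np.minimum(np.asarray(t, dtype=float), self.t[-1])
        if self.subcritical or self._dense is None:
            vals = np.zeros(np.shape(t) + (len(self.types),))
        else:
            q = np.clip(self._dense(t), 0.0, 1.0)
            vals = np.moveaxis(1.0 - q, 0, -1)
        if type_name is None:
            return vals
        return vals[..., self.types.index(type_name)]


def establishment_curves(rates: MutantRateTable,
                         horizon: float | None = None,
                         rtol: float = 1e-9, atol: float = 1e-12) -> EstablishmentCurve:
    """Solve the backward extinction ODEs along the background trajectory.

    The terminal condition at ``horizon`` (default: background elimination
    time plus a buffer) is the stable fixed point of the late-time
    autonomous process; if that process is subcritical every lineage dies
    out and ``p_est`` is identically zero (flagged).
    """
    if horizon is None:
        horizon = rates.traj.t_end + TERMINAL_BUFFER
    q_star = _terminal_fixed_point(rates.rates_inf)
    subcritical = bool(np.all(q_star > 1.0 - 1e-10))
    n = len(rates.types)
    t_grid = np.linspace(0.0, horizon, 801)
    if subcritical:
        return EstablishmentCurve(types=rates.types, t=t_grid,
                                  p_est=np.zeros((t_grid.size, n)),
                                  terminal_extinction=q_star,
                                  subcritical=True)

    def rhs(t, q):
        beta = rates.rates(t)
        return (q - 1.0) + q * (beta @ (1.0 - q))

    sol = solve_ivp(rhs, (horizon, 0.0), q_star, method="LSODA", rtol=rtol,
                    atol=atol, dense_output=True)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"backward extinction solve failed: {sol.message}")
    p = np.clip(1.0 - sol.sol(t_grid).T, 0.0, 1.0)
    return EstablishmentCurve(types=rates.types, t=t_grid, p_est=p,
                              terminal_extinction=q_star, subcritical=False,
                              _dense=sol.sol)


def _creation_integrands(traj: Trajectory, params: ModelParams, variant: str,
                         t: np.ndarray):
    """Mutant-creation rate channels along the background (normalized)."""
    sys = traj.system
    s = traj.state_at(t)
    H = s[sys.index("H")]
    M = s[sys.index("M")]
    F = s[sys.index("F")]
    N = s.sum(axis=0)
    if traj.forcing is not None and traj.forcing.a > 0.0:
        r = params.R_m - np.asarray(traj.forcing.gamma(t)) * N
    else:
        r = params.R_m - params.gamma * N
    r = np.maximum(r, 0.0)
    HM = np.maximum(H + M, 1e-300)
    return H, M, F, r, HM


def probability_mutation_arises(traj: Trajectory, params: ModelParams,
                                variant: str, n_points: int = 4001) -> dict:
    """``P_Mut``: probability at least one mutation arises before elimination.

    Model I integrates the rate at which resistant daughters of driving-Y
    males are born, ``2(1-m)(uN0) r F H/(H+M)``; Model II the genome-wide
    suppressor mutation rate ``4(vN0) r F``.  Returns the probability, the
    exponent (the expected number of mutants created), and a divergence
    flag for non-eliminating backgrounds.
    """
    t = np.linspace(0.0, traj.t_end, n_points)
    H, M, F, r, HM = _creation_integrands(traj, params, variant, t)
    scale = params.N0
    if variant == "modelI":
        integrand = r * (F / scale) * H / HM
        exponent = 2.0 * (1.0 - params.m) * params.uN0 * simpson(integrand, x=t)
    elif variant == "modelII":
        integrand = r * (F / scale)
        exponent = 4.0 * params.vN0 * simpson(integrand, x=t)
    else:
        raise ValueError(f"variant must be modelI or modelII, got {variant!r}")
    diverged = traj.outcome != "eliminated"
    P_Mut = 1.0 if diverged else 1.0 - math.exp(-exponent)
    return {"P_Mut": P_Mut, "exponent": float(exponent), "diverged": diverged}


def probability_rescue(traj: Trajectory, curves: EstablishmentCurve,
                       params: ModelParams, variant: str,
                       n_points: int = 4001) -> "RescueSummary":
    """``P1``: probability a mutation arises *and* establishes (Eqs for
    rescue), together with ``P_Mut`` and ``P_Con = P1/P_Mut``."""
    t = np.linspace(0.0, traj.t_end, n_points)
    H, M, F, r, HM = _creation_integrands(traj, params, variant, t)
    scale = params.N0
    p = curves.p(t)  # (n_times, 3), order (F, M, H) mutant types
    if variant == "modelI":
        integrand = p[:, 0] * r * (F / scale) * H / HM
        exponent1 = 2.0 * (1.0 - params.m) * params.uN0 * simpson(integrand, x=t)
    else:
        mix = (p[:, 0] * (M + 2.0 * (1.0 - params.m) * H) / HM
               + p[:, 2] * 2.0 * params.m * H / HM
               + p[:, 1] * M / HM)
        integrand = r * (F / scale) * mix
        exponent1 = 2.0 * params.vN0 * simpson(integrand, x=t)
    mut = probability_mutation_arises(traj, params, variant, n_points)
    P1 = 1.0 - math.exp(-exponent1)
    P_Mut = mut["P_Mut"]
    P_Con = P1 / P_Mut if P_Mut > 0.0 else float("nan")
    return RescueSummary(P1=float(P1), P_Mut=float(P_Mut), P_Con=float(P_Con),
                         exponent_P1=float(exponent1),
                         exponent_P_Mut=mut["exponent"],
                         diverged=mut["diverged"],
                         subcritical=curves.subcritical,
                         variant=variant, params=params, method="branching")


@dataclass(frozen=True)
class RescueSummary:
    """Rescue probabilities for one scenario.

    ``P1 <= P_Mut`` always; ``P_Con`` is undefined (NaN) when ``P_Mut`` is
    zero.  ``subcritical`` flags a late-time branching process in which no
    lineage can establish; ``diverged`` flags a background that never
    eliminated (P_Mut reported as 1).
    """

    P1: float
    P_Mut: float
    P_Con: float
    exponent_P1: float
    exponent_P_Mut: float
    diverged: bool
    subcritical: bool
    variant: str
    params: ModelParams
    method: str = "branching"


def small_mutation_limit(traj: Trajectory, curves: EstablishmentCurve,
                         params: ModelParams, variant: str) -> dict:
    """Linear-in-mutation-rate approximations (exponents of P_Mut and P1).

    For ``uN0`` (or ``vN0``) ≪ 1 both probabilities are proportional to the
    mutation supply, so their ratio — the conditional establishment
    probability — is independent of it.
    """
    summary = probability_rescue(traj, curves, params, variant)
    return {"P_Mut_linear": summary.exponent_P_Mut,
            "P1_linear": summary.exponent_P1}


def rescue_summary(params: ModelParams, variant: str,
                   forcing: SeasonalForcing | None = None,
                   t_release: float = 0.0,
                   horizon: float = 400.0) -> RescueSummary:
    """End-to-end branching-process pipeline for one scenario.

    Integrates the non-mutant background, builds the linearized mutant
    rates, solves the backward extinction system, and evaluates the rescue
    probabilities.
    """
    background = params.with_(u=0.0, v=0.0)
    system = GenotypeSystem.build("drive", background)
    if forcing is not None and forcing.a > 0.0:
        forcing = forcing.with_phase(t_release)
    y0 = initial_state(background, system, forcing, t_release=t_release)
    traj = simulate_trajectory(y0, background, system, forcing, horizon=horizon)
    rates = build_mutant_rates(traj, params, variant)
    curves = establishment_curves(rates)
    return probability_rescue(traj, curves, params, variant)


def release_time_scan(params: ModelParams, forcing: SeasonalForcing,
                      variant: str = "modelI", n_release: int = 24,
                      horizon: float = 600.0):
    """Scan rescue probabilities over driving-Y release times in one period.

    Each release time integrates its own background (started on the
    pre-release attractor at that seasonal phase) and its own
    establishment curves.  Returns a DataFrame with one row per release
    time plus the uniform average ``P1_avg`` over the period.
    """
    import pandas as pd

    grid = np.linspace(0.0, forcing.T, n_release, endpoint=False)
    rows = []
    for t_rel in grid:
        try:
            s = rescue_summary(params, variant, forcing=forcing,
                               t_release=float(t_rel), horizon=horizon)
            rows.append({"t_release": float(t_rel),
                         "t_release_months": float(t_rel) * 12.0 / forcing.T,
                         "P_Mut": s.P_Mut, "P1": s.P1, "P_Con": s.P_Con,
                         "failed": False})
        except RuntimeError as exc:  # pragma: no cover - per-point failure
            rows.append({"t_release": float(t_rel),
                         "t_release_months": float(t_rel) * 12.0 / forcing.T,
                         "P_Mut": np.nan, "P1": np.nan, "P_Con": np.nan,
                         "failed": True, "error": str(exc)})
    df = pd.DataFrame(rows)
    P1_avg = float(df.loc[~df["failed"], "P1"].mean())
    df.attrs["P1_avg"] = P1_avg
    return df
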