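"""Long-run outcomes: drive thresholds, fitness thresholds, suppression grids.

Closed forms exist for the drive-only system: elimination requires
``m > m_crit = 1 - 1/(2 R_m)``; below that the driving Y fixes and the
population persists at ``N1 = [2(1-m)R_m - 1]/[2(1-m)γ]``.  The fitness
thresholds of the mutant systems — ``w1``, above which the resistant or
suppressor allele fixes, and ``w_ex``, below which the population is
eliminated despite resistance — are located by bisection on the long-run
outcome of the full deterministic genotype ODEs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import GenotypeSystem
from .model_core import simulate_trajectory
from .params import ModelParams

__all__ = [
    "m_crit",
    "rm_max_for_elimination",
    "suppressed_equilibrium_N1",
    "classify_long_run",
    "fitness_thresholds",
    "suppression_grid",
    "no_spread_condition",
    "ThresholdResult",
]

#: integration horizon used for asymptotic (long-run) classification
LONG_RUN_HORIZON = 2000.0
#: susceptible-allele frequency below which the mutant counts as fixed
FIXATION_FREQ = 1e-3


def m_crit(R_m: float) -> float:
    """Critical driving-Y transmission rate for elimination, 1 - 1/(2 R_m)."""
    if R_m <= 1.0:
        raise ValueError(f"m_crit undefined for R_m <= 1, got {R_m}")
    return 1.0 - 1.0 / (2.0 * R_m)


def rm_max_for_elimination(m: float, u: float = 0.0) -> float:
    """Largest R_m at which a drive of strength ``m`` still eliminates.

    With target-site mutation pressure ``u`` the boundary shifts to
    ``R_m = 1/[2(1-m)(1-u)]``; ``u = 0`` inverts ``m_crit``.
    """
    if m >= 1.0:
        return np.inf
    return 1.0 / (2.0 * (1.0 - m) * (1.0 - u))


def suppressed_equilibrium_N1(R_m: float, m: float, gamma: float):
    """Suppressed equilibrium ``N1 = [2(1-m)R_m - 1]/[2(1-m)γ]`` for m < m_crit.

    Returns ``(N1, eliminated_flag)``; for ``m >= m_crit`` there is no
    positive equilibrium and the flag is set.
    """
    if m >= m_crit(R_m):
        return 0.0, True
    N1 = (2.0 * (1.0 - m) * R_m - 1.0) / (2.0 * (1.0 - m) * gamma)
    return N1, False


def no_spread_condition(m: float, w_FR: float, w_HR: float) -> bool:
    """True when a resistant X cannot invade: m < 1 - w_FR·w_HR/(2(2-w_FR)).

    ``w_FR`` and ``w_HR`` are the fitnesses of resistant heterozygous
    females and of driving-Y males carrying a resistant X.  This is the
    u = 0 invasion condition; it recovers Mendelian neutrality (threshold
    1/2) when both fitnesses are 1.
    """
    for name, val in (("w_FR", w_FR), ("w_HR", w_HR)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {val}")
    return m < 1.0 - (w_FR * w_HR) / (2.0 * (2.0 - w_FR))


@dataclass(frozen=True)
class ThresholdResult:
    name: str
    value: float
    context: dict
    method: str


def _mutant_system(variant: str, params: ModelParams) -> GenotypeSystem:
    if variant not in ("modelI", "modelII"):
        raise ValueError(f"fitness thresholds require modelI/modelII, got {variant}")
    return GenotypeSystem.build(variant, params)


def _allele_frequencies(state: np.ndarray, system: GenotypeSystem):
    """(mutant, wild) allele frequencies at the mutation's locus.

    Model I counts X chromosomes (two per female, one per male); Model II
    counts autosome copies (two per individual).
    """
    s = np.asarray(state, dtype=float)
    if system.variant == "modelI":
        copies_tot = np.ones(system.n_classes)
        copies_tot[system.female_idx] = 2.0
    else:
        copies_tot = np.full(system.n_classes, 2.0)
    mut = float(np.dot(system.mutant_copies, s))
    tot = float(np.dot(copies_tot, s))
    if tot <= 0.0:
        return np.nan, np.nan
    return mut / tot, 1.0 - mut / tot


def _seeded_state(params: ModelParams, system: GenotypeSystem) -> np.ndarray:
    """State with the mutant allele established (≈30% frequency) and the
    driving Y present, used to probe the system's attractor.

    The fixation and extinction thresholds are properties of the
    deterministic attractor with the mutation segregating, not of the
    transient after a release: started from the release state the total
    population dips many orders of magnitude below any numerical floor
    before a successful mutant lineage rebounds.  Starting on the mixed
    state instead converges directly to the attractor.
    """
    n0 = params.N0
    y0 = np.zeros(system.n_classes)
    if system.variant == "modelI":
        seed = {"H": 0.2, "M": 0.05, "H_R": 0.05, "M_R": 0.05,
                "F": 0.3, "F_R": 0.2, "F_RR": 0.05}
    else:
        seed = {"H": 0.2, "M": 0.05, "H_S": 0.05, "M_S": 0.05,
                "F": 0.3, "F_S": 0.2, "F_SS": 0.05}
    for label, frac in seed.items():
        y0[system.index(label)] = frac * n0
    return y0


def classify_long_run(params: ModelParams, variant: str,
                      horizon: float = LONG_RUN_HORIZON) -> dict:
    """Integrate the mutant system to its attractor and classify the outcome.

    Starts from a state with the mutant allele already established (see
    :func:`_seeded_state`) and integrates for ``horizon`` generations.
    Returns the allele fate (``fixed`` / ``intermediate`` / ``absent``),
    the eliminated flag, the final total and female population (normalized
    by N0), and the final mutant-allele frequency.  Slow exponential decay
    of either the population or an allele near a threshold is detected by
    comparing the last two half-horizon checkpoints.
    """
    system = _mutant_system(variant, params)
    y0 = _seeded_state(params, system)
    traj = simulate_trajectory(y0, params, system, horizon=horizon, n_out=201)
    final = traj.state_at(traj.t_end)
    mid = traj.state_at(0.5 * traj.t_end)
    N = float(final.sum()) / params.N0
    N_mid = float(mid.sum()) / params.N0
    eliminated = (traj.outcome == "eliminated"
                  or N < 1e-5
                  or (N < 1e-2 and N_mid > 0.0 and N / N_mid < 0.75))
    q_mut, q_wild = _allele_frequencies(final, system)
    q_mut_mid, q_wild_mid = _allele_frequencies(mid, system)

    def vanishing(q_end, q_mid):
        if not np.isfinite(q_end):
            return True
        if q_end < FIXATION_FREQ:
            return True
        return q_end < 1e-1 and np.isfinite(q_mid) and q_mid > 0.0 \
            and q_end / q_mid < 0.75

    if vanishing(q_mut, q_mut_mid):
        fate = "absent"
    elif vanishing(q_wild, q_wild_mid):
        fate = "fixed"
    else:
        fate = "intermediate"
    F = float(final[system.female_idx].sum()) / params.N0
    return {
        "fate": fate,
        "eliminated": bool(eliminated),
        "N_final": 0.0 if eliminated else N,
        "F_final": 0.0 if eliminated else F,
        "mutant_freq": q_mut,
    }


def _bisect_boundary(f_low_true, lo: float, hi: float, tol: float = 1e-4,
                     max_iter: int = 60) -> float:
    """Bisection for the boundary of a monotone boolean classifier on w.

    ``f_low_true(w)`` must hold at ``lo`` and fail at ``hi``; returns the
    midpoint of the final bracket.
    """
    if not f_low_true(lo):
        raise ValueError(f"classifier does not hold at lower bracket {lo}")
    if f_low_true(hi):
        raise ValueError(f"classifier still holds at upper bracket {hi}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if hi - lo <= tol:
            break
        if f_low_true(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fitness_thresholds(R_m: float, m: float, mutation_rate: float,
                       variant: str, tol: float = 1e-4,
                       horizon: float = LONG_RUN_HORIZON) -> dict:
    """Locate ``w1`` (fixation boundary) and ``w_ex`` (elimination boundary).

    Both are found by bisection (|Δw| ≤ ``tol``) on the long-run outcome
    of the deterministic genotype system at the given drive strength and
    mutation rate.  For Model II the fixation boundary is ``1 - v`` to
    within the mutation rate itself, so ``w1`` is returned closed-form
    there; ``w_ex`` is always numerical.
    """

    def make_params(w):
        kw = dict(R_m=R_m, m=m, w=w)
        if variant == "modelI":
            kw["u"] = mutation_rate
        else:
            kw["v"] = mutation_rate
        return ModelParams(**kw)

    def eliminated(w):
        return classify_long_run(make_params(w), variant, horizon)["eliminated"]

    w_ex = _bisect_boundary(eliminated, 1e-3, 1.0, tol=tol)

    if variant == "modelII":
        w1 = 1.0 - mutation_rate
        w1_method = "closed_form"
    else:
        def not_fixed(w):
            res = classify_long_run(make_params(w), variant, horizon)
            return res["fate"] != "fixed"

        w1 = _bisect_boundary(not_fixed, max(w_ex - 2.0 * tol, 1e-3), 1.0, tol=tol)
        w1_method = "root_finding"

    context = {"R_m": R_m, "m": m, "mutation_rate": mutation_rate,
               "variant": variant}
    return {
        "w1": ThresholdResult("w1", float(w1), context, w1_method),
        "w_ex": ThresholdResult("w_ex", float(w_ex), context, "root_finding"),
    }


def suppression_grid(w_values: Iterable[float], R_m_values: Iterable[float],
                     m: float, mutation_rate: float, variant: str,
                     horizon: float = LONG_RUN_HORIZON) -> pd.DataFrame:
    """Classify the deterministic attractor over a (w, R_m) grid.

    Each cell reports the allele fate, the female population relative to
    its cost-free value ``N0/2`` (as percentage suppression), and whether
    the population is eliminated.
    """
    rows = []
    for R_m in R_m_values:
        for w in w_values:
            kw = dict(R_m=R_m, m=m, w=w)
            if variant == "modelI":
                kw["u"] = mutation_rate
            else:
                kw["v"] = mutation_rate
            res = classify_long_run(ModelParams(**kw), variant, horizon)
            suppression = 100.0 * (1.0 - res["F_final"] / 0.5)
            rows.append({
                "w": w, "R_m": R_m, "allele_fate": res["fate"],
                "female_suppression_pct": min(100.0, suppression),
                "eliminated": res["eliminated"],
            })
    return pd.DataFrame(rows)
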