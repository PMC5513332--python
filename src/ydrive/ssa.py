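"""Exact Gillespie simulation of the full genotype systems with mutation.

Events are individual births (per mother class, at rate ``2 r f_i C_i``
with the father sampled from the fitness-weighted male pool and the child
class drawn from the variant's birth tensor, which already includes
mutation at birth) and individual deaths (rate 1 per head).  The chain is
simulated exactly: all propensities are recomputed after every event.
Seasonal forcing is handled by thinning against the upper bound
``r <= R_m`` of the recruitment rate.

A run ends in ``eliminated`` (count hit zero), ``rescued`` (the rescue
criterion fired and the female count recovered), or ``censored`` (horizon
reached, or the population exploded past ``10 N0``).  The rescue
criterion: the population has carried at least one mutant allele and
either the mutant copy number exceeds ``rescue_copies`` (default 500) or
the total count, having dropped below 45% of ``N0``, recovers above 50%
of ``N0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genotypes import GenotypeSystem
from .params import ModelParams, SeasonalForcing

__all__ = ["SSAConfig", "RunOutcome", "EnsembleSummary", "ssa_run",
           "ssa_ensemble", "suppression_duration"]

_OUTCOMES = {0: "eliminated", 1: "rescued", 2: "censored"}


@njit(cache=True)
def _ssa_kernel(seed, C0, T, female_idx, male_idx, fit_f, fit_m, copies,
                R_m, gamma0, amp, period, phase, N0, horizon,
                thr33, thr5, rescue_copies, record_times, record_out):
    # xorshift64* stream seeded through a splitmix64 scramble: fast,
    # reproducible integer arithmetic independent of any global RNG state
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    rng = z ^ (z >> np.uint64(31))
    if rng == np.uint64(0):
        rng = np.uint64(0x9E3779B97F4A7C15)
    K = C0.shape[0]
    nF = female_idx.shape[0]
    nM = male_idx.shape[0]
    C = C0.copy()

    # per-class contributions to the running census (incremental updates)
    is_female = np.zeros(K, dtype=np.float64)
    f_weight = np.zeros(K, dtype=np.float64)   # female-fitness weight
    m_weight = np.zeros(K, dtype=np.float64)   # male-fitness weight
    for i in range(nF):
        is_female[female_idx[i]] = 1.0
        f_weight[female_idx[i]] = fit_f[i]
    for i in range(nM):
        m_weight[male_idx[i]] = fit_m[i]

    N = 0
    F_cnt = 0
    F_fit = 0.0
    M_w = 0.0
    mut_cnt = 0.0
    for k in range(K):
        N += C[k]
        if is_female[k] > 0.0:
            F_cnt += C[k]
        F_fit += f_weight[k] * C[k]
        M_w += m_weight[k] * C[k]
        mut_cnt += copies[k] * C[k]

    t = 0.0
    F0 = float(F_cnt)
    f33 = thr33 * F0
    f5 = thr5 * F0
    half_N0 = 0.5 * N0
    drop_N0 = 0.45 * N0
    cap_N0 = 10.0 * N0

    mut_arisen = False
    t_first_mut = np.nan
    rescued = False
    dropped = False
    dur33 = 0.0
    dur5 = 0.0
    elim_time = np.nan
    outcome = 2  # censored unless decided
    rec_i = 0
    n_rec = record_times.shape[0]
    two_pi = 2.0 * math.pi
    seasonal = amp > 0.0

    while True:
        if N <= 0:
            outcome = 0
            elim_time = t
            break
        if mut_cnt > 0.0:
            if not mut_arisen:
                mut_arisen = True
                t_first_mut = t
            if N <= drop_N0:
                dropped = True
            if mut_cnt >= rescue_copies or (dropped and N >= half_N0):
                rescued = True
            if rescued and F_cnt >= 0.5 * F0:
                outcome = 1
                break
        elif N <= drop_N0:
            dropped = True
        if N > cap_N0:
            outcome = 2
            break

        if M_w > 0.0 and F_fit > 0.0:
            if seasonal:
                birth_prop = 2.0 * R_m * F_fit
            else:
                r = R_m - gamma0 * N
                if r < 0.0:
                    r = 0.0
                birth_prop = 2.0 * r * F_fit
        else:
            birth_prop = 0.0
        total = birth_prop + N
        rng ^= rng << np.uint64(13)
        rng ^= rng >> np.uint64(7)
        rng ^= rng << np.uint64(17)
        u = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
        dt = -math.log(1.0 - u) / total

        # time below the suppression thresholds accrues in the pre-event state
        dt_eff = dt
        if t + dt > horizon:
            dt_eff = horizon - t
        if F_cnt < f33:
            dur33 += dt_eff
            if F_cnt < f5:
                dur5 += dt_eff
        while rec_i < n_rec and record_times[rec_i] < t + dt_eff + 1e-15 \
                and record_times[rec_i] >= t:
            for k in range(K):
                record_out[rec_i, k] = C[k]
            rec_i += 1
        t += dt
        if t >= horizon:
            outcome = 1 if rescued else 2
            break

        rng ^= rng << np.uint64(13)
        rng ^= rng >> np.uint64(7)
        rng ^= rng << np.uint64(17)
        u = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
        x = u * total
        if x < birth_prop:
            if seasonal:
                g = gamma0 * (1.0 + amp * math.sin(two_pi * (t + phase) / period))
                r = R_m - g * N
                if r < 0.0:
                    r = 0.0
                rng ^= rng << np.uint64(13)
                rng ^= rng >> np.uint64(7)
                rng ^= rng << np.uint64(17)
                u = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
                if u >= r / R_m:
                    continue  # thinning rejection: no event
                rng ^= rng << np.uint64(13)
                rng ^= rng >> np.uint64(7)
                rng ^= rng << np.uint64(17)
                u = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
                x = u * F_fit
            else:
                # reuse the uniform: x/(2r) is uniform on [0, F_fit)
                x = x / (birth_prop / F_fit)
            mo = nF - 1
            acc = 0.0
            for i in range(nF):
                acc += fit_f[i] * C[female_idx[i]]
                if x < acc:
                    mo = i
                    break
            rng ^= rng << np.uint64(13)
            rng ^= rng >> np.uint64(7)
            rng ^= rng << np.uint64(17)
            u = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
            y = u * M_w
            fa = nM - 1
            acc = 0.0
            for i in range(nM):
                acc += fit_m[i] * C[male_idx[i]]
                if y < acc:
                    fa = i
                    break
            rng ^= rng << np.uint64(13)
            rng ^= rng >> np.uint64(7)
            rng ^= rng << np.uint64(17)
            zu = float((rng * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * 1.1102230246251565e-16
            z = zu
            acc = 0.0
            child = K - 1
            for k in range(K):
                acc += T[mo, fa, k]
                if z < acc:
                    child = k
                    break
            C[child] += 1
            N += 1
            if is_female[child] > 0.0:
                F_cnt += 1
            F_fit += f_weight[child]
            M_w += m_weight[child]
            mut_cnt += copies[child]
        else:
            x -= birth_prop
            acc = 0.0
            dead = K - 1
            for k in range(K):
                acc += C[k]
                if x < acc:
                    dead = k
                    break
            C[dead] -= 1
            N -= 1
            if is_female[dead] > 0.0:
                F_cnt -= 1
            F_fit -= f_weight[dead]
            M_w -= m_weight[dead]
            mut_cnt -= copies[dead]
            if F_fit < 0.0:
                F_fit = 0.0
            if M_w < 0.0:
                M_w = 0.0
            if mut_cnt < 0.5 and mut_cnt > -0.5:
                mut_cnt = 0.0

    # flush any remaining recording points at/after the final time
    while rec_i < n_rec:
        for k in range(K):
            record_out[rec_i, k] = C[k]
        rec_i += 1
    return outcome, t, elim_time, mut_arisen, t_first_mut, dur33, dur5


@dataclass(frozen=True)
class SSAConfig:
    """Configuration of a stochastic ensemble.

    ``params.N0`` is the absolute pre-release population (>= 100); the
    mutation probabilities in ``params`` are per-event probabilities, so a
    scaled-down run keeping ``uN0`` fixed should set ``u = uN0/N0``.
    """

    params: ModelParams
    variant: str = "modelI"
    n_runs: int = 100
    horizon: float = 200.0
    base_seed: int = 0
    rescue_copies: int = 500
    thresholds: tuple[float, float] = (0.33, 0.05)
    forcing: SeasonalForcing | None = None
    record_times: tuple[float, ...] = ()

    def __post_init__(self):
        if self.params.N0 < 100:
            raise ValueError("SSA requires absolute N0 >= 100")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


@dataclass(frozen=True, eq=False)
class RunOutcome:
    outcome: str                 # eliminated | rescued | censored
    t_end: float
    elimination_time: float      # NaN unless eliminated
    mutation_arisen: bool
    t_first_mutation: float
    below33: float               # generations with females < 33% of F(0)
    below5: float
    seed: int
    recorded: np.ndarray | None = None

    def __eq__(self, other):
        if not isinstance(other, RunOutcome):
            return NotImplemented

        def same(x, y):
            if isinstance(x, float) and isinstance(y, float):
                return x == y or (math.isnan(x) and math.isnan(y))
            if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
                return x is not None and y is not None and np.array_equal(x, y)
            return x == y
        return all(same(getattr(self, f), getattr(other, f))
                   for f in ("outcome", "t_end", "elimination_time",
                             "mutation_arisen", "t_first_mutation",
                             "below33", "below5", "seed", "recorded"))


def _kernel_args(config: SSAConfig):
    p = config.params
    system = GenotypeSystem.build(config.variant, p)
    C0 = np.zeros(system.n_classes, dtype=np.int64)
    half = int(round(p.N0 / 2.0))
    C0[system.index("M")] = half
    C0[system.index("F")] = half
    if "H" in system.classes:
        C0[system.index("H")] = int(round(p.h0 * p.N0))
    if config.forcing is not None and config.forcing.a > 0.0:
        f = config.forcing
        gamma0, amp, period, phase = f.gamma0_calibrated, f.a, f.T, f.phase
        F_att = f.prerelease_female(phase)
        C0[system.index("M")] = int(round(F_att))
        C0[system.index("F")] = int(round(F_att))
    else:
        gamma0, amp, period, phase = p.gamma, 0.0, 1.0, 0.0
    rec = np.asarray(config.record_times, dtype=np.float64)
    return system, C0, gamma0, amp, period, phase, rec


def ssa_run(config: SSAConfig, seed: int) -> RunOutcome:
    """One exact stochastic realization; identical (config, seed) pairs
    give identical outcomes."""
    system, C0, gamma0, amp, period, phase, rec = _kernel_args(config)
    record_out = np.zeros((rec.size, system.n_classes), dtype=np.int64)
    out = _ssa_kernel(seed, C0, system.birth_tensor,
                      system.female_idx, system.male_idx,
                      system.female_fitness, system.male_fitness,
                      system.mutant_copies,
                      config.params.R_m, gamma0, amp, period, phase,
                      float(config.params.N0), config.horizon,
                      config.thresholds[0], config.thresholds[1],
                      float(config.rescue_copies), rec, record_out)
    code, t_end, elim_time, mut_arisen, t_first, dur33, dur5 = out
    return RunOutcome(outcome=_OUTCOMES[code], t_end=t_end,
                      elimination_time=elim_time,
                      mutation_arisen=bool(mut_arisen),
                      t_first_mutation=t_first, below33=dur33, below5=dur5,
                      seed=seed, recorded=record_out if rec.size else None)


@dataclass(frozen=True)
class EnsembleSummary:
    """Outcome tallies and estimates with binomial standard errors."""

    n_runs: int
    n_eliminated: int
    n_rescued: int
    n_censored: int
    P_Mut_hat: float
    P_Mut_se: float
    P1_hat: float
    P1_se: float
    below33_mean: float
    below33_median: float
    below33_iqr: tuple[float, float]
    below5_mean: float
    below5_median: float
    below5_iqr: tuple[float, float]
    runs: tuple = field(repr=False, default=())

    @property
    def usable(self) -> bool:
        return self.n_censored < self.n_runs


def ssa_ensemble(config: SSAConfig) -> EnsembleSummary:
    """Run the ensemble with counter-based seeds ``base_seed + i``.

    Suppression-duration statistics are conditional on rescue, following
    the convention that only runs in which resistance establishes have a
    meaningful "time suppressed before recovery".
    """
    runs = []
    for i in range(config.n_runs):
        seed = (config.base_seed + i) % (2**31 - 1)
        runs.append(ssa_run(config, seed))
    n = config.n_runs
    n_elim = sum(r.outcome == "eliminated" for r in runs)
    n_resc = sum(r.outcome == "rescued" for r in runs)
    n_cens = n - n_elim - n_resc
    p_mut = sum(r.mutation_arisen for r in runs) / n
    p1 = n_resc / n

    def se(p):
        return math.sqrt(p * (1.0 - p) / n)

    d33 = np.array([r.below33 for r in runs if r.outcome == "rescued"])
    d5 = np.array([r.below5 for r in runs if r.outcome == "rescued"])

    def stats(d):
        if d.size == 0:
            return float("nan"), float("nan"), (float("nan"), float("nan"))
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        return float(d.mean()), float(med), (float(q1), float(q3))

    m33, med33, iqr33 = stats(d33)
    m5, med5, iqr5 = stats(d5)
    return EnsembleSummary(
        n_runs=n, n_eliminated=n_elim, n_rescued=n_resc, n_censored=n_cens,
        P_Mut_hat=p_mut, P_Mut_se=se(p_mut), P1_hat=p1, P1_se=se(p1),
        below33_mean=m33, below33_median=med33, below33_iqr=iqr33,
        below5_mean=m5, below5_median=med5, below5_iqr=iqr5,
        runs=tuple(runs))


def suppression_duration(times, female_counts, threshold: float,
                         reference: float) -> float:
    """Total time a recorded female series spends strictly below a threshold.

    ``threshold`` is a fraction of the pre-release female count
    ``reference``; the series is treated as piecewise constant between
    sample times (as an event record is).  A run that ends eliminated
    simply stops, so time below threshold extends to the record's end.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(female_counts, dtype=float)
    if times.shape != counts.shape or times.ndim != 1:
        raise ValueError("times and female_counts must be 1-D and equal length")
    if times.size < 2:
        return 0.0
    below = counts[:-1] < threshold * reference
    return float(np.sum(np.diff(times)[below]))
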