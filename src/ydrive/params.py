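"""Model parameters and seasonal forcing.

The population model runs in normalized units: time is measured in
generations (the death rate is 1, so ``R_m`` is the low-density number of
offspring per female per generation divided by deaths), and abundances are
normalized by the pre-release equilibrium ``N0`` unless an absolute ``N0``
is supplied (as the stochastic simulator requires).  With constant density
dependence the pre-release equilibrium satisfies ``N0 = (R_m - 1)/gamma0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = ["ModelParams", "SeasonalForcing", "calibrate_gamma0", "seasonal_gamma"]


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the driving-Y suppression model.

    Parameters
    ----------
    R_m : float
        Intrinsic growth rate (birth rate over death rate); must exceed 1
        for a viable population.
    m : float
        Proportion of a driving-Y male's progeny inheriting the driving Y,
        in [0.5, 1].  ``m = 0.5`` is a neutral (Mendelian) Y.
    u : float
        Per-daughter probability that a daughter of a driving-Y male
        carries a target-site resistant X (Model I), in [0, 1].
    v : float
        Per-individual, per-autosome probability of a trans-acting
        suppressor mutation at birth (Model II), in [0, 1].
    w : float
        Pleiotropic fitness of mutation carriers: heterozygotes ``w``,
        homozygotes and hemizygous males ``w**2``; wild types and the
        driving Y itself have fitness 1.
    h0 : float
        Release size of driving-Y males as a fraction of the pre-release
        equilibrium population ``N0``.
    N0 : float
        Pre-release equilibrium population size.  The deterministic solver
        works with ``N0 = 1`` (normalized); the stochastic simulator uses
        absolute sizes.
    gamma0 : float, optional
        Density-dependence rate constant per generation; defaults to
        ``(R_m - 1)/N0`` so that the pre-release equilibrium is ``N0``.
    """

    R_m: float = 6.0
    m: float = 0.95
    u: float = 0.0
    v: float = 0.0
    w: float = 1.0
    h0: float = 0.05
    N0: float = 1.0
    gamma0: float | None = None

    def __post_init__(self) -> None:
        if not self.R_m > 1.0:
            raise ValueError(f"R_m must exceed 1, got {self.R_m}")
        if not 0.5 <= self.m <= 1.0:
            raise ValueError(f"m must lie in [0.5, 1], got {self.m}")
        for name in ("u", "v", "w"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.h0 < 0.0:
            raise ValueError(f"h0 must be nonnegative, got {self.h0}")
        if not self.N0 > 0.0:
            raise ValueError(f"N0 must be positive, got {self.N0}")
        if self.gamma0 is not None and not self.gamma0 > 0.0:
            raise ValueError(f"gamma0 must be positive, got {self.gamma0}")

    @property
    def gamma(self) -> float:
        """Density-dependence constant; ``(R_m - 1)/N0`` unless overridden."""
        if self.gamma0 is not None:
            return self.gamma0
        return (self.R_m - 1.0) / self.N0

    @property
    def uN0(self) -> float:
        return self.u * self.N0

    @property
    def vN0(self) -> float:
        return self.v * self.N0

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def seasonal_gamma(t, gamma0: float, a: float, T: float, phase: float = 0.0):
    """Seasonally forced density-dependence γ(t) = γ0·(1 + a·sin(2π(t+phase)/T)).

    ``a`` must lie in [0, 1) so that γ stays strictly positive.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError(f"seasonal amplitude must lie in [0, 1), got {a}")
    return gamma0 * (1.0 + a * np.sin(2.0 * np.pi * (np.asarray(t) + phase) / T))


@dataclass(frozen=True)
class SeasonalForcing:
    """Calibrated sinusoidal forcing of the density-dependence constant.

    ``gamma0_calibrated`` is chosen (see :func:`calibrate_gamma0`) so that
    the time average of the pre-release limit cycle equals ``N0``; with
    ``a = 0`` it reduces to the constant ``(R_m - 1)/N0``.  ``phase`` shifts
    the seasonal clock: a release at seasonal time ``t_release`` is modelled
    by starting the post-release integration at ``t = 0`` with
    ``phase = t_release``.
    """

    a: float = 0.0
    T: float = 18.25
    gamma0_calibrated: float | None = None
    phase: float = 0.0
    # dense samples of the pre-release periodic attractor over one period
    # (filled by calibrate(); None means a == 0, where the attractor is flat)
    _cycle_t: np.ndarray | None = field(default=None, repr=False, compare=False)
    _cycle_F: np.ndarray | None = field(default=None, repr=False, compare=False)

    def gamma(self, t):
        return seasonal_gamma(t, self.gamma0_calibrated, self.a, self.T, self.phase)

    def prerelease_female(self, t) -> float:
        """Female abundance of the pre-release attractor at seasonal time ``t``."""
        if self.a == 0.0 or self._cycle_t is None:
            # constant-γ equilibrium: F = N0/2 with N0 = (R_m-1)/γ0; the
            # calibrated cycle carries N0 through _cycle_F when present
            raise ValueError("attractor samples unavailable; use calibrate()")
        tt = np.mod(t, self.T)
        return float(np.interp(tt, self._cycle_t, self._cycle_F))

    def with_phase(self, phase: float) -> "SeasonalForcing":
        return replace(self, phase=phase)


def _prerelease_cycle(gamma0: float, a: float, T: float, R_m: float,
                      n_transient: int = 30, n_samples: int = 512):
    """Integrate the pre-release female dynamics dF/dt = [R_m - 2γ(t)F]F - F
    to its periodic attractor; return one period of samples (t in [0, T])."""
    def rhs(t, y):
        g = gamma0 * (1.0 + a * math.sin(2.0 * math.pi * t / T))
        F = y[0]
        return [(R_m - 2.0 * g * F) * F - F]

    F_start = (R_m - 1.0) / (2.0 * gamma0)
    sol = solve_ivp(rhs, (0.0, n_transient * T), [F_start], rtol=1e-10,
                    atol=1e-12, dense_output=False, method="LSODA",
                    t_eval=[n_transient * T])
    t_cycle = np.linspace(0.0, T, n_samples + 1)
    sol2 = solve_ivp(rhs, (0.0, T), [sol.y[0, -1]], rtol=1e-10, atol=1e-12,
                     t_eval=t_cycle, method="LSODA")
    return t_cycle, sol2.y[0]


def calibrate_gamma0(a: float, T: float, params: ModelParams) -> SeasonalForcing:
    """Calibrate γ0[a] so the mean pre-release population over a period is N0.

    Root-finds γ0 such that the time average of ``N(t) = 2 F(t)`` on the
    pre-release limit cycle equals ``params.N0``.  For ``a = 0`` this is the
    constant-γ identity γ0 = (R_m - 1)/N0.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError(f"seasonal amplitude must lie in [0, 1), got {a}")
    g_flat = (params.R_m - 1.0) / params.N0
    if a == 0.0:
        return SeasonalForcing(a=0.0, T=T, gamma0_calibrated=g_flat)

    def mean_N_minus_N0(g0: float) -> float:
        t, F = _prerelease_cycle(g0, a, T, params.R_m)
        mean_N = 2.0 * np.trapezoid(F, t) / T
        return mean_N - params.N0

    # the cycle mean scales like 1/γ0, so a wide bracket around the flat
    # value is guaranteed to straddle the root
    lo, hi = 0.05 * g_flat, 20.0 * g_flat
    try:
        g0 = brentq(mean_N_minus_N0, lo, hi, xtol=1e-12 * g_flat, rtol=1e-12)
    except ValueError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"seasonal calibration failed to bracket for a={a}, T={T}: {exc}")
    t, F = _prerelease_cycle(g0, a, T, params.R_m, n_samples=2048)
    return SeasonalForcing(a=a, T=T, gamma0_calibrated=g0,
                           _cycle_t=t, _cycle_F=F)
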