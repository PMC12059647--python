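"""Backward-time effective-size trajectory and the coalescence size ratio.

Selection at linked sites amplifies drift cumulatively: a lineage's fitness
background persists over generations, decaying only as mutation turns the
genetic variance over.  The cumulative amplification after ``tau``
generations is

    Q_tau = sum_{x=0}^{tau} (1 - Vm/Va)^x -> Va/Vm  as tau -> infinity,

and the apparent (coalescence-rate) effective size at time ``tau`` back is

    1/Ne'(tau) = (1/N0) * exp(Va * Q_tau^2),

a monotonically decreasing function of ``tau`` whose asymptote
``N0 * exp(-Va^3/Vm^2)`` equals the fixation effective size ``B N0`` — the
fixation ratio is governed by the long-time limit, while diversity reflects
the shorter coalescent timescale.  Integrating the survival function of the
pairwise coalescence time along this trajectory yields the coalescence
effective-size ratio ``B'``, which controls neutral diversity and always
exceeds ``B`` when interference distorts allele frequencies.

For spectrum prediction the continuous trajectory is discretized into a
fixed number of equal steps of population-size decrease (default 10),
each piece held at its band's lower level with an unbounded tail at the
asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import ModelParams
from .solver import HriSolution

#: Pnc truncation threshold for the upper limit of the survival integral.
_PNC_EPS = 1e-12


def q_factor(tau, Va: float, Vm: float):
    """Cumulative selection-amplification factor ``Q_tau``.

    Closed geometric-sum form
    ``Q_tau = (Va/Vm) * [1 - (1 - Vm/Va)^(tau+1)]`` for integer generations;
    equals 1 at ``tau = 0`` and tends to ``Va/Vm`` as ``tau -> infinity``,
    monotonically non-decreasing.
    """
    if Va <= 0 or Vm <= 0:
        raise ValueError("Va and Vm must be > 0")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    r = Vm / Va
    if r >= 1.0:
        out = np.ones_like(tau)
    else:
        out = (1.0 / r) * (1.0 - (1.0 - r) ** (tau + 1.0))
    return out if out.ndim else float(out)


def ne_prime(tau, params: ModelParams, sol: HriSolution):
    """Effective size ``Ne'(tau)`` at ``tau`` generations back.

    Uses the continuous-time exponential form of ``Q_tau`` (appropriate for
    large populations), so ``Ne'(0) = N0`` and
    ``Ne'(inf) = N0 exp(-Va^3/Vm^2) = B N0`` at a converged solution.
    Returns ``N0`` identically when ``Va = 0`` (no selection, no
    distortion).
    """
    tau = np.asarray(tau, dtype=float)
    if sol.Va == 0.0:
        out = np.full_like(tau, params.N0)
        return out if out.ndim else float(out)
    tc = sol.Va / sol.Vm  # background turnover time, generations
    amp = (sol.Va**3 / sol.Vm**2) * (1.0 - np.exp(-tau / tc)) ** 2
    out = params.N0 * np.exp(-amp)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class NeTrajectory:
    """Piecewise-constant rendering of the backward-time size trajectory.

    ``pieces`` lists ``(duration_in_generations, Ne)`` from the present
    backwards; the final piece has infinite duration at ``asymptote``.
    ``continuous`` is the underlying smooth curve ``tau -> Ne'(tau)``.
    """

    continuous: Callable[[float], float]
    pieces: Tuple[Tuple[float, float], ...]
    asymptote: float
    source_solution: HriSolution

    def __post_init__(self) -> None:
        sizes = [p[1] for p in self.pieces]
        if any(n <= 0 for n in sizes):
            raise ValueError("trajectory sizes must be positive")
        if any(b > a + 1e-9 for a, b in zip(sizes, sizes[1:])):
            raise ValueError("trajectory must be non-increasing backwards in time")
        if not math.isinf(self.pieces[-1][0]):
            raise ValueError("last piece must have unbounded duration")

    @property
    def n_finite_pieces(self) -> int:
        return len(self.pieces) - 1

    def sizes(self) -> np.ndarray:
        return np.array([p[1] for p in self.pieces])

    def durations(self) -> np.ndarray:
        return np.array([p[0] for p in self.pieces])

    def mean_pairwise_coalescence_time(self) -> float:
        """Expected pairwise coalescence time (generations) on the
        piecewise-constant history."""
        surv = 1.0
        t = 0.0
        et = 0.0
        for dur, n in self.pieces:
            if math.isinf(dur):
                et += surv * (t + n)
                break
            p = math.exp(-dur / n)
            et += surv * ((t + n) - (t + dur + n) * p)
            surv *= p
            t += dur
        return et


def discretize_trajectory(
    params: ModelParams, sol: HriSolution, n_steps: int = 10
) -> NeTrajectory:
    """Discretize ``Ne'(tau)`` into equal steps of population-size decrease.

    The size range between ``Ne'(0) = N0`` and the asymptote ``B N0`` is cut
    into ``n_steps`` equal decrements.  Each piece lasts as long as the
    continuous curve spends inside its band (found by inverting the monotone
    curve) and is held at the band's lower level; the final piece holds the
    asymptote forever.  With ``Va = 0`` the result is a single unbounded
    piece at ``N0``.
    """
    N0 = params.N0
    cont = lambda tau: float(ne_prime(tau, params, sol))  # noqa: E731
    if sol.Va == 0.0 or sol.B >= 1.0 - 1e-12:
        return NeTrajectory(
            continuous=cont,
            pieces=((math.inf, N0),),
            asymptote=N0 * sol.B if sol.Va > 0 else N0,
            source_solution=sol,
        )
    asym = N0 * math.exp(-(sol.Va**3 / sol.Vm**2))
    dN = (N0 - asym) / n_steps
    levels = N0 - dN * np.arange(1, n_steps + 1)
    times: List[float] = []
    hi = sol.Va / sol.Vm  # start near the turnover timescale
    for lev in levels[:-1]:
        f = lambda t: cont(t) - lev  # noqa: E731
        while f(hi) > 0:
            hi *= 2.0
        times.append(brentq(f, 0.0, hi, xtol=1e-9 * hi))
    durs = np.diff([0.0] + times).tolist() + [math.inf]
    pieces = tuple(zip(durs, levels.tolist()))
    return NeTrajectory(
        continuous=cont, pieces=pieces, asymptote=asym, source_solution=sol
    )


def _pnc_ingredients(params: ModelParams, sol: HriSolution):
    """Scaled quantities for the no-coalescence probability.

    Time is measured in units of ``Ne = B N0`` generations.  The pairwise
    coalescence rate at scaled time ``X`` is
    ``B * exp(delta * (1 - e^(-rho X))^2)`` with ``delta = Va^3/Vm^2`` (the
    long-time amplification, equal to ``-ln B`` at a converged solution) and
    ``rho = Ne Vm / Va = gamma (1 + kappa e^-gamma) / (2 (1 - e^-gamma))``.
    """
    if sol.Va == 0.0:
        return sol.B, 0.0, 1.0
    delta = sol.Va**3 / sol.Vm**2
    rho = sol.B * params.N0 * sol.Vm / sol.Va
    return sol.B, delta, rho


def prob_no_coalescence(T, params: ModelParams, sol: HriSolution):
    """Survival function of the pairwise coalescence time at scaled time
    ``T`` (units of ``Ne = B N0`` generations).

    ``Pnc(0) = 1``; strictly decreasing to 0.  With ``Va = 0`` and ``B = 1``
    this is the constant-size pair survival ``exp(-T)``.
    """
    B, delta, rho = _pnc_ingredients(params, sol)
    T_arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(T_arr < 0):
        raise ValueError("T must be >= 0")
    out = np.empty_like(T_arr)
    for i, t in enumerate(T_arr):
        if delta == 0.0:
            out[i] = math.exp(-B * t)
            continue
        integral, _ = quad(
            lambda X: math.exp(delta * (1.0 - math.exp(-rho * X)) ** 2),
            0.0, t, limit=200,
        )
        out[i] = math.exp(-B * integral)
    return out if np.ndim(T) else float(out[0])


def coalescence_ratio(params: ModelParams, sol: HriSolution) -> Tuple[float, float]:
    """Coalescence-to-fixation size ratio ``B'/B`` and ``B'``.

    ``B'/B`` is the mean pairwise coalescence time in units of ``Ne``,
    obtained as the integral of the survival function by adaptive
    quadrature.  The integral is truncated where ``Pnc`` falls below 1e-12,
    with the analytic exponential tail (asymptotic rate
    ``B e^delta``) added.  Returns ``(B'/B, B')``.
    """
    B, delta, rho = _pnc_ingredients(params, sol)
    if delta == 0.0:
        return 1.0 / B, 1.0
    # cumulative hazard H(T) = B * int_0^T exp(delta (1-e^-rho X)^2) dX
    asym_rate = B * math.exp(delta)

    def hazard_rate(X: float) -> float:
        return B * math.exp(delta * (1.0 - math.exp(-rho * X)) ** 2)

    # find truncation point where hazard ~ -ln(_PNC_EPS)
    target = -math.log(_PNC_EPS)
    T_hi = 1.0
    H_hi, _ = quad(hazard_rate, 0.0, T_hi, limit=200)
    it = 0
    while H_hi < target and it < 60:
        T_hi *= 2.0
        H_hi, _ = quad(hazard_rate, 0.0, T_hi, limit=400)
        it += 1

    def pnc(T: float) -> float:
        H, _ = quad(hazard_rate, 0.0, T, limit=400)
        return math.exp(-H)

    val, err = quad(pnc, 0.0, T_hi, limit=400)
    if not math.isfinite(val) or err > 1e-6 * max(val, 1.0):
        raise RuntimeError(
            f"coalescence-ratio quadrature failed: value={val}, err={err}"
        )
    # analytic tail: beyond T_hi the rate is ~ asym_rate
    val += pnc(T_hi) / asym_rate
    ratio = val
    Bprime = sol.B * ratio
    return ratio, Bprime
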