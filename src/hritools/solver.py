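"""Fixation effective size under Hill-Robertson interference.

Interference among completely linked selected sites reduces the effective
population size governing fixation probabilities below the baseline ``N0``.
Writing ``B = Ne/N0``, the reduction satisfies the implicit relation

    -ln(B) = Va^3 / Vm^2
           = (U/s) * [(1 - e^-gamma) / (1 + kappa e^-gamma)]^3,

where ``gamma = B * gamma0`` is the scaled selection coefficient at the
reduced size, ``Va`` the additive fitness variance evaluated at that
``gamma`` and ``Vm = U s^2`` the mutational variance input.  The right-hand
side comes from the asymptotic (long-time) effective size of the
backward-time trajectory driven by the cumulative amplification of fitness
variance (see :mod:`hritools.trajectory`).

Two closed-form approximations are provided alongside the numerical solve:
a small-``delta`` expansion valid when ``B`` stays near 1, and the
clonal-interference formula of Good et al. (2014) appropriate for
``Ne s << 1`` with many sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .equilibrium import fitness_variances
from .params import ModelParams

#: -ln(B) validity threshold above which the small-delta expansion is flagged.
SMALL_DELTA_LIMIT = 0.2


@dataclass(frozen=True)
class HriSolution:
    """Result of a fixation effective-size computation.

    Attributes
    ----------
    B : float
        Fixation effective-size ratio ``Ne/N0`` in ``(0, 1]``.
    gamma : float
        Scaled selection coefficient at the solution, ``B * gamma0``.
    Va, Vm : float
        Additive and mutational fitness variances evaluated at ``gamma``.
    method : str
        One of ``fixed_point``, ``small_delta``, ``good_approx``,
        ``bgs_limit``.
    converged : bool
        Whether the residual criterion (or the approximation's validity
        condition) was met.
    iterations : int
        Root-refinement iterations used (0 for closed forms).
    delta : float
        ``-ln(B)``.
    X : float
        Composite parameter of the small-delta expansion (populated by
        :func:`small_delta_approx`, else ``nan``).
    Bmax : float
        Upper-limit factor of the clonal-interference approximation
        (populated by :func:`good_etal_approx`, else ``nan``).
    residual : float
        ``|ln(B) + RHS(B)|`` at the returned ``B`` (solver only).
    """

    B: float
    gamma: float
    Va: float
    Vm: float
    method: str
    converged: bool
    iterations: int = 0
    delta: float = float("nan")
    X: float = float("nan")
    Bmax: float = float("nan")
    residual: float = float("nan")


def _rhs(B: float, params: ModelParams) -> float:
    """Right-hand side -ln(B) = Va^3/Vm^2 evaluated at gamma = B*gamma0."""
    g = B * params.gamma0
    if g < 1e-12:
        frac = g / (1.0 + params.kappa)
    else:
        frac = -math.expm1(-g) / (1.0 + params.kappa * math.exp(-g))
    return params.U / params.s * frac**3


def solve_fixation_B(
    params: ModelParams, tol: float = 1e-10, max_iter: int = 200
) -> HriSolution:
    """Solve the implicit relation for the fixation effective-size ratio.

    A bracketed root of ``g(B) = ln B + RHS(B * gamma0)`` is found on
    ``(eps, 1]``; a damped fixed-point sweep from ``B = 1`` seeds the
    bracket.  If multiple roots existed, the largest in ``(0, 1]`` would be
    returned (continuity with the no-interference branch ``B -> 1`` as
    ``alpha0 -> 0``); in practice the right-hand side is increasing in ``B``
    so the root is unique.
    """
    if params.s <= 0:
        raise ValueError("solve_fixation_B requires s > 0")

    def g(B: float) -> float:
        return math.log(B) + _rhs(B, params)

    hi = 1.0 - 1e-14
    if g(hi) <= 0.0:
        # no interference strong enough to pull B below ~1
        B = 1.0
        sol_g = params.gamma0
        fv = fitness_variances(params, sol_g)
        return HriSolution(
            B=1.0, gamma=sol_g, Va=fv.Va, Vm=fv.Vm, method="fixed_point",
            converged=True, iterations=0, delta=0.0, residual=abs(g(hi)),
        )

    # damped fixed-point sweep from B=1 to find a sign change quickly
    lo = 1e-12
    B_it = 1.0
    iters = 0
    for _ in range(max_iter):
        iters += 1
        B_new = 0.5 * (B_it + math.exp(-_rhs(B_it, params)))
        B_new = min(max(B_new, lo), hi)
        if g(B_new) < 0.0:
            lo = B_new
            break
        B_it = B_new
        if abs(g(B_it)) < tol:
            break
    if g(lo) > 0.0:
        # fall back to geometric scan for the lower bracket edge
        lo = 1e-12

    try:
        B = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=max_iter)
    except Exception as exc:  # pragma: no cover - brentq is robust here
        raise RuntimeError(
            f"fixation-size solve failed: last iterate {B_it}, "
            f"residual {g(B_it)}"
        ) from exc
    resid = abs(g(B))
    if resid > tol:
        raise RuntimeError(
            f"fixation-size solve did not reach tol={tol}: B={B}, residual={resid}"
        )
    sol_g = B * params.gamma0
    fv = fitness_variances(params, sol_g)
    return HriSolution(
        B=B, gamma=sol_g, Va=fv.Va, Vm=fv.Vm, method="fixed_point",
        converged=True, iterations=iters, delta=-math.log(B), residual=resid,
    )


def small_delta_approx(params: ModelParams) -> HriSolution:
    """Closed-form expansion for weak interference (``B`` near 1).

    Expanding the implicit relation for small ``gamma`` (so both brackets
    linearize) and small ``delta = -ln B`` gives, with
    ``X = alpha0 * gamma0^2 / (1 + kappa)^3``, the closed form
    ``delta = X / (1 + 3X)`` and ``B = e^-delta``.  The result is flagged
    unconverged when ``delta`` exceeds ~0.2, where the expansion degrades;
    the call still succeeds since the approximation remains a useful guide
    outside its formal regime.
    """
    k = params.kappa
    X = params.alpha0 * params.gamma0**2 / (1.0 + k) ** 3
    delta = X / (1.0 + 3.0 * X)
    delta = max(delta, 0.0)
    B = math.exp(-delta)
    fv = fitness_variances(params, B * params.gamma0)
    return HriSolution(
        B=B, gamma=B * params.gamma0, Va=fv.Va, Vm=fv.Vm, method="small_delta",
        converged=delta <= SMALL_DELTA_LIMIT, delta=delta, X=X,
    )


def good_etal_approx(params: ModelParams) -> HriSolution:
    """Clonal-interference approximation for ``B`` (Good et al. 2014 style).

    ``B ~ [16 (1 + kappa) Bmax gamma0 / alpha0]^(1/3)`` with the notional
    mutation-selection-balance ceiling
    ``Bmax = 1 / [1 + gamma0 ln(1 + kappa s/u)]`` (clipped to 1 when the
    expression exceeds 1).  Derived for ``Ne s << 1``, large ``L`` and
    ``u/s << 1``; flagged unconverged outside that regime but always
    evaluated, and the result is clamped to ``B <= 1``.
    """
    if params.s <= 0:
        raise ValueError("good_etal_approx requires s > 0")
    Bmax = 1.0 / (1.0 + params.gamma0 * math.log1p(params.kappa * params.s / params.u))
    Bmax = min(Bmax, 1.0)
    B = (16.0 * (1.0 + params.kappa) * Bmax * params.gamma0 / params.alpha0) ** (1.0 / 3.0)
    B = min(B, 1.0)
    in_regime = (B * params.gamma0 < 1.0) and (params.u / params.s < 0.1)
    fv = fitness_variances(params, B * params.gamma0)
    return HriSolution(
        B=B, gamma=B * params.gamma0, Va=fv.Va, Vm=fv.Vm, method="good_approx",
        converged=in_regime, delta=-math.log(B) if B > 0 else float("inf"),
        Bmax=Bmax,
    )
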