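"""Closed-form single-site equilibrium quantities.

Everything here treats one diallelic site under reversible mutation
(A1 -> A2 at rate ``u``, back at ``v = u/kappa``), selection ``s`` against
A2, and drift at a scaled intensity ``gamma = 2 Ne s``.  These are the
building blocks that the interference solver composes: the Li-Bulmer
equilibrium level of adaptation, diffusion fixation-probability ratios, the
expected nucleotide diversity at a selected site, the fitness variances, the
classical background-selection limit, the two-way substitution rate, and the
partial-neutrality diversity ratio.

Removable singularities at ``gamma -> 0`` are evaluated by series expansion
below ``|gamma| < 1e-6`` rather than by raw division.
"""

from __future__ import annotations

import math

import numpy as np

from .params import FitnessVariances, ModelParams, PartialNeutralityModel

_GAMMA_SMALL = 1e-6


def li_bulmer_pbar(gamma, kappa):
    """Equilibrium mean frequency of the favored allele, ``1/(1 + kappa e^-gamma)``.

    This is the Li-Bulmer equation relating the level of adaptation (e.g.
    the frequency of preferred codons) to the scaled selection coefficient
    ``gamma = 2 Ne s`` and the mutational bias ``kappa``.  Strictly it gives
    the proportion of fixed sites fixed for the favored allele, obtained by
    equating the two opposing substitution fluxes under the diffusion
    fixation probability.

    Increasing in ``gamma``, decreasing in ``kappa``, and equal to 1/2 when
    ``gamma = ln(kappa)``.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be > 0")
    out = 1.0 / (1.0 + kappa * np.exp(-gamma))
    return out if out.ndim else float(out)


def gamma_hat(pbar, kappa):
    """Invert the Li-Bulmer equation: ``ln(kappa * pbar / (1 - pbar))``.

    The estimate is undefined at ``pbar`` of exactly 0 or 1 (it diverges as
    the level of adaptation approaches complete fixation, where drift no
    longer leaves a signal).
    """
    pbar = np.asarray(pbar, dtype=float)
    if np.any(pbar <= 0.0) or np.any(pbar >= 1.0):
        raise ValueError("gamma estimate undefined: pbar must lie strictly in (0, 1)")
    out = np.log(kappa * pbar / (1.0 - pbar))
    return out if out.ndim else float(out)


def relative_fixation_prob(gamma, deleterious=True):
    """Fixation probability of a mutation relative to a neutral one.

    ``gamma / (e^gamma - 1)`` for a deleterious mutation (scaled coefficient
    ``gamma`` against it) and ``gamma / (1 - e^-gamma)`` for the favorable
    back mutation.  Both tend to 1 as ``gamma -> 0`` and satisfy
    ``P_del * e^gamma = P_fav`` identically.
    """
    g = np.asarray(gamma, dtype=float)
    small = np.abs(g) < _GAMMA_SMALL
    gs = np.where(small, 1.0, g)
    if deleterious:
        out = np.where(small, 1.0 - g / 2.0, gs / np.expm1(gs))
    else:
        out = np.where(small, 1.0 + g / 2.0, gs / -np.expm1(-gs))
    return out if out.ndim else float(out)


def expected_site_diversity(u, s, gamma, kappa):
    """Expected nucleotide diversity at a selected site.

    ``(2u/s) * (1 - e^-gamma) / (1 + kappa e^-gamma)`` under the
    infinite-sites accounting of mutations in transit to fixation or loss.
    As ``gamma -> 0`` (with ``gamma = 2 Ne s``) this tends to the neutral
    reversible-site diversity ``4 Ne u / (1 + kappa)``, which is evaluated
    via the series limit ``(2u/s)*gamma/(1+kappa)`` so ``s`` may be small.
    """
    g = np.asarray(gamma, dtype=float)
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be > 0")
    s_arr = np.asarray(s, dtype=float)
    if np.any((s_arr == 0) & (g != 0)):
        raise ValueError("s = 0 requires gamma = 0 (neutral limit)")
    small = np.abs(g) < _GAMMA_SMALL
    gs = np.where(small, 1.0, g)
    frac = np.where(
        small,
        g / (1.0 + kappa),
        -np.expm1(-gs) / (1.0 + kappa * np.exp(-gs)),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * u / s_arr * frac
    # s == 0 and gamma == 0: 4 Ne u/(1+kappa), but Ne is not recoverable
    # from (s, gamma) alone; use neutral_diversity() for that limit.
    out = np.where((s_arr == 0) & (g == 0), np.nan, out)
    return out if out.ndim else float(out)


def neutral_diversity(N0, u, kappa):
    """Neutral reversible-site diversity in the absence of interference,
    ``4 N0 u / (1 + kappa)`` (assumes ``4 N0 u << 1``)."""
    return 4.0 * N0 * u / (1.0 + kappa)


def fitness_variances(params: ModelParams, gamma: float) -> FitnessVariances:
    """Genic/additive variance in fitness and the mutational variance input.

    A single segregating site contributes ``(s^2/2) * pi_sel`` to the genic
    variance; summing over ``L`` sites gives
    ``Vg = U s (1 - e^-gamma)/(1 + kappa e^-gamma)``, and ``Va = Vg`` under
    the no-LD assumption.  New mutations inject variance ``Vm = U s^2`` per
    genome per generation.
    """
    g = float(gamma)
    if abs(g) < _GAMMA_SMALL:
        frac = g / (1.0 + params.kappa)
    else:
        frac = -math.expm1(-g) / (1.0 + params.kappa * math.exp(-g))
    Vg = params.U * params.s * frac
    Vm = params.U * params.s**2
    return FitnessVariances(Va=Vg, Vg=Vg, Vm=Vm)


def bgs_limit_B(U, s):
    """Classical background-selection reduction ``exp(-U/s)`` for a
    nonrecombining region with all sites at deterministic mutation-selection
    balance.  Valid for ``gamma >> 1`` and ``U/s`` not too large."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("s must be > 0")
    out = np.exp(-np.asarray(U, dtype=float) / s)
    return out if out.ndim else float(out)


def substitution_rate(L, u, gamma, kappa):
    """Expected fixations per generation across the region (both directions).

    The flux of A2 substitutions from sites fixed for A1 (a fraction
    ``pbar``) plus the flux of A1 substitutions from sites fixed for A2.
    Both fluxes are equal at equilibrium and sum to

        ``lambda = 2 L u gamma / [(1 + kappa e^-gamma)(e^gamma - 1)]``

    with the neutral two-way limit ``2 L u / (1 + kappa)`` as
    ``gamma -> 0``.
    """
    g = np.asarray(gamma, dtype=float)
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be > 0")
    small = np.abs(g) < _GAMMA_SMALL
    gs = np.where(small, 1.0, g)
    out = np.where(
        small,
        2.0 * L * u / (1.0 + kappa) * (1.0 - g / 2.0 + g / (1.0 + kappa) * kappa),
        2.0 * L * u * gs / ((1.0 + kappa * np.exp(-gs)) * np.expm1(gs)),
    )
    return out if out.ndim else float(out)


def partial_neutrality_ratio(model: PartialNeutralityModel) -> float:
    """Ratio of selected-site diversity to its value at ``Bprime = 1`` under
    the strong-plus-neutral mixture model.

    ``R = 1 - (1 - Ps)(1 - B') pi_neut0 / [Ps pi_strong + (1 - Ps) pi_neut0]``.
    Increasing in ``B'``; equals 1 at ``B' = 1`` and ``B'`` itself at
    ``Ps = 0``.
    """
    denom = model.Ps * model.pi_strong + (1.0 - model.Ps) * model.pi_neut0
    if denom == 0.0:
        raise ValueError("degenerate model: zero diversity in both classes")
    return 1.0 - (1.0 - model.Ps) * (1.0 - model.Bprime) * model.pi_neut0 / denom
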