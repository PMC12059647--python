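"""Expected neutral site frequency spectra and distortion statistics.

Under a time-varying effective size the genealogy of a sample is a pure
death process on the number of ancestral lineages, run on the
coalescent-rescaled clock ``Lambda(t) = int_0^t dt'/Ne(t')``.  For a
piecewise-constant ``Ne`` history the occupancy probabilities of the
lineage-count process (Tavare's exponential mixture) integrate in closed
form piece by piece, giving exact expected interval lengths ``E[T_j]``
(time while ``j`` lineages survive).  The expected spectrum follows by the
standard branch-size argument: a branch present while ``j`` lineages exist
subtends ``i`` of ``k`` sampled leaves with probability
``C(k-i-1, j-2)/C(k-1, j-1)``.  This is the stable equivalent of the
classical expected-spectrum formulas of Polanski & Kimmel for arbitrary
size histories.

Distortion is summarized by ``delta_theta_w = 1 - pi/theta_w`` and its
normalization by the all-singleton maximum ``1 - 2 a_k / k``, computable
from the spectrum shape alone without the number of segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trajectory import NeTrajectory

#: default guard: double precision is ample below this sample size
MAX_SAMPLE_SIZE = 50


def watterson_a(k: int) -> float:
    """Harmonic sum ``a_k = sum_{i=1}^{k-1} 1/i`` of Watterson's estimator."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return math.fsum(1.0 / i for i in range(1, k))


@dataclass(frozen=True)
class ExpectedSFS:
    """Expected relative spectrum: ``probs[i-1]`` is the probability that a
    segregating neutral site shows ``i`` derived copies in a sample of
    ``k``."""

    k: int
    probs: np.ndarray
    a_k: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(p) != self.k - 1:
            raise ValueError("probs must have length k-1")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p <= 0):
            raise ValueError("probs must be positive and sum to 1")


@dataclass(frozen=True)
class SampleSFS:
    """Observed spectrum: ``counts[i-1]`` segregating sites with ``i``
    derived copies among ``k`` sampled genomes; sites fixed within the
    sample are tallied separately."""

    k: int
    counts: np.ndarray
    n_fixed_in_sample: int = 0

    @property
    def S(self) -> float:
        return float(np.sum(self.counts))


@dataclass(frozen=True)
class DistortionStats:
    """Skew of a spectrum toward rare variants relative to the constant-size
    neutral expectation (``pi/theta_w = 1``, all deltas 0)."""

    pi_over_thetaw: float
    delta_thetaw: float
    delta_thetaw_max: float
    delta_thetaw_prime: float
    S_k: float


def _lineage_mixture_coeffs(k: int, j: int) -> np.ndarray:
    """Coefficients c_m with P(n(lambda) = j | n(0) = k) =
    sum_{m=j}^{k} c_m * exp(-m(m-1)/2 * lambda)  (Tavare 1984)."""
    coeffs = np.zeros(k + 1)
    for m in range(j, k + 1):
        num = (2 * m - 1) * (-1) ** (m - j)
        rising_j = 1.0
        for i in range(m - 1):
            rising_j *= j + i
        falling_k = 1.0
        rising_k = 1.0
        for i in range(m):
            falling_k *= k - i
            rising_k *= k + i
        coeffs[m] = (
            num * rising_j * falling_k
            / (math.factorial(j) * math.factorial(m - j) * rising_k)
        )
    return coeffs


def expected_interval_lengths(trajectory: NeTrajectory, k: int) -> np.ndarray:
    """Exact ``E[T_j]`` (generations while ``j`` lineages remain, j=2..k)
    for a sample of ``k`` on a piecewise-constant size history.

    Integrates each exponential term of the lineage-count mixture in closed
    form over every piece, including the unbounded tail.
    """
    rates = np.array([m * (m - 1) / 2.0 for m in range(k + 1)])
    ET = np.zeros(k + 1)
    for j in range(2, k + 1):
        c = _lineage_mixture_coeffs(k, j)
        lam0 = 0.0
        acc = []
        for dur, n in trajectory.pieces:
            if math.isinf(dur):
                for m in range(j, k + 1):
                    acc.append(c[m] * math.exp(-rates[m] * lam0) / rates[m] * n)
                break
            dlam = dur / n
            for m in range(j, k + 1):
                acc.append(
                    c[m] * math.exp(-rates[m] * lam0)
                    * -math.expm1(-rates[m] * dlam) / rates[m] * n
                )
            lam0 += dlam
        ET[j] = math.fsum(acc)
    return ET


def expected_sfs_varne(trajectory: NeTrajectory, k: int) -> ExpectedSFS:
    """Expected relative neutral spectrum under a piecewise-constant history.

    For a constant history this reduces to ``p_i`` proportional to ``1/i``
    exactly.  Skewed (backward-decreasing) histories shift weight toward
    singletons.  ``k`` is capped at ``MAX_SAMPLE_SIZE`` where the
    alternating lineage-count mixtures stay well conditioned in double
    precision; larger samples would need a high-precision mode.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > MAX_SAMPLE_SIZE:
        raise ValueError(
            f"k={k} exceeds the numerical-stability guard ({MAX_SAMPLE_SIZE}); "
            "use a high-precision implementation for larger samples"
        )
    ET = expected_interval_lengths(trajectory, k)
    xi = np.zeros(k - 1)
    for i in range(1, k):
        tot = 0.0
        for j in range(2, k + 1):
            # P(branch while j lineages subtends i of k leaves)
            p = math.comb(k - i - 1, j - 2) / math.comb(k - 1, j - 1)
            if p:
                tot += j * ET[j] * p
        xi[i - 1] = tot
    return ExpectedSFS(k=k, probs=xi / xi.sum(), a_k=watterson_a(k))


def delta_theta_stats(sfs, k: int | None = None) -> DistortionStats:
    """Distortion statistics from a spectrum alone.

    ``pi/theta_w`` is computed without reference to the number of
    segregating sites as ``[sum_i i(k-i) x_i / C(k,2)] * [a_k / sum_i x_i]``;
    then ``delta_theta_w = 1 - pi/theta_w``, its all-singleton maximum is
    ``1 - 2 a_k / k``, and the normalized statistic is their ratio (equal to
    minus the normalized Tajima's D of Schaeffer's D_min construction).
    Requires ``k >= 3`` for a nonzero maximum.
    """
    if isinstance(sfs, ExpectedSFS):
        x = np.asarray(sfs.probs, dtype=float)
        kk = sfs.k
        S = float("nan")
    elif isinstance(sfs, SampleSFS):
        x = np.asarray(sfs.counts, dtype=float)
        kk = sfs.k
        S = float(x.sum())
    else:
        x = np.asarray(sfs, dtype=float)
        if k is None:
            raise ValueError("k required when passing a bare vector")
        kk = k
        S = float(x.sum())
    if kk < 3:
        raise ValueError("k must be >= 3 for a meaningful maximum distortion")
    if len(x) != kk - 1:
        raise ValueError("spectrum must have length k-1")
    tot = x.sum()
    if tot <= 0:
        raise ValueError("degenerate spectrum: no segregating sites")
    ak = watterson_a(kk)
    i = np.arange(1, kk)
    pi_over_thetaw = float((i * (kk - i) * x).sum() / math.comb(kk, 2) * ak / tot)
    d = 1.0 - pi_over_thetaw
    dmax = 1.0 - 2.0 * ak / kk
    return DistortionStats(
        pi_over_thetaw=pi_over_thetaw,
        delta_thetaw=d,
        delta_thetaw_max=dmax,
        delta_thetaw_prime=d / dmax,
        S_k=S,
    )
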