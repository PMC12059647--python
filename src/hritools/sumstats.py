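"""Summary statistics from simulated populations and samples.

Provides the empirical counterparts of the analytical predictions: the level
of adaptation ``pbar`` and the implied fixation-size ratio ``B_hat``
(via the inverted Li-Bulmer relation), per-site pairwise diversities with
unbiased sample corrections, the whole-population linkage-disequilibrium sum
over all pairs of selected sites (via an O(N L) variance identity) together
with its diversity correction, observed sample spectra, and replicate-level
summaries with normal-approximation confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .equilibrium import expected_site_diversity, gamma_hat
from .params import ModelParams
from .sfs import SampleSFS, delta_theta_stats
from .simulate import GenotypeMatrix, PopulationState, sample_genomes


@dataclass(frozen=True)
class LdSummary:
    """Pairwise linkage disequilibrium over selected sites.

    ``sum_D`` is the sum of ``D_ij = p_AB - p_A p_B`` (deleterious-allele
    coupling orientation) over all ``L(L-1)/2`` ordered pairs; pairs with a
    monomorphic member contribute exactly 0.  ``C = -4 sum_D / L``
    (equivalently ``-2 (L-1) mean_D``) is the correction added to the
    predicted selected-site diversity: negative mean LD (repulsion) implies
    a positive correction.
    """

    sum_D: float
    mean_D: float
    C: float
    n_segregating_pairs: int


@dataclass
class SummaryStats:
    pbar: float
    gamma_hat: Optional[float]
    B_hat: Optional[float]
    pi_sel: float
    pi_neut: float
    Bprime_hat: float
    S_k: float
    theta_w: float
    delta_thetaw: float
    delta_thetaw_prime: float
    sum_D: float
    C: float
    lambda_neutral_hat: float
    lambda_selected_hat: float


def pbar_and_B(state_or_pbar, params: ModelParams):
    """Level of adaptation and the implied fixation-size ratio.

    ``pbar`` is 1 minus the mean deleterious-allele frequency over all ``L``
    sites of the whole population; ``gamma_hat = ln(kappa pbar/(1-pbar))``
    and ``B_hat = gamma_hat / gamma0``.  At ``pbar`` of exactly 0 or 1 the
    estimate is undefined and ``(pbar, None, None)`` is returned.
    """
    if isinstance(state_or_pbar, PopulationState):
        pb = state_or_pbar.pbar()
    else:
        pb = float(state_or_pbar)
    if pb <= 0.0 or pb >= 1.0:
        return pb, None, None
    gh = gamma_hat(pb, params.kappa)
    return pb, gh, gh / params.gamma0 if params.gamma0 > 0 else None


def pairwise_pi(matrix: np.ndarray | GenotypeMatrix, L_norm: float) -> float:
    """Mean pairwise diversity per site from a 0/1 sample matrix.

    ``pi = (1/L_norm) sum_sites [k/(k-1)] 2 p (1-p)`` with ``p`` the sample
    derived-allele frequency — identical to the average Hamming distance
    between sampled genome pairs divided by ``L_norm``.
    """
    if L_norm <= 0:
        raise ValueError("L_norm must be > 0")
    if isinstance(matrix, GenotypeMatrix):
        geno = matrix.genotypes
        k = matrix.k
    else:
        geno = np.asarray(matrix)
        k = geno.shape[1]
    if k < 2:
        raise ValueError("need k >= 2")
    if geno.shape[0] == 0:
        return 0.0
    p = geno.mean(axis=1)
    return float(np.sum(2.0 * p * (1.0 - p)) * k / (k - 1) / L_norm)


def ld_sum_and_correction(state: PopulationState, params: ModelParams) -> LdSummary:
    """LD sum over all pairs of selected sites via the variance identity.

    With ``K_j`` the deleterious-allele count of genome ``j`` and ``p_i``
    the per-site deleterious frequencies,
    ``sum_{i<j} D_ij = [Var(K) - sum_i p_i (1 - p_i)] / 2`` where ``Var`` is
    the population (not sample) variance — an O(N L) computation replacing
    the O(N L^2) pair sum.
    """
    N = state.N
    counts = state.deleterious_counts_per_site()
    p = counts / N
    var_k = float(np.var(state.K))  # population variance
    sum_pq = float(np.sum(p * (1.0 - p)))
    sum_D = 0.5 * (var_k - sum_pq)
    L = params.L
    npairs = L * (L - 1) // 2
    seg = int(np.sum((counts > 0) & (counts < N)))
    return LdSummary(
        sum_D=sum_D,
        mean_D=sum_D / npairs,
        C=-4.0 * sum_D / L,
        n_segregating_pairs=seg * (seg - 1) // 2,
    )


def observed_sfs(matrix: GenotypeMatrix, class_filter: int = 1) -> SampleSFS:
    """Unfolded spectrum of derived-allele counts for one site class
    (neutral by default).  In-sample-fixed sites are excluded from the
    spectrum and reported separately."""
    sub = matrix.by_class(class_filter)
    k = matrix.k
    counts = np.zeros(k - 1, dtype=np.int64)
    n_fixed = 0
    if sub.n_sites:
        dac = sub.genotypes.sum(axis=1)
        n_fixed = int(np.sum(dac == k))
        seg = dac[(dac > 0) & (dac < k)]
        for d in seg:
            counts[d - 1] += 1
    return SampleSFS(k=k, counts=counts, n_fixed_in_sample=n_fixed)


def replicate_stats(
    state: PopulationState,
    params: ModelParams,
    k: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> SummaryStats:
    """All summary statistics for one finished replicate."""
    rng = rng or np.random.default_rng(state.seed + 0x9E3779B1)
    pb, gh, bh = pbar_and_B(state, params)
    matrix = sample_genomes(state, k, rng)
    pi_sel = pairwise_pi(matrix.by_class(0), params.L)
    pi_neut = pairwise_pi(matrix.by_class(1), params.L)
    sfs = observed_sfs(matrix, class_filter=1)
    ak = math.fsum(1.0 / i for i in range(1, k))
    theta_w = sfs.S / ak / params.L
    if sfs.S > 0:
        ds = delta_theta_stats(sfs)
        dtw, dtwp = ds.delta_thetaw, ds.delta_thetaw_prime
    else:
        dtw = dtwp = float("nan")
    ld = ld_sum_and_correction(state, params)
    gens = max(state.generation, 1)
    return SummaryStats(
        pbar=pb,
        gamma_hat=gh,
        B_hat=bh,
        pi_sel=pi_sel,
        pi_neut=pi_neut,
        Bprime_hat=pi_neut / (2.0 * params.N0 * params.u),
        S_k=sfs.S,
        theta_w=theta_w,
        delta_thetaw=dtw,
        delta_thetaw_prime=dtwp,
        sum_D=ld.sum_D,
        C=ld.C,
        lambda_neutral_hat=state.fixed_neutral / gens,
        lambda_selected_hat=state.fixed_selected / gens,
    )


def summarize_replicates(
    stats: Iterable[SummaryStats], params: ModelParams
) -> pd.DataFrame:
    """Per-replicate table plus mean and normal-approximation 95% CI rows.

    ``Bprime_hat`` is normalized by ``2 N0 u`` (the no-interference neutral
    diversity on the haploid scale; identical to ``4 N0 u/(1+kappa)`` at
    ``kappa = 1``) — the convention is recorded in the table attributes.
    """
    rows: List[dict] = [vars(s).copy() for s in stats]
    if not rows:
        raise ValueError("no replicates to summarize")
    df = pd.DataFrame(rows)
    num = df.select_dtypes(include=[float, int])
    mean = num.mean()
    n = len(df)
    se = num.std(ddof=1) / math.sqrt(n) if n > 1 else num.std(ddof=0) * float("nan")
    lo = mean - 1.96 * se
    hi = mean + 1.96 * se
    summary = pd.DataFrame(
        {"mean": mean, "ci95_lo": lo, "ci95_hi": hi, "n": n}
    )
    df.attrs["summary"] = summary
    df.attrs["bprime_normalization"] = "2*N0*u"
    df.attrs["params"] = params.asdict()
    return df


def corrected_pi_sel(params: ModelParams, gamma: float, C: float) -> float:
    """Predicted selected-site diversity at scaled coefficient ``gamma``
    plus the LD correction ``C`` estimated from simulation."""
    return expected_site_diversity(params.u, params.s, gamma, params.kappa) + C
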