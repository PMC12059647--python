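"""Forward Wright-Fisher simulator for a nonrecombining haploid block.

The simulated genome carries ``L`` selected sites with reversible (toggle)
mutation and an interspersed stream of infinite-sites neutral variants that
may stack onto selected positions.  Each generation: multiplicative fitness
``(1-s)^(deleterious count)``, Wright-Fisher resampling of ``N`` offspring
with probability proportional to fitness, Poisson numbers of selected-site
mutation events (a toggle flips the allele, which implements reversibility
with ``kappa = 1``; asymmetric per-site rates handle ``kappa != 1`` as a
documented generalization), and Poisson numbers of new neutral variants,
each with a unique origin id.  Neutral variants fixed in the whole
population are purged and tallied, giving an empirical neutral substitution
count; selected-site substitutions are tallied from periodic monomorphism
scans.

Selected states and neutral-variant membership are bit-packed into uint64
words; the per-generation cost is O(N (L + V)/64 + events), which keeps
multi-10^4-generation replicates at ``N = 1000`` in the seconds range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .params import ModelParams

_SCAN_INTERVAL = 200  # generations between monomorphism scans / compactions


@dataclass
class GenotypeMatrix:
    """Sample of ``k`` genomes: one row per retained site.

    ``classes`` is 0 for selected sites (derived = deleterious allele) and
    1 for neutral variants (derived = mutant).  Sites monomorphic-derived
    within the sample are retained and flagged in ``fixed_in_sample``.
    """

    k: int
    positions: np.ndarray
    classes: np.ndarray
    genotypes: np.ndarray  # (n_sites, k) uint8
    fixed_in_sample: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def by_class(self, cls: int) -> "GenotypeMatrix":
        m = self.classes == cls
        return GenotypeMatrix(
            k=self.k,
            positions=self.positions[m],
            classes=self.classes[m],
            genotypes=self.genotypes[m],
            fixed_in_sample=self.fixed_in_sample[m],
        )


@dataclass
class PopulationState:
    """Full simulated population (bit-packed) plus bookkeeping tallies."""

    N: int
    L: int
    sel: np.ndarray          # (N, Ws) uint64, 1 = deleterious
    K: np.ndarray            # (N,) int64 deleterious counts
    neu: np.ndarray          # (N, Wn) uint64 membership over variant columns
    neu_pos: np.ndarray      # (cap,) int64 positions of active variants
    neu_origin: np.ndarray   # (cap,) int64 unique origin ids
    n_variants: int
    next_origin: int
    generation: int
    seed: int
    fixed_neutral: int = 0
    fixed_selected: int = 0
    fixed_state: Optional[np.ndarray] = None  # per-site 0/1/2(seg) at last scan
    pbar_log: list = field(default_factory=list)

    @property
    def words_selected(self) -> int:
        return self.sel.shape[1]

    def deleterious_counts_per_site(self) -> np.ndarray:
        """Allele count of the deleterious allele at each of the L sites."""
        bits = np.unpackbits(
            self.sel.view(np.uint8), axis=1, bitorder="little"
        )[:, : self.L]
        return bits.sum(axis=0).astype(np.int64)

    def neutral_counts(self) -> np.ndarray:
        bits = np.unpackbits(
            self.neu.view(np.uint8), axis=1, bitorder="little"
        )[:, : self.n_variants]
        return bits.sum(axis=0).astype(np.int64)

    def pbar(self) -> float:
        """Mean frequency of the favored allele across all L sites."""
        return 1.0 - float(self.K.mean()) / self.L


@njit(cache=True)
def _wf_kernel(sel, K, neu, neu_pos, neu_origin, n_variants, next_origin,
               N, L, u, v, s, kappa_is_one, ngen, seed, scan_interval,
               fixed_state, pbar_log, log_interval, tallies):
    """Advance the population ``ngen`` generations in place.

    tallies: int64[2] = (fixed_neutral, fixed_selected), updated in place.
    Returns (n_variants, next_origin).
    """
    np.random.seed(seed)
    Ws = sel.shape[1]
    Wn = neu.shape[1]
    cap = Wn * 64
    logw = math.log(1.0 - s) if s > 0.0 else 0.0
    w = np.empty(N)
    cumw = np.empty(N)
    sel_new = np.empty_like(sel)
    K_new = np.empty_like(K)
    neu_new = np.empty_like(neu)
    parents = np.empty(N, dtype=np.int64)

    for gen in range(ngen):
        # --- selection + reproduction ---
        if s > 0.0:
            tot = 0.0
            for j in range(N):
                w[j] = math.exp(K[j] * logw)
                tot += w[j]
                cumw[j] = tot
            if tot <= 0.0:
                raise RuntimeError("all genomes have zero fitness")
            for j in range(N):
                r = np.random.random() * tot
                lo, hi = 0, N - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cumw[mid] < r:
                        lo = mid + 1
                    else:
                        hi = mid
                parents[j] = lo
        else:
            for j in range(N):
                parents[j] = np.random.randint(0, N)
        wa = (n_variants + 63) // 64  # active neutral words only
        for j in range(N):
            p = parents[j]
            for wd in range(Ws):
                sel_new[j, wd] = sel[p, wd]
            for wd in range(wa):
                neu_new[j, wd] = neu[p, wd]
            K_new[j] = K[p]
        for j in range(N):
            for wd in range(Ws):
                sel[j, wd] = sel_new[j, wd]
            for wd in range(wa):
                neu[j, wd] = neu_new[j, wd]
            K[j] = K_new[j]

        # --- selected-site mutation ---
        if kappa_is_one:
            nmut = np.random.poisson(N * u * L)
            for _ in range(nmut):
                j = np.random.randint(0, N)
                site = np.random.randint(0, L)
                wd = site // 64
                mask = np.uint64(1) << np.uint64(site % 64)
                sel[j, wd] ^= mask  # toggle: reversible mutation
                if sel[j, wd] & mask:
                    K[j] += 1
                else:
                    K[j] -= 1
        else:
            # asymmetric rates: forward u at favored sites, back v at
            # deleterious sites.  Thinned Poisson process at the maximum
            # per-site rate: candidate events at rate max(u, v) per site,
            # each accepted with (state rate)/max -- exact in distribution.
            umax = max(u, v)
            nmut = np.random.poisson(N * umax * L)
            for _ in range(nmut):
                j = np.random.randint(0, N)
                site = np.random.randint(0, L)
                wd = site // 64
                mask = np.uint64(1) << np.uint64(site % 64)
                isdel = (sel[j, wd] & mask) != np.uint64(0)
                pacc = (v if isdel else u) / umax
                if np.random.random() < pacc:
                    sel[j, wd] ^= mask
                    if isdel:
                        K[j] -= 1
                    else:
                        K[j] += 1

        # --- neutral mutation (infinite sites, stacking allowed) ---
        nneu = np.random.poisson(N * u * L)
        for _ in range(nneu):
            if n_variants >= cap:
                break  # compaction below frees space next scan
            j = np.random.randint(0, N)
            site = np.random.randint(0, L)
            col = n_variants
            neu[j, col // 64] |= np.uint64(1) << np.uint64(col % 64)
            neu_pos[col] = site
            neu_origin[col] = next_origin
            next_origin += 1
            n_variants += 1

        # --- periodic compaction + monomorphism scan ---
        if (gen + 1) % scan_interval == 0 or n_variants >= cap - 64:
            # neutral: drop lost, purge + count fixed
            keep = 0
            for c in range(n_variants):
                wd = c // 64
                mask = np.uint64(1) << np.uint64(c % 64)
                cnt = 0
                for j in range(N):
                    if neu[j, wd] & mask:
                        cnt += 1
                if cnt == 0:
                    continue
                if cnt == N:
                    tallies[0] += 1
                    continue
                if keep != c:
                    kwd = keep // 64
                    kmask = np.uint64(1) << np.uint64(keep % 64)
                    for j in range(N):
                        carrier = (neu[j, wd] & mask) != np.uint64(0)
                        has = (neu[j, kwd] & kmask) != np.uint64(0)
                        if carrier != has:
                            neu[j, kwd] ^= kmask
                    neu_pos[keep] = neu_pos[c]
                    neu_origin[keep] = neu_origin[c]
                keep += 1
            # clear stale bits in columns beyond keep
            for c in range(keep, n_variants):
                wd = c // 64
                mask = np.uint64(1) << np.uint64(c % 64)
                for j in range(N):
                    if neu[j, wd] & mask:
                        neu[j, wd] ^= mask
            n_variants = keep

            # selected: monomorphism via AND/OR over genomes
            for wd in range(Ws):
                orw = np.uint64(0)
                andw = np.uint64(0xFFFFFFFFFFFFFFFF)
                for j in range(N):
                    orw |= sel[j, wd]
                    andw &= sel[j, wd]
                for b in range(64):
                    site = wd * 64 + b
                    if site >= L:
                        break
                    mask = np.uint64(1) << np.uint64(b)
                    if andw & mask:
                        st = 1
                    elif orw & mask:
                        st = 2
                    else:
                        st = 0
                    prev = fixed_state[site]
                    if prev != 2 and st != 2 and prev != st:
                        tallies[1] += 1
                    if st != 2:
                        fixed_state[site] = st

        if log_interval > 0 and (gen + 1) % log_interval == 0:
            ksum = 0
            for j in range(N):
                ksum += K[j]
            pbar_log[(gen + 1) // log_interval - 1] = 1.0 - ksum / (N * L)

    return n_variants, next_origin


def initialize_population(
    params: ModelParams, N: int, seed: int, variant_capacity: int = 8192
) -> PopulationState:
    """All-favorable starting state: no deleterious alleles, no neutral
    variants, generation 0, a seeded per-replicate stream."""
    if N < 2:
        raise ValueError("N must be >= 2")
    Ws = (params.L + 63) // 64
    Wn = (variant_capacity + 63) // 64
    return PopulationState(
        N=N,
        L=params.L,
        sel=np.zeros((N, Ws), dtype=np.uint64),
        K=np.zeros(N, dtype=np.int64),
        neu=np.zeros((N, Wn), dtype=np.uint64),
        neu_pos=np.zeros(Wn * 64, dtype=np.int64),
        neu_origin=np.zeros(Wn * 64, dtype=np.int64),
        n_variants=0,
        next_origin=0,
        generation=0,
        seed=int(seed) % 2**31,
        fixed_state=np.zeros(params.L, dtype=np.int64),
    )


def seed_equilibrium_frequencies(
    state: PopulationState, params: ModelParams, pbar: float, rng: np.random.Generator
) -> None:
    """Optionally start selected sites near equilibrium: each site fixed for
    the deleterious allele with probability ``1 - pbar`` (sites i.i.d.).

    Shortens burn-in for statistics that equilibrate on the slow
    substitution timescale; the subsequent run should still be checked for a
    plateau in the ``pbar`` trajectory log.
    """
    del_sites = np.nonzero(rng.random(state.L) > pbar)[0]
    for site in del_sites:
        state.sel[:, site // 64] |= np.uint64(1) << np.uint64(site % 64)
        state.fixed_state[site] = 1
    state.K[:] = len(del_sites)


def step_generation(state: PopulationState, params: ModelParams, n: int = 1) -> PopulationState:
    """Advance ``n`` generations in place (reseeded continuation of the
    state's stream; a single uninterrupted run is bit-reproducible)."""
    tallies = np.array([state.fixed_neutral, state.fixed_selected], dtype=np.int64)
    dummy_log = np.empty(0, dtype=np.float64)
    nv, no = _wf_kernel(
        state.sel, state.K, state.neu, state.neu_pos, state.neu_origin,
        state.n_variants, state.next_origin, state.N, state.L,
        params.u, params.v, params.s, params.kappa == 1.0, n,
        (state.seed + state.generation * 7919) % 2**31,
        _SCAN_INTERVAL, state.fixed_state, dummy_log, 0, tallies,
    )
    state.n_variants = nv
    state.next_origin = no
    state.generation += n
    state.fixed_neutral = int(tallies[0])
    state.fixed_selected = int(tallies[1])
    return state


def run_replicate(
    params: ModelParams,
    N: int,
    generations: int,
    seed: int,
    log_interval: int = 1000,
    init: str = "favored",
) -> PopulationState:
    """Run one replicate from scratch; reproducible from its arguments.

    ``init='equilibrium'`` seeds site states at the predicted equilibrium
    level of adaptation to shorten burn-in (documented deviation from the
    all-favorable start; the ``pbar_log`` plateau should be checked either
    way).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    state = initialize_population(params, N, seed)
    if init == "equilibrium":
        from .equilibrium import li_bulmer_pbar
        from .solver import solve_fixation_B

        sol = solve_fixation_B(params) if params.s > 0 else None
        pb = li_bulmer_pbar(sol.gamma, params.kappa) if sol else 1.0 / (1.0 + params.kappa)
        rng = np.random.default_rng(state.seed ^ 0x5DEECE66)
        seed_equilibrium_frequencies(state, params, pb, rng)
    elif init != "favored":
        raise ValueError("init must be 'favored' or 'equilibrium'")
    nlog = generations // log_interval if log_interval > 0 else 0
    log = np.zeros(max(nlog, 1), dtype=np.float64)
    tallies = np.zeros(2, dtype=np.int64)
    nv, no = _wf_kernel(
        state.sel, state.K, state.neu, state.neu_pos, state.neu_origin,
        state.n_variants, state.next_origin, N, params.L,
        params.u, params.v, params.s, params.kappa == 1.0, generations,
        state.seed, _SCAN_INTERVAL, state.fixed_state, log,
        log_interval if nlog > 0 else 0, tallies,
    )
    state.n_variants = nv
    state.next_origin = no
    state.generation = generations
    state.fixed_neutral = int(tallies[0])
    state.fixed_selected = int(tallies[1])
    state.pbar_log = log[:nlog].tolist()
    return state


def sample_genomes(
    state: PopulationState, k: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw ``k`` genomes without replacement and export site columns.

    Selected sites with at least one derived (deleterious) copy in the
    sample and all neutral variants carried by the sample are retained;
    sites where every sampled genome carries the derived allele are flagged
    fixed-in-sample.
    """
    if not 2 <= k <= state.N:
        raise ValueError("need 2 <= k <= N")
    idx = rng.choice(state.N, size=k, replace=False)
    sel_bits = np.unpackbits(
        state.sel[idx].view(np.uint8), axis=1, bitorder="little"
    )[:, : state.L]
    neu_bits = np.unpackbits(
        state.neu[idx].view(np.uint8), axis=1, bitorder="little"
    )[:, : state.n_variants]
    positions, classes, cols, fixed = [], [], [], []
    sel_counts = sel_bits.sum(axis=0)
    for site in np.nonzero(sel_counts > 0)[0]:
        positions.append(site)
        classes.append(0)
        cols.append(sel_bits[:, site])
        fixed.append(sel_counts[site] == k)
    neu_counts = neu_bits.sum(axis=0)
    for c in np.nonzero(neu_counts > 0)[0]:
        positions.append(state.neu_pos[c])
        classes.append(1)
        cols.append(neu_bits[:, c])
        fixed.append(neu_counts[c] == k)
    geno = (
        np.array(cols, dtype=np.uint8)
        if cols
        else np.empty((0, k), dtype=np.uint8)
    )
    return GenotypeMatrix(
        k=k,
        positions=np.array(positions, dtype=np.int64),
        classes=np.array(classes, dtype=np.int64),
        genotypes=geno,
        fixed_in_sample=np.array(fixed, dtype=bool),
    )
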