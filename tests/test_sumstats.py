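import itertools
import math

import numpy as np
import pytest

import hritools as h
from hritools.fixtures import make_fixtures
from hritools.params import ModelParams
from hritools.simulate import PopulationState


def _state_from_matrix(genomes: np.ndarray) -> PopulationState:
    """Pack an explicit (N x L) 0/1 matrix into a PopulationState."""
    N, L = genomes.shape
    Ws = (L + 63) // 64
    sel = np.zeros((N, Ws), dtype=np.uint64)
    for j in range(N):
        for site in range(L):
            if genomes[j, site]:
                sel[j, site // 64] |= np.uint64(1) << np.uint64(site % 64)
    return PopulationState(
        N=N, L=L, sel=sel, K=genomes.sum(axis=1).astype(np.int64),
        neu=np.zeros((N, 1), dtype=np.uint64),
        neu_pos=np.zeros(64, dtype=np.int64),
        neu_origin=np.zeros(64, dtype=np.int64),
        n_variants=0, next_origin=0, generation=1, seed=0,
    )


def _brute_force_sum_D(genomes: np.ndarray) -> float:
    """O(L^2) oracle: sum of D_ij = p_AB - p_A p_B over all site pairs."""
    N, L = genomes.shape
    tot = 0.0
    for i, j in itertools.combinations(range(L), 2):
        pa = genomes[:, i].mean()
        pb = genomes[:, j].mean()
        pab = (genomes[:, i] & genomes[:, j]).mean()
        tot += pab - pa * pb
    return tot


class TestPbarAndB:
    def test_all_favorable_undefined(self):
        p = ModelParams(N0=1000, s=1e-3, u=1e-5, kappa=2.0, L=100)
        st = h.initialize_population(p, N=50, seed=1)
        pb, gh, bh = h.pbar_and_B(st, p)
        assert pb == 1.0 and gh is None and bh is None

    def test_worked_inversion(self):
        p = ModelParams.from_gamma0(N0=1000, gamma0=1.0, u=1e-5, kappa=2.0, L=100)
        pb, gh, bh = h.pbar_and_B(0.576, p)
        assert bh == pytest.approx(1.0, abs=5e-3)

    def test_symmetric_point_gives_zero(self):
        p = ModelParams.from_gamma0(N0=1000, gamma0=2.0, u=1e-5, kappa=1.0, L=100)
        pb, gh, bh = h.pbar_and_B(0.5, p)
        assert gh == 0.0 and bh == 0.0


class TestPairwisePi:
    def test_identical_rows_zero(self):
        m = np.ones((5, 10), dtype=np.uint8).T  # sites x k
        assert h.pairwise_pi(m.T * 0 + 1, L_norm=10) == 0.0

    def test_two_genomes_one_difference(self):
        L = 20
        geno = np.zeros((L, 2), dtype=np.uint8)
        geno[3, 0] = 1
        assert h.pairwise_pi(geno, L_norm=L) == pytest.approx(1 / L)

    def test_matches_average_hamming_distance(self, rng):
        sites, k = 50, 20
        geno = (rng.random((sites, k)) < 0.4).astype(np.uint8)
        brute = np.mean(
            [
                np.sum(geno[:, a] != geno[:, b])
                for a, b in itertools.combinations(range(k), 2)
            ]
        )
        assert h.pairwise_pi(geno, L_norm=sites) == pytest.approx(
            brute / sites, rel=1e-12
        )

    def test_bad_norm(self):
        with pytest.raises(ValueError):
            h.pairwise_pi(np.zeros((3, 4), dtype=np.uint8), L_norm=0)


class TestLdSum:
    def test_monomorphic_population_zero(self):
        genomes = np.zeros((10, 6), dtype=np.uint8)
        p = ModelParams(N0=10, s=1e-3, u=1e-5, kappa=1.0, L=6)
        ld = h.ld_sum_and_correction(_state_from_matrix(genomes), p)
        assert ld.sum_D == 0.0 and ld.C == 0.0

    def test_planted_coupling_fixture(self):
        fx = make_fixtures(0)
        p = ModelParams(N0=4, s=1e-3, u=1e-5, kappa=1.0, L=2)
        ld = h.ld_sum_and_correction(_state_from_matrix(fx.planted_ld_matrix), p)
        assert ld.sum_D == pytest.approx(fx.planted_ld_manifest["sum_D"], abs=1e-12)
        assert ld.C == pytest.approx(fx.planted_ld_manifest["C"], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_variance_identity_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        N, L = 50, 30
        genomes = (rng.random((N, L)) < rng.uniform(0.05, 0.6)).astype(np.uint8)
        p = ModelParams(N0=N, s=1e-3, u=1e-5, kappa=1.0, L=L)
        ld = h.ld_sum_and_correction(_state_from_matrix(genomes), p)
        assert ld.sum_D == pytest.approx(_brute_force_sum_D(genomes), abs=1e-10)
        assert ld.C == pytest.approx(-2 * (L - 1) * ld.mean_D, rel=1e-12)

    def test_mean_ld_negative_under_interference(self, warm_simulator):
        # repulsion disequilibrium among deleterious alleles is the
        # signature of interference; check on a scaled-down population
        p = ModelParams.from_gamma0(N0=300, gamma0=20.0, u=1e-4, kappa=1.0, L=1000)
        sums = []
        for rep in range(8):
            st = h.run_replicate(p, 300, 6000, seed=40 + rep, init="equilibrium")
            sums.append(h.ld_sum_and_correction(st, p).sum_D)
        assert np.mean(sums) < 0

    def test_correction_improves_selected_diversity_prediction(
        self, warm_simulator
    ):
        # the LD-corrected predicted diversity at selected sites should sit
        # closer to the simulated value than the uncorrected one
        p = ModelParams.from_gamma0(N0=500, gamma0=10.0, u=5e-5, kappa=1.0, L=2000)
        sol = h.solve_fixation_B(p)
        pi_sims, Cs = [], []
        for rep in range(6):
            st = h.run_replicate(p, 500, 8000, seed=60 + rep, init="equilibrium")
            rng = np.random.default_rng(160 + rep)
            m = h.sample_genomes(st, 20, rng)
            pi_sims.append(h.pairwise_pi(m.by_class(0), p.L))
            Cs.append(h.ld_sum_and_correction(st, p).C)
        pi_sim = np.mean(pi_sims)
        pred_u = h.expected_site_diversity(p.u, p.s, sol.gamma, p.kappa)
        pred_c = pred_u + np.mean(Cs)
        assert abs(pred_c - pi_sim) < abs(pred_u - pi_sim)


class TestObservedSfs:
    def test_monomorphic_sample(self):
        p = ModelParams(N0=100, s=0.0, u=1e-300, kappa=1.0, L=64)
        st = h.initialize_population(p, N=100, seed=3)
        m = h.sample_genomes(st, 10, np.random.default_rng(4))
        sfs = h.observed_sfs(m)
        assert sfs.counts.sum() == 0

    def test_counts_by_derived_allele_number(self, rng):
        from hritools.simulate import GenotypeMatrix

        k = 20
        geno = np.zeros((3, k), dtype=np.uint8)
        geno[0, 0] = 1          # singleton
        geno[1, :5] = 1         # 5 copies
        geno[2, :] = 1          # fixed in sample
        m = GenotypeMatrix(
            k=k,
            positions=np.array([1, 2, 3]),
            classes=np.array([1, 1, 1]),
            genotypes=geno,
            fixed_in_sample=np.array([False, False, True]),
        )
        sfs = h.observed_sfs(m)
        assert sfs.counts[0] == 1 and sfs.counts[4] == 1
        assert sfs.counts.sum() == 2
        assert sfs.n_fixed_in_sample == 1

    def test_empirical_distortion_consistent_with_pooled_path(
        self, warm_simulator, rng
    ):
        # the pooled spectrum fed to the analytic statistics must agree with
        # per-replicate spectra summed by hand
        p = ModelParams(N0=300, s=0.0, u=5e-5, kappa=1.0, L=500)
        pooled = np.zeros(19, dtype=np.int64)
        for rep in range(5):
            st = h.run_replicate(p, 300, 3000, seed=70 + rep)
            m = h.sample_genomes(st, 20, np.random.default_rng(300 + rep))
            pooled += h.observed_sfs(m).counts
        ds_pooled = h.delta_theta_stats(h.SampleSFS(k=20, counts=pooled))
        ds_vector = h.delta_theta_stats(pooled.astype(float), k=20)
        assert ds_pooled.delta_thetaw_prime == pytest.approx(
            ds_vector.delta_thetaw_prime, rel=1e-12
        )


class TestSummaries:
    def test_ci_width_scales_with_replicates(self):
        rng = np.random.default_rng(0)
        p = ModelParams(N0=100, s=1e-3, u=1e-5, kappa=1.0, L=100)

        def fake_stats(n):
            return [
                h.SummaryStats(
                    pbar=0.9 + 0.01 * rng.standard_normal(),
                    gamma_hat=1.0, B_hat=0.5, pi_sel=0.001, pi_neut=0.01,
                    Bprime_hat=0.5, S_k=10, theta_w=0.01, delta_thetaw=0.1,
                    delta_thetaw_prime=0.2, sum_D=-0.1, C=0.001,
                    lambda_neutral_hat=0.001, lambda_selected_hat=0.0001,
                )
                for _ in range(n)
            ]

        df1 = h.summarize_replicates(fake_stats(25), p)
        df2 = h.summarize_replicates(fake_stats(100), p)
        w1 = df1.attrs["summary"].loc["pbar", "ci95_hi"] - df1.attrs["summary"].loc["pbar", "ci95_lo"]
        w2 = df2.attrs["summary"].loc["pbar", "ci95_hi"] - df2.attrs["summary"].loc["pbar", "ci95_lo"]
        assert w2 < w1
        assert w2 == pytest.approx(w1 / 2, rel=0.5)

    def test_neutral_replicates_recover_baseline_diversity(self, warm_simulator):
        p = ModelParams(N0=1000, s=0.0, u=1e-5, kappa=1.0, L=500)
        stats = []
        for rep in range(10):
            st = h.run_replicate(p, 1000, 10_000, seed=810 + rep)
            stats.append(h.replicate_stats(st, p, k=20))
        df = h.summarize_replicates(stats, p)
        s = df.attrs["summary"]
        lo, hi = s.loc["pi_neut", "ci95_lo"], s.loc["pi_neut", "ci95_hi"]
        assert lo - 0.004 < 0.02 < hi + 0.004
        assert df.attrs["bprime_normalization"] == "2*N0*u"
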