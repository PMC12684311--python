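"""Coalescent engine: standard expectations, msprime oracle, scenarios."""

import numpy as np
import pytest

from gfchrono.coalescent import (IMModel, SampleConfig, expected_joint_sfs,
                                 make_scenario, sample_genealogy,
                                 scale_scenario, simulate_observed_sfs)


def single_deme(n=1000.0):
    return IMModel(n, n, n, t_split=0.0)


def batched_sfs(model, samples, seq_len, mu, reps_per_batch, n_batches,
                seed0):
    """Per-cell batch means, for Monte Carlo standard errors."""
    out = []
    for b in range(n_batches):
        sfs = expected_joint_sfs(model, samples, seq_len, mu,
                                 reps_per_batch, seed=seed0 + 7919 * b)
        out.append(sfs.counts)
    return np.array(out)


class TestSingleDemeExpectations:
    def test_mean_tmrca_two_samples(self):
        n = 1000.0
        tm = [sample_genealogy(single_deme(n), SampleConfig(2, 0), s).tmrca
              for s in range(4000)]
        se = 2 * n / np.sqrt(len(tm))  # sd of T2 is 2N
        assert abs(np.mean(tm) - 2 * n) < 3 * se

    def test_mean_total_length_two_samples(self):
        n = 1000.0
        tl = [sample_genealogy(single_deme(n), SampleConfig(2, 0),
                               s).total_length for s in range(4000)]
        se = 4 * n / np.sqrt(len(tl))
        assert abs(np.mean(tl) - 4 * n) < 3 * se

    def test_branch_tally_sums_to_total_length(self):
        model = IMModel(500, 800, 2000, t_split=3000, x_break=1000,
                        m_recent=1e-4, m_old=1e-5)
        for seed in range(20):
            tal = sample_genealogy(model, SampleConfig(5, 4), seed)
            assert tal.branch.sum() == pytest.approx(tal.total_length,
                                                     rel=1e-12)

    def test_marginal_sfs_proportional_to_inverse_frequency(self):
        n, mu, L = 1000.0, 1e-8, 1e6
        theta = 4 * n * mu * L
        batches = batched_sfs(single_deme(n), SampleConfig(6, 0), L, mu,
                              500, 10, seed0=11)
        mean = batches.mean(axis=0)[:, 0]
        se = batches.std(axis=0, ddof=1)[:, 0] / np.sqrt(batches.shape[0])
        for i in range(1, 6):
            assert abs(mean[i] - theta / i) < 3 * se[i]

    def test_pairwise_diversity_equals_theta(self):
        n, mu, L = 1000.0, 1e-8, 1e6
        batches = batched_sfs(single_deme(n), SampleConfig(1, 1), L, mu,
                              500, 10, seed0=23)
        het = batches.sum(axis=(1, 2))
        se = het.std(ddof=1) / np.sqrt(het.size)
        assert abs(het.mean() - 4 * n * mu * L) < 3 * se


class TestAgainstMsprime:
    """Cross-checks against an independent coalescent simulator."""

    @staticmethod
    def msprime_branch_tally(k1, k2, n_diploid, t_split, m, n_anc, reps,
                             seed):
        """Mean (i, j)-configuration branch lengths from msprime trees."""
        import msprime
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=n_diploid)
        dem.add_population(name="p2", initial_size=n_diploid)
        dem.add_population(name="anc", initial_size=n_anc)
        if m > 0:
            dem.set_symmetric_migration_rate(["p1", "p2"], m)
        dem.add_population_split(time=t_split, derived=["p1", "p2"],
                                 ancestral="anc")
        acc = np.zeros((k1 + 1, k2 + 1))
        # diploid populations, haploid sample sets: coalescence at 1/(2N)
        # per pair with k1 + k2 sampled chromosomes
        reps_iter = msprime.sim_ancestry(
            samples=[msprime.SampleSet(k1, population="p1", ploidy=1),
                     msprime.SampleSet(k2, population="p2", ploidy=1)],
            demography=dem, num_replicates=reps, random_seed=seed)
        for ts in reps_iter:
            tree = ts.first()
            pop = [ts.node(s).population for s in range(k1 + k2)]
            for node in tree.nodes():
                if tree.parent(node) == -1:
                    continue
                i = sum(1 for s in tree.samples(node) if pop[s] == 0)
                j = sum(1 for s in tree.samples(node) if pop[s] == 1)
                acc[i, j] += tree.branch_length(node)
        return acc / reps

    def test_two_deme_joint_branch_lengths_match(self):
        k1 = k2 = 3
        n, t, m, nanc = 600.0, 1500.0, 2e-4, 1200.0
        oracle = self.msprime_branch_tally(k1, k2, n, t, m, nanc,
                                           reps=8000, seed=5)
        model = IMModel(n, n, nanc, t_split=t, x_break=t, m_recent=m,
                        m_old=m)
        batches = []
        for b in range(10):
            sfs = expected_joint_sfs(model, SampleConfig(k1, k2), 1.0, 1.0,
                                     800, seed=31 + 101 * b)
            batches.append(sfs.counts)
        batches = np.array(batches)
        mean = batches.mean(axis=0)
        se = batches.std(axis=0, ddof=1) / np.sqrt(10)
        mask = np.ones_like(mean, dtype=bool)
        mask[0, 0] = mask[k1, k2] = False  # engine zeroes fixed cells
        big = oracle[mask] > oracle[mask].max() * 0.02
        diff = np.abs(mean[mask] - oracle[mask])[big]
        # both sides carry Monte Carlo error; allow 4 SE plus the oracle's
        # own sampling slack
        bound = (4 * se[mask] + 0.05 * oracle[mask])[big]
        assert (diff < bound).all()

    def test_isolated_demes_have_no_recent_shared_polymorphism(self):
        # m = 0 and a deep split: every branch with descendants in both
        # demes must live in the ancestral epoch, so shared-polymorphism
        # mass is bounded by the ancestral fraction seen by the oracle
        k = 4
        model = IMModel(500, 500, 500, t_split=50_000.0, x_break=0.0)
        sfs = expected_joint_sfs(model, SampleConfig(k, k), 1.0, 1.0, 2000,
                                 seed=3)
        shared = sum(sfs.counts[i, j]
                     for i in range(1, k) for j in range(1, k))
        oracle = self.msprime_branch_tally(k, k, 500.0, 50_000.0, 0.0,
                                           500.0, 2000, seed=9)
        shared_oracle = sum(oracle[i, j]
                            for i in range(1, k) for j in range(1, k))
        assert shared == pytest.approx(shared_oracle, rel=0.25, abs=5.0)


class TestExpectedSfsProperties:
    def test_doubling_length_doubles_cells(self):
        model = single_deme()
        a = expected_joint_sfs(model, SampleConfig(4, 0), 1e6, 1e-8, 200, 1)
        b = expected_joint_sfs(model, SampleConfig(4, 0), 2e6, 1e-8, 200, 1)
        np.testing.assert_allclose(b.counts, 2 * a.counts, rtol=1e-12)

    def test_migration_increases_shared_polymorphism(self):
        base = dict(n1_current=1000.0, n2_current=1000.0,
                    n_ancestral=1000.0, t_split=8000.0, x_break=8000.0)
        k = 4
        shared = []
        for m in (0.0, 3e-4):
            sfs = expected_joint_sfs(IMModel(m_recent=m, m_old=m, **base),
                                     SampleConfig(k, k), 1e6, 1e-8, 4000,
                                     seed=17)
            shared.append(sum(sfs.counts[i, j] for i in range(1, k)
                              for j in range(1, k)))
        assert shared[1] > shared[0]

    def test_observed_sfs_deterministic_under_seed(self):
        sc = scale_scenario(make_scenario(2), 0.1, n_loci=20,
                            locus_length=1e4, windows_per_locus=1)
        a = simulate_observed_sfs(sc, SampleConfig(4, 4), seed=42)
        b = simulate_observed_sfs(sc, SampleConfig(4, 4), seed=42)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_observed_sfs(sc, SampleConfig(4, 4), seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_observed_counts_are_poisson_around_expectation(self):
        sc = scale_scenario(make_scenario(1), 0.1, n_loci=50,
                            locus_length=2e4, windows_per_locus=1)
        samp = SampleConfig(4, 4)
        obs = simulate_observed_sfs(sc, samp, seed=7)
        expected = expected_joint_sfs(sc.model, samp,
                                      sc.genome_length, sc.mutation_rate,
                                      sc.n_windows, seed=7)
        tot_obs, tot_exp = obs.counts.sum(), expected.counts.sum()
        assert abs(tot_obs - tot_exp) < 5 * np.sqrt(tot_exp)


class TestScenarioTable:
    """The five validation scenarios carry the published parameterization."""

    @pytest.mark.parametrize("sid", [1, 2, 3, 4, 5])
    def test_common_parameters(self, sid):
        sc = make_scenario(sid)
        m = sc.model
        assert m.n_ancestral == 202_500.0
        assert m.t_split == 45_000.0
        assert sc.n_loci == 6 and sc.locus_length == 15_000_000.0
        assert sc.recombination_rate == 1e-8
        assert sc.mutation_rate == 1e-8

    def test_scenario1_no_gene_flow(self):
        m = make_scenario(1).model
        assert m.m_recent == 0.0 and m.m_old == 0.0
        assert m.n1_current == 11_250.0

    def test_scenario2_constant_gene_flow(self):
        m = make_scenario(2).model
        assert m.migration_rate(1.0) == 6e-5
        assert m.migration_rate(44_999.0) == 6e-5

    def test_scenario3_decline(self):
        sc = make_scenario(3)
        m = sc.model
        assert m.growth_rate_1 == -5e-5
        # ~90% reduction from the size at the split
        assert sc.annotations["size_reduction_fraction"] == pytest.approx(
            1 - np.exp(-2.25))
        assert m.n1_current == pytest.approx(11_250 * np.exp(-2.25))
        assert sc.annotations["printed_current_diploid"] == 1_000.0

    def test_scenario4_growth(self):
        sc = make_scenario(4)
        assert sc.model.growth_rate_1 == 5e-5
        assert sc.annotations["size_fold_increase"] == pytest.approx(
            np.exp(2.25))
        assert sc.model.n1_current == pytest.approx(11_250 * np.exp(2.25))
        assert sc.annotations["printed_current_diploid"] == 500_000.0

    @pytest.mark.parametrize("tau,rate", [
        (100.0, 0.0),       # most recent window: gene flow off
        (400.0, 1e-5),
        (700.0, 2e-5),      # 600-3000 generations ago
        (4_000.0, 3e-5),
        (7_000.0, 4e-5),
        (10_000.0, 5e-5),
        (13_000.0, 6e-5),
        (44_000.0, 6e-5),   # from the split until 12,000 generations ago
    ])
    def test_scenario5_schedule(self, tau, rate):
        assert make_scenario(5).model.migration_rate(tau) == rate

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_scenario(6)

    def test_rescaling_preserves_coalescent_units(self):
        sc = scale_scenario(make_scenario(5), 0.1)
        m = make_scenario(5).model
        s = sc.model
        assert s.t_split == m.t_split * 0.1
        assert s.n_ancestral == m.n_ancestral * 0.1
        assert s.migration_rate(70.0) == pytest.approx(
            m.migration_rate(700.0) * 10)
        assert sc.mutation_rate == pytest.approx(1e-7)
        assert sc.recombination_rate == pytest.approx(1e-7)


class TestModelValidation:
    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            IMModel(0.0, 100.0, 100.0, t_split=10.0)

    def test_x_break_beyond_split_rejected(self):
        with pytest.raises(ValueError):
            IMModel(100.0, 100.0, 100.0, t_split=10.0, x_break=20.0)

    def test_migration_probability_range(self):
        with pytest.raises(ValueError):
            IMModel(100.0, 100.0, 100.0, t_split=10.0, x_break=5.0,
                    m_recent=1.5)

    def test_sample_config_requires_two(self):
        with pytest.raises(ValueError):
            SampleConfig(1, 0)
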