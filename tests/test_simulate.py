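import numpy as np
import pytest

import phyloglmm as pg
from phyloglmm.simulate import sample_library_sizes, signal_density_pct


class TestRandomTree:
    def test_two_tips(self):
        dist, nwk = pg.random_tree(2, seed=0)
        assert dist.n_tips == 2
        assert dist.D.shape == (2, 2)
        assert dist.D[0, 1] == dist.D[1, 0] >= 0

    def test_determinism_per_seed(self):
        d1, _ = pg.random_tree(50, seed=5)
        d2, _ = pg.random_tree(50, seed=5)
        d3, _ = pg.random_tree(50, seed=6)
        assert np.array_equal(d1.D, d2.D)
        assert not np.array_equal(d1.D, d3.D)

    def test_default_dimension_778(self):
        dist, _ = pg.random_tree(778, seed=0)
        assert dist.n_tips == 778


class TestSimulateCounts:
    def test_proportions_sum_to_one(self):
        dm = pg.DmParams.default(30)
        counts, z = pg.simulate_counts(dm, 25, seed=1)
        assert np.max(np.abs(z.sum(axis=1) - 1.0)) < 1e-12
        assert np.array_equal(counts.sum(axis=1) > 0, np.ones(25, bool))

    def test_library_size_calibration(self):
        dm = pg.DmParams.default(10)
        rng = np.random.default_rng(2)
        lib = sample_library_sizes(dm, 10_000, rng)
        se = lib.std(ddof=1) / np.sqrt(len(lib))
        assert abs(lib.mean() - 5000.0) < 2 * se
        assert np.all(lib > 0)

    def test_overdispersion_monotone_in_phi(self):
        p, n = 20, 600
        base = pg.DmParams.default(p)
        variances = []
        for phi in (0.01, 0.1, 0.5):
            dm = pg.DmParams(base.mean_proportions, phi=phi)
            _, z = pg.simulate_counts(dm, n, seed=3)
            variances.append(z.var(axis=0).sum())
        assert variances[0] < variances[1] < variances[2]

    def test_phi_near_zero_concentrates_at_mean(self):
        dm = pg.DmParams.default(15, phi=0.001)
        _, z = pg.simulate_counts(dm, 400, seed=4)
        assert np.max(np.abs(z.mean(axis=0) - dm.mean_proportions)) < 0.01


class TestEstimateDm:
    def test_round_trip_recovers_phi(self):
        truth = pg.DmParams.default(25, phi=0.05)
        counts, _ = pg.simulate_counts(truth, 5000, seed=9)
        est = pg.estimate_dm(counts)
        assert abs(est.phi - truth.phi) / truth.phi < 0.2

    def test_mean_proportions_are_empirical_means(self):
        truth = pg.DmParams.default(10, phi=0.1)
        counts, z = pg.simulate_counts(truth, 50, seed=10)
        est = pg.estimate_dm(counts)
        assert np.allclose(est.mean_proportions, z.mean(axis=0), atol=1e-12)

    def test_identical_rows_give_phi_near_zero(self):
        row = np.array([100, 50, 25, 25])
        counts = np.tile(row, (20, 1))
        est = pg.estimate_dm(counts)
        assert est.phi < 1e-4

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            pg.estimate_dm(np.array([[10.0], [20.0]]))


class TestPamClusters:
    def test_m_equals_p_gives_singletons(self, small_tree):
        clusters = pg.pam_clusters(small_tree, small_tree.n_tips)
        assert len(clusters) == small_tree.n_tips
        assert all(len(c) == 1 for c in clusters)

    def test_single_cluster_contains_everything(self, small_tree):
        clusters = pg.pam_clusters(small_tree, 1)
        assert len(clusters) == 1
        assert sorted(clusters[0]) == list(range(small_tree.n_tips))

    def test_partition_is_disjoint_and_complete(self, small_tree):
        clusters = pg.pam_clusters(small_tree, 4)
        all_idx = np.concatenate(clusters)
        assert sorted(all_idx) == list(range(small_tree.n_tips))

    def test_two_separated_clades_recovered(self):
        # two tight clades far apart; PAM with m=2 must split on the gap
        labels = [f"t{i}" for i in range(8)]
        D = np.zeros((8, 8))
        rng = np.random.default_rng(0)
        for i in range(8):
            for j in range(i + 1, 8):
                same = (i < 4) == (j < 4)
                D[i, j] = D[j, i] = rng.uniform(0.1, 0.3) if same else rng.uniform(9, 11)
        dist = pg.PhyloDistances(labels, D)
        clusters = pg.pam_clusters(dist, 2)
        groups = {frozenset(c.tolist()) for c in clusters}
        assert groups == {frozenset(range(4)), frozenset(range(4, 8))}

    def test_m_out_of_range(self, small_tree):
        with pytest.raises(ValueError):
            pg.pam_clusters(small_tree, small_tree.n_tips + 1)


class TestSelectAclusters:
    def _setup(self, seed=0):
        dist, _ = pg.random_tree(40, seed=seed)
        dm = pg.DmParams.default(40)
        _, z = pg.simulate_counts(dm, 30, seed=seed)
        clusters = pg.pam_clusters(dist, 8)
        return clusters, z

    def test_mc_equals_m_returns_all(self):
        clusters, z = self._setup()
        assert pg.select_aclusters(clusters, z, len(clusters), "low") == list(
            range(len(clusters))
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_abundance_levels_are_ordered(self, seed):
        clusters, z = self._setup(seed)
        def cum(level):
            chosen = pg.select_aclusters(clusters, z, 2, level, seed=seed)
            return sum(z[:, clusters[i]].sum(axis=1).mean() for i in chosen)
        assert cum("high") >= cum("medium") >= cum("low")

    def test_dominant_cluster_always_selected_at_high(self):
        clusters, z = self._setup()
        # make cluster 0 dominate the table
        z = z.copy()
        z[:, clusters[0]] += 10.0
        for seed in range(5):
            chosen = pg.select_aclusters(clusters, z, 1, "high", seed=seed)
            assert chosen == [0]

    def test_density_level_lookup(self):
        assert signal_density_pct(10, "low") == 10.0
        assert signal_density_pct(100, "medium") == 5.0
        assert signal_density_pct(778, "high", p=778) == 30.0


class TestGenerateOutcome:
    def _design(self, **kw):
        base = dict(
            m=10, signal_density_pct=20, abundance_level="high",
            outcome_type="continuous", seed=0,
        )
        base.update(kw)
        return pg.SimulationDesign(**base)

    def test_variance_decomposition_is_exact(self):
        rng = np.random.default_rng(0)
        z = rng.random((100, 30))
        members = [np.arange(5), np.arange(10, 14)]
        for seed in (0, 1, 99):
            y, eta, b, sigma_e2 = pg.generate_outcome(
                z, members, self._design(), seed=seed
            )
            signal = eta - 0.0
            ratio = np.var(signal) / (np.var(signal) + sigma_e2)
            assert ratio == pytest.approx(0.8, abs=1e-12)

    def test_presence_transform_ignores_magnitudes(self):
        rng = np.random.default_rng(1)
        z = rng.random((50, 20)) * (rng.random((50, 20)) > 0.4)
        members = [np.arange(6)]
        design = self._design(signal_transform="presence")
        _, eta1, _, _ = pg.generate_outcome(z, members, design, seed=5)
        z2 = z * (1.0 + rng.random(z.shape))  # same support, new magnitudes
        _, eta2, _, _ = pg.generate_outcome(z2, members, design, seed=5)
        assert np.array_equal(eta1, eta2)

    def test_zero_effect_variance_gives_constant_eta(self):
        rng = np.random.default_rng(2)
        z = rng.random((40, 10))
        design = self._design(outcome_type="binary", sigma_b2=0.0, beta0=0.3)
        y, eta, b, _ = pg.generate_outcome(z, [np.arange(3)], design, seed=3)
        assert np.all(eta == 0.3)
        assert set(np.unique(y)) <= {0.0, 1.0}

    def test_empty_acluster_list_rejected(self):
        with pytest.raises(ValueError):
            pg.generate_outcome(np.ones((5, 3)), [], self._design())

    def test_shared_coefficient_within_cluster(self):
        rng = np.random.default_rng(3)
        z = rng.random((30, 12))
        members = [np.array([0, 1, 2])]
        _, eta, b, _ = pg.generate_outcome(z, members, self._design(), seed=4)
        manual = b[0] * z[:, [0, 1, 2]].sum(axis=1)
        assert np.allclose(eta, manual)


class TestPermuteTree:
    def test_zero_pct_is_identity(self, small_tree):
        out = pg.permute_tree(small_tree, 0, seed=1)
        assert np.array_equal(out.D, small_tree.D)

    def test_full_permutation_preserves_offdiagonal_multiset(self, small_tree):
        out = pg.permute_tree(small_tree, 100, seed=2)
        iu = np.triu_indices(small_tree.n_tips, k=1)
        assert sorted(out.D[iu]) == pytest.approx(sorted(small_tree.D[iu]))

    @pytest.mark.parametrize("pct", [10, 50, 100])
    def test_output_remains_valid_distance_matrix(self, small_tree, pct):
        out = pg.permute_tree(small_tree, pct, seed=3)
        assert np.array_equal(out.D, out.D.T)
        assert np.all(np.diag(out.D) == 0)


class TestSimulateDataset:
    def test_end_to_end_shapes_and_truth(self):
        design = pg.SimulationDesign(
            m=10, signal_density_pct=20, abundance_level="medium", seed=8
        )
        data = pg.simulate_dataset(design, n=40, p=50)
        assert data.counts.shape == (40, 50)
        assert data.proportions.shape == (40, 50)
        assert len(data.outcome) == 40
        assert len(data.coefficients) == design.n_aclusters
        # eta is reproducible from the stored pieces
        signal = np.zeros(40)
        for bl, members in zip(data.coefficients, data.acluster_members):
            signal += data.proportions[:, members].sum(axis=1) * bl
        assert np.allclose(data.eta, data.beta0 + signal)

    def test_same_seed_reproduces_dataset(self):
        design = pg.SimulationDesign(m=10, signal_density_pct=10, seed=12)
        a = pg.simulate_dataset(design, n=20, p=30)
        b = pg.simulate_dataset(design, n=20, p=30)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.outcome, b.outcome)

    def test_binary_outcome_is_bernoulli(self):
        design = pg.SimulationDesign(
            m=10, signal_density_pct=20, outcome_type="binary", seed=4
        )
        data = pg.simulate_dataset(design, n=30, p=30)
        assert set(np.unique(data.outcome)) <= {0.0, 1.0}
        assert data.design.sigma_b2 == 4.0
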