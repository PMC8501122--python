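import dataclasses

import numpy as np
import pytest

from scgraphae.synthetic_data import (ClusterSimConfig, TrajectorySimConfig,
                                      scenario_config, simulate_clusters,
                                      simulate_trajectory)


class TestClusterSim:
    def test_seeded_determinism(self):
        cfg = ClusterSimConfig(n_cells=50, n_genes=80, seed=7,
                               dropout_shape=-1.0)
        m1, l1, r1 = simulate_clusters(cfg)
        m2, l2, r2 = simulate_clusters(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(l1, l2)
        assert r1 == r2

    def test_counts_are_integer_and_labeled(self):
        cfg = ClusterSimConfig(n_cells=60, n_genes=40, n_groups=3, seed=0)
        m, labels, rate = simulate_clusters(cfg)
        assert m.values.shape == (60, 40)
        np.testing.assert_array_equal(m.values, np.round(m.values))
        assert labels.shape == (60,)
        assert set(labels) <= set(range(3))
        assert rate == 0.0  # dropout disabled

    def test_groups_roughly_balanced(self):
        cfg = ClusterSimConfig(n_cells=2000, n_genes=20, n_groups=4, seed=1)
        _, labels, _ = simulate_clusters(cfg)
        counts = np.bincount(labels, minlength=4)
        assert counts.min() > 2000 / 4 * 0.7

    def test_overdispersion(self):
        cfg = ClusterSimConfig(n_cells=400, n_genes=200, n_groups=2,
                               de_prob=0.01, de_strength=0.01,
                               dispersion=0.5, seed=3)
        m, labels, _ = simulate_clusters(cfg)
        x = m.values[labels == 0]
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        high = mean > 5
        # NB with dispersion 0.5: var clearly exceeds mean
        assert np.mean(var[high] > mean[high]) > 0.9

    def test_dropout_rate_monotone_in_midpoint(self):
        rates = []
        for mid in (-0.5, 0.0, 0.5, 1.0):
            cfg = ClusterSimConfig(n_cells=300, n_genes=500,
                                   dropout_shape=-1.0, dropout_mid=mid,
                                   seed=11)
            _, _, rate = simulate_clusters(cfg)
            rates.append(rate)
        assert rates == sorted(rates)
        assert rates[0] > 0

    def test_very_negative_shape_spares_high_expression(self):
        cfg = ClusterSimConfig(n_cells=200, n_genes=400,
                               dropout_shape=-20.0, dropout_mid=0.0,
                               seed=5)
        m, _, _ = simulate_clusters(cfg)
        cfg0 = dataclasses.replace(cfg, dropout_shape=None)
        m0, _, _ = simulate_clusters(cfg0)
        high = m0.values.mean(axis=0) > 10
        # strongly expressed genes keep (almost) all their counts
        zero_frac = (m.values[:, high] == 0).mean()
        zero_frac0 = (m0.values[:, high] == 0).mean()
        assert zero_frac <= zero_frac0 + 0.01

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ClusterSimConfig(n_groups=1)
        with pytest.raises(ValueError):
            ClusterSimConfig(de_prob=0.0)
        with pytest.raises(ValueError):
            ClusterSimConfig(dispersion=0.0)


class TestTrajectorySim:
    def test_seeded_determinism(self):
        cfg = TrajectorySimConfig(n_cells=40, n_genes=60, seed=2,
                                  tree=((None, 0, 10),))
        m1, p1, b1 = simulate_trajectory(cfg)
        m2, p2, b2 = simulate_trajectory(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_drift_null(self):
        cfg = TrajectorySimConfig(n_cells=50, n_genes=60,
                                  tree=((None, 0, 10),),
                                  program_drift_sd=0.0, seed=4)
        m, pt, branch = simulate_trajectory(cfg)
        assert (branch == 0).all()
        assert pt.min() >= 0 and pt.max() <= 10

    def test_pc1_correlates_with_pseudotime(self):
        from sklearn.decomposition import PCA
        from scgraphae.metrics import kendall_tau
        taus = []
        for seed in range(5):
            cfg = TrajectorySimConfig(n_cells=200, n_genes=300,
                                      tree=((None, 0, 30),),
                                      program_drift_sd=0.3, seed=seed)
            m, pt, _ = simulate_trajectory(cfg)
            logx = np.log1p(m.values)
            pc1 = PCA(n_components=1).fit_transform(logx)[:, 0]
            taus.append(abs(kendall_tau(pc1, pt)))
        assert np.median(taus) >= 0.5

    def test_branch_ends_separable(self):
        cfg = TrajectorySimConfig(n_cells=300, n_genes=200,
                                  tree=((None, 0, 20), (0, 1, 20),
                                        (0, 2, 20)),
                                  program_drift_sd=0.4, seed=6)
        m, pt, branch = simulate_trajectory(cfg)
        assert set(branch) == {0, 1, 2}
        # cells near the tips of branches 1 and 2 differ in expression
        logx = np.log1p(m.values)
        tips1 = logx[(branch == 1) & (pt > 35)].mean(axis=0)
        tips2 = logx[(branch == 2) & (pt > 35)].mean(axis=0)
        within = logx[(branch == 1) & (pt > 35)].std(axis=0).mean()
        assert np.abs(tips1 - tips2).mean() > within

    def test_pseudotime_consistent_with_tree_depth(self):
        cfg = TrajectorySimConfig(n_cells=100, n_genes=50,
                                  tree=((None, 0, 10), (0, 1, 10)),
                                  seed=8)
        _, pt, branch = simulate_trajectory(cfg)
        assert pt[branch == 1].min() >= 10.0 - 1e-9

    def test_invalid_trees(self):
        with pytest.raises(ValueError):
            TrajectorySimConfig(tree=((None, 0, 10), (None, 1, 10)))
        with pytest.raises(ValueError):
            TrajectorySimConfig(tree=((5, 0, 10),))
        with pytest.raises(ValueError):
            TrajectorySimConfig(tree=((None, 0, 0),))


class TestScenarioPresets:
    def test_presets_return_expected_kinds(self):
        assert isinstance(scenario_config("scenario1"), TrajectorySimConfig)
        assert isinstance(scenario_config("scenario2"), TrajectorySimConfig)
        assert isinstance(scenario_config("scenario3"), ClusterSimConfig)
        cfg4 = scenario_config("scenario4")
        assert isinstance(cfg4, ClusterSimConfig)
        assert cfg4.dropout_shape == -1.0
        assert cfg4.n_cells == 2000 and cfg4.n_genes == 5000

    def test_scenario2_concentrates_at_branch_centers(self):
        cfg = scenario_config("scenario2", seed=1, n_cells=600, n_genes=30)
        _, pt, branch = simulate_trajectory(cfg)
        # center-peaked sampling: positions cluster around branch middles
        for b, (start, length) in {0: (0, 30), 1: (30, 30)}.items():
            pos = (pt[branch == b] - start) / length
            assert 0.1 < pos.mean() < 0.9
            assert pos.std() < 0.29  # uniform would be ~0.289; beta(3,3) ~0.19
        assert isinstance(cfg, TrajectorySimConfig)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            scenario_config("scenario9")
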