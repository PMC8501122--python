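import numpy as np
import pytest

from scgraphae import ClusterSimConfig, ModelConfig, simulate_clusters


@pytest.fixture(scope="session")
def four_cluster_data():
    """Well-separated 4-cluster counts (500 cells, 1000 genes) with truth."""
    cfg = ClusterSimConfig(n_cells=500, n_genes=1000, n_groups=4,
                           de_strength=1.0, seed=1)
    m, labels, _ = simulate_clusters(cfg)
    return m, labels


@pytest.fixture(scope="session")
def small_train_config():
    """Desk-scale training schedule used by the recovery tests."""
    return ModelConfig(latent_dim=10, pretrain_epochs=60, alter_iterations=8,
                       inner_epochs=3, loss_reduction="mean", seed=1,
                       dtype="float32")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
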