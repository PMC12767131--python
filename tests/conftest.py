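"""Shared fixtures: scaled-down simulator configuration and trained models.

The simulator fixtures run at a reduced problem size (256 elements, 24 mm
radius, 6x48x48 grids at 0.2 mm) that keeps the full physics — the same
transducer band, subsampling index formulas and reconstruction — while
staying fast enough for repeated use.  Expensive artifacts (datasets, the
trained restorer) are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import pactdiff as pd
from pactdiff.network import NetworkConfig, RestorationNetwork
from pactdiff.training import TrainConfig, train


@pytest.fixture(scope="session")
def sim_config():
    return pd.SimConfig(
        n_elements=256,
        radius=24.0,
        grid_shape=(6, 48, 48),
        voxel_spacing=0.2,
        n_branches=5,
    )


@pytest.fixture(scope="session")
def geometry(sim_config):
    return sim_config.build_geometry()


@pytest.fixture(scope="session")
def sparse_scheme():
    return pd.SubsampleScheme("sparse", 64)


@pytest.fixture(scope="session")
def cluster_scheme():
    return pd.SubsampleScheme("cluster", 32)


@pytest.fixture(scope="session")
def sparse_pairs_small(sim_config, geometry, sparse_scheme):
    """Four sparse pairs for lightweight dataset-consumer tests."""
    return pd.make_paired_dataset(4, sparse_scheme, sim_config, seed=0, geometry=geometry)


@pytest.fixture(scope="session")
def tiny_network_config():
    return NetworkConfig(
        base_channels=8, n_scales=2, kv_reduction=4, emb_dim=32, seed=1
    )


@pytest.fixture(scope="session")
def trained_sparse(sim_config, geometry, sparse_scheme, tiny_network_config):
    """A restorer trained on sparse pairs, with its train/test datasets.

    This is the package's scaled-down study condition: 30 training volumes,
    20 held-out volumes, 400 optimizer iterations on 32x32 crops.
    """
    train_ds = pd.make_paired_dataset(
        30, sparse_scheme, sim_config, seed=100, geometry=geometry
    )
    test_ds = pd.make_paired_dataset(
        20, sparse_scheme, sim_config, seed=900, geometry=geometry
    )
    net = RestorationNetwork(tiny_network_config)
    cfg = TrainConfig(iterations=400, input_size=32, seed=0)
    log = train(net, train_ds, cfg, log_every=10)
    return {
        "network": net,
        "train_config": cfg,
        "train_ds": train_ds,
        "test_ds": test_ds,
        "log": log,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
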