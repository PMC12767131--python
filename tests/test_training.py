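"""Two-stage losses, training determinism, checkpointing, transfer init."""

import numpy as np
import pytest

import pactdiff as pd
from pactdiff.degradation import GaborParams, alpha_schedule, build_operator
from pactdiff.network import NetworkConfig, RestorationNetwork
from pactdiff.nn import Tensor
from pactdiff.training import (
    TrainConfig,
    compute_losses,
    load_checkpoint,
    save_checkpoint,
    train,
    transfer_finetune,
)


class _OracleModel:
    """Stub restorer returning a fixed prediction (default: the true x0)."""

    def __init__(self, x0, offset=0.0, emb_dim=8):
        self.x0 = np.asarray(x0, dtype=np.float32)
        self.offset = offset
        self.emb_dim = emb_dim
        self.calls = 0

    def __call__(self, ctx, t, modulation=None):
        self.calls += 1
        return Tensor(self.x0[:, None] + self.offset)

    def embed_time(self, t, batch):
        return Tensor(np.zeros((batch, self.emb_dim), dtype=np.float32))

    def emm(self, x0_hat, xT, f):
        return f


@pytest.fixture(scope="module")
def ops():
    op = build_operator(GaborParams(), (16, 16))
    return op, alpha_schedule(2)


class TestComputeLosses:
    def test_perfect_prediction_zeroes_all_losses(self, ops, rng):
        op, sched = ops
        x0 = rng.random((2, 16, 16))
        xT = rng.random((2, 16, 16))
        model = _OracleModel(x0)
        _, bundle = compute_losses(x0, xT, (xT, xT), model, op, sched, t=2)
        assert bundle.stage_one < 1e-12
        assert bundle.error < 1e-12
        assert bundle.stage_two < 1e-12

    def test_total_is_exact_sum_of_components(self, ops, rng):
        op, sched = ops
        x0 = rng.random((1, 16, 16))
        xT = rng.random((1, 16, 16))
        model = _OracleModel(x0, offset=0.05)
        _, bundle = compute_losses(x0, xT, (xT, xT), model, op, sched, t=2)
        assert bundle.total == bundle.stage_one + bundle.stage_two + bundle.error

    def test_uniform_offset_mean_square(self, ops):
        op, sched = ops
        x0 = np.zeros((1, 16, 16))
        xT = np.zeros((1, 16, 16))
        model = _OracleModel(x0, offset=0.1)
        _, bundle = compute_losses(x0, xT, (xT, xT), model, op, sched, t=2)
        assert bundle.stage_one == pytest.approx(0.01, rel=1e-6)

    def test_first_step_rejected(self, ops):
        op, sched = ops
        z = np.zeros((1, 16, 16))
        with pytest.raises(ValueError):
            compute_losses(z, z, (z, z), _OracleModel(z), op, sched, t=1)


def _tiny_cfg(seed=0, iterations=25):
    return TrainConfig(iterations=iterations, input_size=32, seed=seed)


@pytest.fixture(scope="module")
def tiny_dataset(sim_config, geometry, sparse_scheme):
    return pd.make_paired_dataset(3, sparse_scheme, sim_config, seed=50,
                                  geometry=geometry)


class TestTrain:
    def test_seeded_run_reproduces_final_loss(self, tiny_dataset, tiny_network_config):
        logs = []
        for _ in range(2):
            net = RestorationNetwork(tiny_network_config)
            logs.append(train(net, tiny_dataset, _tiny_cfg()))
        assert logs[0][-1]["total"] == logs[1][-1]["total"]

    def test_empty_dataset_rejected(self, tiny_dataset, tiny_network_config):
        empty = pd.PairedDataset(pairs=[], scheme=tiny_dataset.scheme,
                                 config=tiny_dataset.config, seed=0)
        with pytest.raises(ValueError):
            train(RestorationNetwork(tiny_network_config), empty, _tiny_cfg())

    def test_checkpoint_resume_matches_uninterrupted_run(
        self, tiny_dataset, tiny_network_config, tmp_path
    ):
        ck = tmp_path / "state.npz"
        net_a = RestorationNetwork(tiny_network_config)
        log_a = train(net_a, tiny_dataset, _tiny_cfg(iterations=16))
        net_b = RestorationNetwork(tiny_network_config)
        train(net_b, tiny_dataset, _tiny_cfg(iterations=8),
              checkpoint_path=ck, checkpoint_every=8)
        net_c = RestorationNetwork(tiny_network_config)
        log_c = train(net_c, tiny_dataset, _tiny_cfg(iterations=16), resume=ck)
        assert log_a[-1]["total"] == pytest.approx(log_c[-1]["total"], rel=1e-6)
        for ka, pa in net_a.named_parameters().items():
            assert np.allclose(pa.data, net_c.named_parameters()[ka].data,
                               atol=1e-6)

    def test_gradients_finite_at_initialization(self, tiny_network_config, rng):
        op = build_operator(GaborParams(), (16, 16))
        sched = alpha_schedule(2)
        net = RestorationNetwork(tiny_network_config)
        for _ in range(100):
            x0 = rng.random((1, 16, 16))
            xT = rng.random((1, 16, 16))
            loss, _ = compute_losses(x0, xT, (xT, xT), net, op, sched, t=2)
            net.zero_grad()
            loss.backward()
            for p in net.parameters():
                if p.grad is not None:
                    assert np.all(np.isfinite(p.grad))


class TestCheckpointIO:
    def test_roundtrip_preserves_weights_and_config(
        self, tiny_network_config, tmp_path
    ):
        net = RestorationNetwork(tiny_network_config)
        sched = alpha_schedule(2)
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, sched, extra={"note": "test"})
        loaded, sched2, extra = load_checkpoint(path)
        assert sched2.T == 2
        assert extra["note"] == "test"
        assert loaded.cfg == net.cfg
        for k, p in net.named_parameters().items():
            assert np.array_equal(p.data, loaded.named_parameters()[k].data)
        sidecar = path.with_suffix(".npz.json")
        assert sidecar.exists()
        assert "config_sha256" in sidecar.read_text()

    def test_architecture_mismatch_rejected(self, tiny_network_config):
        net = RestorationNetwork(tiny_network_config)
        other = RestorationNetwork(NetworkConfig(base_channels=4, n_scales=2))
        with pytest.raises(ValueError):
            other.load_state_dict(net.state_dict())


class TestTransfer:
    def test_initializes_from_pretrained_weights(
        self, tiny_dataset, tiny_network_config
    ):
        pre = RestorationNetwork(tiny_network_config)
        pre.head.weight.data += 0.25  # make the source distinguishable
        model, log = transfer_finetune(pre, tiny_dataset, _tiny_cfg(), iterations=0)
        assert log == []
        for k, p in pre.named_parameters().items():
            assert np.array_equal(p.data, model.named_parameters()[k].data)

    def test_iteration_budget_honored(self, tiny_dataset, tiny_network_config):
        pre = RestorationNetwork(tiny_network_config)
        _, log = transfer_finetune(pre, tiny_dataset, _tiny_cfg(), iterations=7)
        assert log[-1]["iteration"] == 7
        assert len(log) == 7
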