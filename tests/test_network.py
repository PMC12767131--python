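"""Restoration network components: ECA, EHM attention, modulation, U-shape."""

import numpy as np
import pytest

from pactdiff.network import (
    ECA,
    EHMBlock,
    ErrorModulation,
    NetworkConfig,
    RestorationNetwork,
    eca,
    ehm_block,
    sinusoidal_embedding,
)
from pactdiff.nn import Tensor


class TestECA:
    def test_zero_weights_halve_features(self, rng):
        f = Tensor(rng.standard_normal((2, 6, 4, 4)))
        out = eca(f, Tensor(np.zeros(3)))
        assert np.allclose(out.data, 0.5 * f.data, atol=1e-7)

    def test_output_shape_preserved(self, rng):
        f = Tensor(rng.standard_normal((3, 5, 8, 8)))
        assert eca(f, Tensor(rng.standard_normal(3))).shape == f.shape

    def test_k1_gate_increases_with_channel_mean(self, rng):
        """With k=1 and positive weight, larger channel means get larger gates."""
        f = rng.standard_normal((1, 8, 6, 6))
        out = eca(Tensor(f), Tensor(np.array([2.0])))
        means = f.mean(axis=(2, 3))[0]
        gates = out.data[0, :, 0, 0] / f[0, :, 0, 0]
        order = np.argsort(means)
        assert np.all(np.diff(gates[order]) > 0)


class TestEHMBlock:
    def test_output_shape_matches_input(self, rng):
        cfg = NetworkConfig(base_channels=8, kv_reduction=2, ssm_state_size=4, seed=0)
        block = EHMBlock(8, cfg)
        f = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        assert block(f).shape == f.shape

    def test_indivisible_spatial_dims_rejected(self, rng):
        cfg = NetworkConfig(kv_reduction=4)
        block = EHMBlock(4, cfg)
        with pytest.raises(ValueError):
            block(Tensor(rng.standard_normal((1, 4, 6, 6)).astype(np.float32)))

    def test_attention_rows_are_normalized(self, rng):
        cfg = NetworkConfig(kv_reduction=2, use_ssm=False, seed=1)
        block = EHMBlock(4, cfg)
        f = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        fe = block.eca(f)
        q = block.q_proj(fe)
        k = block.k_proj(fe).avg_pool2d(2)
        B, C, H, W = f.shape
        q_seq = q.data.reshape(B, C, H * W).transpose(0, 2, 1)
        k_seq = k.data.reshape(B, C, 16).transpose(0, 2, 1)
        scores = (q_seq @ k_seq.transpose(0, 2, 1)) / block.attention_scale()
        p = np.exp(scores - scores.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        assert np.allclose(p.sum(-1), 1.0, atol=1e-6)

    def test_kv_reduction_shrinks_attention_map(self, rng):
        """Scores are (HW, HW/r^2): an r^2-fold reduction over full attention."""
        for r in (1, 2, 4):
            cfg = NetworkConfig(kv_reduction=r, use_ssm=False)
            H = W = 8
            hw_keys = (H // r) * (W // r)
            assert (H * W) * hw_keys == (H * W) ** 2 // r**2

    def test_degenerate_config_equals_plain_attention(self, rng):
        """r=1, identity projections, SSM bypassed: plain softmax attention."""
        C, H, W = 4, 6, 6
        cfg = NetworkConfig(kv_reduction=1, use_ssm=False,
                            attention_scale_mode="cbrt_C", seed=0)
        block = EHMBlock(C, cfg)
        eye = np.eye(C, dtype=np.float32).reshape(C, C, 1, 1)
        for proj in (block.q_proj, block.k_proj, block.v_proj, block.out_proj):
            proj.weight.data = eye.copy()
            proj.bias.data = np.zeros(C, dtype=np.float32)
        f = rng.standard_normal((1, C, H, W)).astype(np.float32)
        out = block(Tensor(f)).data
        # independent NumPy evaluation of the same degenerate block
        z = f.mean(axis=(2, 3))
        w = block.eca.weights.data
        pad = np.pad(z, ((0, 0), (1, 1)))
        gate = 1 / (1 + np.exp(-sum(w[j] * pad[:, j:j + C] for j in range(3))))
        fe = f * gate[:, :, None, None]
        seq = fe.reshape(1, C, H * W).transpose(0, 2, 1)
        scores = seq @ seq.transpose(0, 2, 1) / C ** (1 / 3)
        p = np.exp(scores - scores.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        attn = (p @ seq).transpose(0, 2, 1).reshape(1, C, H, W)
        assert np.allclose(out, f + attn, atol=1e-5)

    def test_functional_wrapper_runs(self, rng):
        cfg = NetworkConfig(kv_reduction=2, seed=3)
        f = rng.standard_normal((1, 6, 8, 8)).astype(np.float32)
        assert ehm_block(f, cfg).shape == (1, 6, 8, 8)


class TestErrorModulation:
    def test_identity_at_initialization(self, rng):
        emm = ErrorModulation(emb_dim=16)
        f = Tensor(rng.standard_normal((2, 16)).astype(np.float32))
        x0 = Tensor(rng.random((2, 1, 8, 8)).astype(np.float32))
        xT = Tensor(rng.random((2, 1, 8, 8)).astype(np.float32))
        out = emm(x0, xT, f)
        assert np.allclose(out.data, f.data, atol=1e-7)

    def test_factor_dimensionality(self, rng):
        emm = ErrorModulation(emb_dim=12)
        x = Tensor(rng.random((3, 1, 8, 8)).astype(np.float32))
        beta, gamma = emm.factors(x, x)
        assert beta.shape == (3, 12) and gamma.shape == (3, 12)

    def test_deterministic_given_fixed_weights(self, rng):
        emm = ErrorModulation(emb_dim=8)
        emm.conv2.weight.data = rng.standard_normal(
            emm.conv2.weight.shape
        ).astype(np.float32)
        f = Tensor(rng.standard_normal((1, 8)).astype(np.float32))
        x = Tensor(rng.random((1, 1, 6, 6)).astype(np.float32))
        a = emm(x, x, f).data
        b = emm(x, x, f).data
        assert np.array_equal(a, b)


class TestRestorationNetwork:
    def test_output_shape_and_channel_validation(self, tiny_network_config, rng):
        net = RestorationNetwork(tiny_network_config)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        assert net(x, t=2).shape == (2, 1, 32, 32)
        with pytest.raises(ValueError):
            net(rng.random((2, 2, 32, 32)).astype(np.float32), t=2)

    def test_forward_is_deterministic(self, tiny_network_config, rng):
        net = RestorationNetwork(tiny_network_config)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(net(x, t=2).data, net(x, t=2).data)

    def test_same_seed_same_init(self, tiny_network_config):
        a = RestorationNetwork(tiny_network_config)
        b = RestorationNetwork(tiny_network_config)
        for (ka, pa), (kb, pb) in zip(sorted(a.named_parameters().items()),
                                      sorted(b.named_parameters().items())):
            assert ka == kb and np.array_equal(pa.data, pb.data)

    def test_modulation_overrides_time_embedding(self, tiny_network_config, rng):
        net = RestorationNetwork(tiny_network_config)
        # the head is zero-initialized (identity network), so give it weight
        net.head.weight.data = 0.1 * rng.standard_normal(
            net.head.weight.shape
        ).astype(np.float32)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        base = net(x, t=1).data
        shifted = net(x, t=1, modulation=net.embed_time(1, 1) + 0.5).data
        assert not np.allclose(base, shifted)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(eca_kernel=4)
        with pytest.raises(ValueError):
            NetworkConfig(attention_scale_mode="linear")


def test_sinusoidal_embedding_is_smooth_and_bounded():
    e = sinusoidal_embedding([1, 2], 32)
    assert e.shape == (2, 32)
    assert np.all(np.abs(e) <= 1.0)
    assert not np.allclose(e[0], e[1])
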