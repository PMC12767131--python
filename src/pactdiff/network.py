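"""Restoration network: encoder-decoder with efficient hybrid attention blocks.

The network R_theta maps a 3-slice context stack (previous, current, next)
to an estimate of the clean center slice.  Encoder stages and the
bottleneck carry an EHM block: efficient channel attention gates the
channels, reduced-key/value self-attention (keys and values spatially
pooled by a factor r per axis, exploiting the low-rank structure of the
attention map) mixes space, and a selective state-space (Mamba-style)
layer refines the pooled key/value sequences.  A sinusoidal time embedding
passed through an MLP conditions every convolution block; at the second
sampling stage the embedding is feature-wise modulated (scale gamma, shift
beta) by a shallow network looking at the stage-one estimate and the
degraded endpoint, which realigns the embedding with the re-degraded input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import Conv2d, GroupNorm, Linear, Module, Parameter, Tensor, concat

__all__ = [
    "NetworkConfig",
    "sinusoidal_embedding",
    "eca",
    "ECA",
    "SelectiveSSM",
    "EHMBlock",
    "ehm_block",
    "ErrorModulation",
    "RestorationNetwork",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the restoration network.

    base_channels        : channels of the first encoder stage (doubled per scale).
    n_scales             : number of encoder scales (the last is the bottleneck).
    eca_kernel           : cross-channel 1D kernel size of the ECA gate (odd).
    kv_reduction         : spatial pooling factor r of keys/values per axis.
    ssm_state_size       : state dimension N of the selective SSM refiner.
    attention_scale_mode : "cbrt_C" (s = C^(1/3)) or "sqrt_C" (s = C^(1/2)).
    emb_dim              : time-embedding width (default 4 * base_channels).
    use_ssm              : disable to bypass the SSM refiner (diagnostics).
    """

    base_channels: int = 16
    n_scales: int = 3
    eca_kernel: int = 3
    kv_reduction: int = 2
    ssm_state_size: int = 8
    attention_scale_mode: str = "cbrt_C"
    emb_dim: int | None = None
    use_ssm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eca_kernel % 2 == 0:
            raise ValueError("eca_kernel must be odd")
        if self.kv_reduction < 1 or self.ssm_state_size < 1:
            raise ValueError("kv_reduction and ssm_state_size must be >= 1")
        if self.attention_scale_mode not in ("cbrt_C", "sqrt_C"):
            raise ValueError(f"unknown attention_scale_mode {self.attention_scale_mode!r}")

    @property
    def embedding_dim(self) -> int:
        return self.emb_dim if self.emb_dim is not None else 4 * self.base_channels

    def to_dict(self) -> dict:
        return asdict(self)


def sinusoidal_embedding(t, dim: int) -> np.ndarray:
    """Transformer-style sinusoidal position embedding of time step(s) t."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((t.shape[0], 1))], axis=1)
    return emb.astype(np.float32)


def eca(f: Tensor, weights: Tensor) -> Tensor:
    """Efficient channel attention: gate each channel of f (B,C,H,W).

    z = per-channel global average pool; the gate is
    omega_i = sigmoid(sum_j w_j z_{i+j}) — a zero-padded 1D convolution
    across the channel axis — and the output is omega_i * f_i.
    """
    B, C, H, W = f.shape
    k = weights.shape[0]
    pad = k // 2
    z = f.mean(axis=3).mean(axis=2)  # (B, C)
    zp = concat(
        [Tensor(np.zeros((B, pad), dtype=f.data.dtype)), z,
         Tensor(np.zeros((B, pad), dtype=f.data.dtype))],
        axis=1,
    )
    acc = None
    for j in range(k):
        term = zp[:, j : j + C] * weights[j : j + 1]
        acc = term if acc is None else acc + term
    omega = acc.sigmoid().reshape(B, C, 1, 1)
    return f * omega


class ECA(Module):
    def __init__(self, kernel: int = 3):
        self.weights = Parameter(np.zeros(kernel))

    def forward(self, f: Tensor) -> Tensor:
        return eca(f, self.weights)


class SelectiveSSM(Module):
    """Selective (input-dependent) diagonal state-space layer over a sequence.

    For input u of shape (B, L, D): per-step Delta (softplus-positive), B and
    C are linear projections of u; A is a learned negative-real diagonal
    (D, N).  Discretization is exact zero-order hold per diagonal entry:
    Abar = exp(Delta A), Bbar = (exp(Delta A) - 1)/A * B.  A learned skip
    D_skip * u is added to the scan output.
    """

    def __init__(self, d_model: int, state_size: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model
        self.state_size = state_size
        self.delta_proj = Linear(d_model, d_model, rng=rng)
        self.b_proj = Linear(d_model, state_size, rng=rng)
        self.c_proj = Linear(d_model, state_size, rng=rng)
        # A = -exp(A_log): negative-real diagonal dynamics, S4D-style init
        self.A_log = Parameter(
            np.tile(np.log(1.0 + np.arange(state_size, dtype=np.float32)[None, :] ),
                    (d_model, 1))
        )
        self.D_skip = Parameter(np.ones(d_model))
        self.delta_bias = Parameter(np.full(d_model, -2.0))  # softplus(-2) ~ 0.13

    def forward(self, u: Tensor) -> Tensor:
        from .nn import selective_scan

        A = -(self.A_log.exp())  # (D, N), strictly negative
        delta = (self.delta_proj(u) + self.delta_bias).softplus()  # (B, L, D)
        Bs = self.b_proj(u)  # (B, L, N)
        Cs = self.c_proj(u)  # (B, L, N)
        y = selective_scan(u, delta, A, Bs, Cs)
        return y + u * self.D_skip


class EHMBlock(Module):
    """Efficient hybrid attention block (ECA -> reduced-KV attention + SSM).

    Residual: output = f + proj(softmax(Q Khat^T / s) Vhat).  The output
    projection is zero-initialized so the block starts as the identity.
    """

    def __init__(self, channels: int, cfg: NetworkConfig,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.channels = channels
        self.eca = ECA(cfg.eca_kernel)
        self.q_proj = Conv2d(channels, channels, kernel=1, rng=rng)
        self.k_proj = Conv2d(channels, channels, kernel=1, rng=rng)
        self.v_proj = Conv2d(channels, channels, kernel=1, rng=rng)
        self.out_proj = Conv2d(channels, channels, kernel=1, rng=rng, zero_init=True)
        if cfg.use_ssm:
            self.ssm_k = SelectiveSSM(channels, cfg.ssm_state_size, rng=rng)
            self.ssm_v = SelectiveSSM(channels, cfg.ssm_state_size, rng=rng)

    def attention_scale(self) -> float:
        C = self.channels
        return C ** (1.0 / 3.0) if self.cfg.attention_scale_mode == "cbrt_C" else C**0.5

    def forward(self, f: Tensor) -> Tensor:
        B, C, H, W = f.shape
        r = self.cfg.kv_reduction
        if H % r or W % r:
            raise ValueError(f"spatial dims ({H},{W}) must divide kv_reduction {r}")
        fe = self.eca(f)
        q = self.q_proj(fe)
        k = self.k_proj(fe).avg_pool2d(r) if r > 1 else self.k_proj(fe)
        v = self.v_proj(fe).avg_pool2d(r) if r > 1 else self.v_proj(fe)
        hw = (H // r) * (W // r)
        q_seq = q.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, HW, C)
        k_seq = k.reshape(B, C, hw).transpose(0, 2, 1)  # (B, hw, C)
        v_seq = v.reshape(B, C, hw).transpose(0, 2, 1)
        if self.cfg.use_ssm:
            k_seq = self.ssm_k(k_seq)
            v_seq = self.ssm_v(v_seq)
        scores = (q_seq @ k_seq.transpose(0, 2, 1)) * (1.0 / self.attention_scale())
        attn = scores.softmax(axis=-1)  # rows sum to 1 over the hw keys
        mixed = attn @ v_seq  # (B, HW, C)
        mixed = mixed.transpose(0, 2, 1).reshape(B, C, H, W)
        return f + self.out_proj(mixed)


def ehm_block(f, cfg: NetworkConfig) -> Tensor:
    """Functional EHM block: builds a block (seeded by cfg) and applies it."""
    f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=np.float32))
    block = EHMBlock(f.shape[1], cfg)
    return block(f)


class ErrorModulation(Module):
    """Shallow network F_phi producing (beta, gamma) from (x0_hat, x_T).

    Two pointwise convolutions on the concatenated pair, global average
    pooling, and a zero-initialized head, so the modulation
    f~ = (1 + gamma_raw) * f + beta starts as the identity.
    """

    def __init__(self, emb_dim: int, hidden: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.emb_dim = emb_dim
        self.conv1 = Conv2d(2, hidden, kernel=1, rng=rng)
        self.conv2 = Conv2d(hidden, 2 * emb_dim, kernel=1, rng=rng, zero_init=True)

    def factors(self, x0_hat: Tensor, xT: Tensor):
        """Return (beta, gamma_raw), each (B, emb_dim)."""
        pair = concat([x0_hat, xT], axis=1)
        h = self.conv2(self.conv1(pair).silu())
        pooled = h.mean(axis=3).mean(axis=2)  # (B, 2E)
        E = self.emb_dim
        return pooled[:, :E], pooled[:, E:]

    def forward(self, x0_hat: Tensor, xT: Tensor, f_t: Tensor) -> Tensor:
        beta, gamma_raw = self.factors(x0_hat, xT)
        return (1.0 + gamma_raw) * f_t + beta


class _ConvBlock(Module):
    """Two 3x3 convolutions with group norm, SiLU, time bias and residual."""

    def __init__(self, c_in: int, c_out: int, emb_dim: int,
                 rng: np.random.Generator):
        self.norm1 = GroupNorm(c_in)
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.norm2 = GroupNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, rng=rng)
        self.time_bias = Linear(emb_dim, c_out, rng=rng)
        self.skip = Conv2d(c_in, c_out, kernel=1, rng=rng) if c_in != c_out else None

    def forward(self, x: Tensor, emb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x)).silu()
        B, C = h.shape[0], h.shape[1]
        h = h + self.time_bias(emb).reshape(B, C, 1, 1)
        h = self.conv2(self.norm2(h)).silu()
        return h + (self.skip(x) if self.skip is not None else x)


class RestorationNetwork(Module):
    """U-shaped restorer: EHM in encoder stages and bottleneck, plain decoder.

    Input is a 3-channel stack of adjacent slices; output is the restored
    center slice plus a global residual from the degraded center channel.
    """

    def __init__(self, cfg: NetworkConfig | None = None):
        cfg = cfg or NetworkConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        E = cfg.embedding_dim
        C = cfg.base_channels
        ns = cfg.n_scales
        self.time_mlp = [Linear(E, E, rng=rng), Linear(E, E, rng=rng)]
        self.stem = Conv2d(3, C, rng=rng)
        chans = [C * 2**s for s in range(ns)]
        self.enc_blocks = []
        self.enc_ehm = []
        for s in range(ns):
            c_in = chans[s - 1] if s > 0 else C
            self.enc_blocks.append(_ConvBlock(c_in, chans[s], E, rng))
            self.enc_ehm.append(EHMBlock(chans[s], cfg, rng=rng))
        self.dec_blocks = []
        for s in range(ns - 2, -1, -1):
            self.dec_blocks.append(_ConvBlock(chans[s + 1] + chans[s], chans[s], E, rng))
        self.head = Conv2d(chans[0], 1, rng=rng, zero_init=True)
        self.emm = ErrorModulation(E, rng=rng)

    def embed_time(self, t, batch: int) -> Tensor:
        """MLP(SinPE(t)) broadcast to the batch, shape (B, E)."""
        E = self.cfg.embedding_dim
        e = sinusoidal_embedding(t, E)
        if e.shape[0] == 1:
            e = np.repeat(e, batch, axis=0)
        h = Tensor(e)
        h = self.time_mlp[0](h).silu()
        return self.time_mlp[1](h)

    def forward(self, x_context, t: int, modulation: Tensor | None = None) -> Tensor:
        x = x_context if isinstance(x_context, Tensor) else Tensor(
            np.asarray(x_context, dtype=np.float32)
        )
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) context stack, got {x.shape}")
        B = x.shape[0]
        emb = modulation if modulation is not None else self.embed_time(t, B)
        h = self.stem(x)
        skips = []
        ns = self.cfg.n_scales
        for s in range(ns):
            h = self.enc_blocks[s](h, emb)
            h = self.enc_ehm[s](h)
            if s < ns - 1:
                skips.append(h)
                h = h.avg_pool2d(2)
        for d, s in enumerate(range(ns - 2, -1, -1)):
            h = h.upsample_nearest(2)
            h = concat([h, skips[s]], axis=1)
            h = self.dec_blocks[d](h, emb)
        out = self.head(h)
        return out + x[:, 1:2]
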