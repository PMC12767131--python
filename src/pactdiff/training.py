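"""Two-stage training of the restoration network.

Each iteration draws a batch of slice triplets, degrades the clean center
slice to x_t, and optimizes the sum of three losses: the stage-one
restoration error ||R(x_t^c, t) - x0||, the stage-two error after
re-degrading the stage-one estimate to x̂_{t-1} and restoring it with the
error-modulated embedding, and the forward-consistency error
||x̂_{t-1} - x_{t-1}||.  The re-degraded image entering stage two is
detached from the stage-one gradient path; the consistency loss still
trains stage one through the (self-adjoint) degradation operator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import PairedDataset
from .degradation import (
    DegradationOperator,
    DiffusionSchedule,
    GaborParams,
    alpha_schedule,
    build_operator,
    forward_degrade,
)
from .network import NetworkConfig, RestorationNetwork
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "LossBundle",
    "compute_losses",
    "train",
    "transfer_finetune",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale recipe)."""

    batch_size: int = 4
    lr: float = 2e-4
    adam_betas: tuple[float, float] = (0.9, 0.99)
    iterations: int = 125_000
    input_size: int = 128
    T: int = 2
    seed: int = 0
    loss_norm: str = "L2"
    gabor: GaborParams = field(default_factory=GaborParams)
    domain_mode: str = "frequency_mask"

    def __post_init__(self) -> None:
        if self.loss_norm not in ("L2", "L1"):
            raise ValueError(f"loss_norm must be L2 or L1, got {self.loss_norm!r}")
        if self.T < 2:
            raise ValueError("diffusion needs T >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        return d


@dataclass
class LossBundle:
    """The three loss terms and their sum for one batch."""

    stage_one: float
    stage_two: float
    error: float

    @property
    def total(self) -> float:
        return self.stage_one + self.stage_two + self.error


def _norm_loss(diff: Tensor, norm: str) -> Tensor:
    if norm == "L1":
        return ((diff**2 + 1e-12) ** 0.5).mean()
    return (diff**2).mean()


def _degrade_batch_tensor(
    x0_hat: Tensor, xT: np.ndarray, t: int, op: DegradationOperator,
    sched: DiffusionSchedule,
) -> Tensor:
    """Tensor-valued D(x̂0, xT, t), linear (self-adjoint G) in x̂0.

    x0_hat: (B, 1, H, W) Tensor; xT: (B, H, W) ndarray constant.
    """
    a = sched.alpha(t)
    B = x0_hat.shape[0]
    data = np.stack(
        [xT[b] + a * op.apply(x0_hat.data[b, 0] - xT[b]) for b in range(B)]
    )[:, None].astype(x0_hat.data.dtype)

    def backward(g):
        gx = np.stack([a * op.apply(g[b, 0]) for b in range(B)])[:, None]
        x0_hat._accum(gx.astype(x0_hat.data.dtype))

    out = Tensor(data)
    if x0_hat.requires_grad:
        out.requires_grad = True
        out._prev = (x0_hat,)
        out._backward = backward
    return out


def compute_losses(
    x0: np.ndarray,
    xT: np.ndarray,
    context: tuple[np.ndarray, np.ndarray],
    model: RestorationNetwork,
    op: DegradationOperator,
    sched: DiffusionSchedule,
    t: int,
    loss_norm: str = "L2",
):
    """Both training stages for one batch at step t (requires t >= 2).

    x0, xT            : (B, H, W) clean and degraded center slices.
    context           : (prev, next) degraded neighbor slices, (B, H, W) each.
    Returns ``(loss_tensor, LossBundle)``; backward on the tensor trains the
    network.
    """
    if t < 2:
        raise ValueError(f"stage two needs t >= 2 (got t={t})")
    x0 = np.asarray(x0, dtype=np.float32)
    xT = np.asarray(xT, dtype=np.float32)
    prev, nxt = (np.asarray(c, dtype=np.float32) for c in context)
    B = x0.shape[0]
    x_t = np.stack([forward_degrade(x0[b], xT[b], t, op, sched) for b in range(B)])
    x_t = x_t.astype(np.float32)
    x_tm1 = np.stack(
        [forward_degrade(x0[b], xT[b], t - 1, op, sched) for b in range(B)]
    ).astype(np.float32)

    ctx_t = np.stack([prev, x_t, nxt], axis=1)  # (B, 3, H, W)
    x0_hat = model(ctx_t, t)  # stage one
    f1 = _norm_loss(x0_hat - Tensor(x0[:, None]), loss_norm)

    # consistency of the re-degraded estimate with the true x_{t-1};
    # gradient reaches stage one through the linear operator
    x_tm1_hat = _degrade_batch_tensor(x0_hat, xT, t - 1, op, sched)
    f_err = _norm_loss(x_tm1_hat - Tensor(x_tm1[:, None]), loss_norm)

    # stage two sees the re-degraded input detached from stage one
    x0_hat_det = x0_hat.detach()
    x_tm1_det = x_tm1_hat.detach()
    ctx_tm1 = np.stack([prev, x_tm1_det.data[:, 0], nxt], axis=1)
    f_tm1 = model.embed_time(t - 1, B)
    modulated = model.emm(x0_hat_det, Tensor(xT[:, None]), f_tm1)
    x0_hat2 = model(ctx_tm1, t - 1, modulation=modulated)
    f2 = _norm_loss(x0_hat2 - Tensor(x0[:, None]), loss_norm)

    total = f1 + f2 + f_err
    bundle = LossBundle(
        stage_one=float(f1.data), stage_two=float(f2.data), error=float(f_err.data)
    )
    return total, bundle


def _slice_triplet(vol_full: np.ndarray, vol_deg: np.ndarray, k: int):
    """Center slices at k with edge-replicated degraded neighbors."""
    nz = vol_full.shape[0]
    km, kp = max(k - 1, 0), min(k + 1, nz - 1)
    return vol_full[k], vol_deg[k], vol_deg[km], vol_deg[kp]


def _sample_batch(dataset: PairedDataset, cfg: TrainConfig, rng: np.random.Generator):
    """Random (x0, xT, prev, next) crops of cfg.input_size from the dataset."""
    b = cfg.batch_size
    x0s, xTs, prevs, nxts = [], [], [], []
    for _ in range(b):
        pair = dataset[int(rng.integers(len(dataset)))]
        vf, vd = pair.full.voxels, pair.degraded.voxels
        k = int(rng.integers(vf.shape[0]))
        x0, xT, pv, nx = _slice_triplet(vf, vd, k)
        H, W = x0.shape
        ch = min(cfg.input_size, H)
        cw = min(cfg.input_size, W)
        i0 = int(rng.integers(H - ch + 1))
        j0 = int(rng.integers(W - cw + 1))
        sl = (slice(i0, i0 + ch), slice(j0, j0 + cw))
        x0s.append(x0[sl]); xTs.append(xT[sl]); prevs.append(pv[sl]); nxts.append(nx[sl])
    return (np.stack(x0s), np.stack(xTs), np.stack(prevs), np.stack(nxts))


def train(
    model: RestorationNetwork,
    dataset: PairedDataset,
    cfg: TrainConfig,
    log_every: int = 1,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int | None = None,
    resume: str | Path | None = None,
) -> list[dict]:
    """Train in place; returns the loss log (one dict per logged iteration)."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    sched = alpha_schedule(cfg.T)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas)
    rng = np.random.default_rng(cfg.seed)
    start = 0
    if resume is not None:
        payload = np.load(resume, allow_pickle=False)
        meta = json.loads(str(payload["__meta__"]))
        model.load_state_dict(
            {k[len("param."):]: payload[k] for k in payload.files if k.startswith("param.")}
        )
        opt.load_state_dict(
            {
                "t": meta["opt_t"],
                "m": [payload[f"opt_m.{i}"] for i in range(meta["n_params"])],
                "v": [payload[f"opt_v.{i}"] for i in range(meta["n_params"])],
            }
        )
        rng.bit_generator.state = meta["rng_state"]
        start = meta["iteration"]
    op_cache: dict[tuple[int, int], DegradationOperator] = {}
    log: list[dict] = []
    for it in range(start, cfg.iterations):
        x0, xT, prev, nxt = _sample_batch(dataset, cfg, rng)
        shape = x0.shape[1:]
        if shape not in op_cache:
            op_cache[shape] = build_operator(cfg.gabor, shape, cfg.domain_mode)
        op = op_cache[shape]
        t = int(rng.integers(2, cfg.T + 1))
        loss, bundle = compute_losses(
            x0, xT, (prev, nxt), model, op, sched, t, cfg.loss_norm
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (it + 1) % log_every == 0:
            log.append(
                {
                    "iteration": it + 1,
                    "stage_one": bundle.stage_one,
                    "stage_two": bundle.stage_two,
                    "error": bundle.error,
                    "total": bundle.total,
                }
            )
        if (
            checkpoint_path is not None
            and checkpoint_every
            and (it + 1) % checkpoint_every == 0
        ):
            _save_train_state(checkpoint_path, model, opt, rng, it + 1, cfg)
    return log


def _save_train_state(path, model, opt, rng, iteration, cfg) -> None:
    arrays = {f"param.{k}": v for k, v in model.state_dict().items()}
    ostate = opt.state_dict()
    for i, (m, v) in enumerate(zip(ostate["m"], ostate["v"])):
        arrays[f"opt_m.{i}"] = m
        arrays[f"opt_v.{i}"] = v
    meta = {
        "iteration": int(iteration),
        "opt_t": int(ostate["t"]),
        "n_params": len(ostate["m"]),
        "rng_state": rng.bit_generator.state,
        "train_config": cfg.to_dict(),
        "network_config": model.cfg.to_dict(),
    }
    arrays["__meta__"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def save_checkpoint(
    path: str | Path,
    model: RestorationNetwork,
    sched: DiffusionSchedule | None = None,
    extra: dict | None = None,
) -> None:
    """Single-file .npz archive (weights + configs) with a JSON sidecar.

    The sidecar repeats the configuration together with a SHA-256 hash of
    it, so checkpoints are identifiable without loading the arrays.
    """
    path = Path(path)
    arrays = {f"param.{k}": v for k, v in model.state_dict().items()}
    cfg_doc = {
        "network_config": model.cfg.to_dict(),
        "schedule": {"T": sched.T, "alphas": list(sched.alphas)} if sched else None,
        "extra": extra or {},
    }
    arrays["__config__"] = np.array(json.dumps(cfg_doc))
    np.savez(path, **arrays)
    digest = hashlib.sha256(
        json.dumps(cfg_doc, sort_keys=True).encode()
    ).hexdigest()
    sidecar = dict(cfg_doc, config_sha256=digest, format="pactdiff-checkpoint-v1")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path):
    """Rebuild (model, schedule, extra) from a checkpoint archive."""
    payload = np.load(path, allow_pickle=False)
    cfg_doc = json.loads(str(payload["__config__"]))
    model = RestorationNetwork(NetworkConfig(**cfg_doc["network_config"]))
    model.load_state_dict(
        {k[len("param."):]: payload[k] for k in payload.files if k.startswith("param.")}
    )
    sched = None
    if cfg_doc.get("schedule"):
        sched = alpha_schedule(cfg_doc["schedule"]["T"])
    return model, sched, cfg_doc.get("extra", {})


def transfer_finetune(
    pretrained: RestorationNetwork | str | Path,
    dataset: PairedDataset,
    cfg: TrainConfig | None = None,
    iterations: int = 9792,
) -> tuple[RestorationNetwork, list[dict]]:
    """Fine-tune a pretrained restorer on a new subsampling regime.

    All weights initialize from the pretrained model; hyperparameters match
    pretraining except the iteration budget (default 9792).
    """
    if isinstance(pretrained, (str, Path)):
        model, _, _ = load_checkpoint(pretrained)
    else:
        model = RestorationNetwork(pretrained.cfg)
        model.load_state_dict(pretrained.state_dict())
    cfg = cfg or TrainConfig()
    cfg = TrainConfig(**{**cfg.to_dict(), "iterations": iterations,
                         "gabor": cfg.gabor, "adam_betas": cfg.adam_betas})
    log = train(model, dataset, cfg)
    return model, log
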