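"""Model/Results front end over the training and inference machinery.

``DiffusionRestorationModel`` is built from paired data (or simulates it),
``fit()`` runs the two-stage optimization and returns a
``RestorationResults`` carrying the trained network, the loss trace and
evaluation helpers with a ``summary()`` table — the workflow mirrors the
fit/results split familiar from statistical modeling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import PairedDataset, SimConfig, make_paired_dataset
from .degradation import alpha_schedule, build_operator
from .inference import RestorationResult, restore_volume
from .metrics import psnr, ssim
from .network import NetworkConfig, RestorationNetwork
from .simulate import SubsampleScheme
from .training import TrainConfig, save_checkpoint, train
from .volume import VolumeImage

__all__ = ["DiffusionRestorationModel", "RestorationResults"]


class DiffusionRestorationModel:
    """Two-step diffusion restorer bound to a paired training dataset."""

    def __init__(
        self,
        dataset: PairedDataset,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        self.network_config = network_config or NetworkConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_simulation(
        cls,
        n_pairs: int,
        scheme: SubsampleScheme,
        sim_config: SimConfig | None = None,
        seed: int = 0,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "DiffusionRestorationModel":
        ds = make_paired_dataset(n_pairs, scheme, sim_config, seed=seed)
        return cls(ds, network_config, train_config)

    def fit(self, start_from: RestorationNetwork | None = None) -> "RestorationResults":
        """Train the restorer; optionally warm-start from a pretrained network."""
        net = RestorationNetwork(self.network_config)
        if start_from is not None:
            net.load_state_dict(start_from.state_dict())
        log = train(net, self.dataset, self.train_config)
        return RestorationResults(
            network=net,
            loss_log=log,
            train_config=self.train_config,
            scheme_name=self.dataset.scheme.name,
        )


@dataclass
class RestorationResults:
    """Fitted restorer: trained weights, loss trace, evaluation and IO."""

    network: RestorationNetwork
    loss_log: list[dict]
    train_config: TrainConfig
    scheme_name: str
    _op_cache: dict = field(default_factory=dict, repr=False)

    def _op_for(self, shape):
        if shape not in self._op_cache:
            self._op_cache[shape] = build_operator(
                self.train_config.gabor, shape, self.train_config.domain_mode
            )
        return self._op_cache[shape]

    def restore(self, volume: VolumeImage) -> RestorationResult:
        sched = alpha_schedule(self.train_config.T)
        return restore_volume(
            self.network, volume, self._op_for(volume.shape[1:]), sched
        )

    def evaluate(self, dataset: PairedDataset) -> dict:
        """PSNR/SSIM of restored vs full, with the degraded input as baseline."""
        rows = []
        for pair in dataset.pairs:
            res = self.restore(pair.degraded)
            rows.append(
                {
                    "psnr_degraded": psnr(pair.degraded.voxels, pair.full.voxels),
                    "psnr_restored": psnr(res.restored.voxels, pair.full.voxels),
                    "ssim_degraded": ssim(pair.degraded.voxels, pair.full.voxels),
                    "ssim_restored": ssim(res.restored.voxels, pair.full.voxels),
                }
            )
        out = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
        out["n_pairs"] = len(rows)
        out["per_pair"] = rows
        return out

    def summary(self, eval_dataset: PairedDataset | None = None) -> str:
        """Plain-text summary table of the fit (and optional evaluation)."""
        first = self.loss_log[0] if self.loss_log else {}
        last = self.loss_log[-1] if self.loss_log else {}
        n_params = sum(p.data.size for p in self.network.parameters())
        lines = [
            "Diffusion restoration results",
            "=" * 46,
            f"{'scheme':<28}{self.scheme_name:>18}",
            f"{'iterations':<28}{self.train_config.iterations:>18}",
            f"{'parameters':<28}{n_params:>18}",
            f"{'diffusion steps T':<28}{self.train_config.T:>18}",
            f"{'initial total loss':<28}{first.get('total', float('nan')):>18.5f}",
            f"{'final total loss':<28}{last.get('total', float('nan')):>18.5f}",
            f"{'final stage-one loss':<28}{last.get('stage_one', float('nan')):>18.5f}",
            f"{'final stage-two loss':<28}{last.get('stage_two', float('nan')):>18.5f}",
            f"{'final consistency loss':<28}{last.get('error', float('nan')):>18.5f}",
        ]
        if eval_dataset is not None:
            ev = self.evaluate(eval_dataset)
            lines += [
                "-" * 46,
                f"{'held-out pairs':<28}{ev['n_pairs']:>18}",
                f"{'PSNR degraded (dB)':<28}{ev['psnr_degraded']:>18.2f}",
                f"{'PSNR restored (dB)':<28}{ev['psnr_restored']:>18.2f}",
                f"{'SSIM degraded':<28}{ev['ssim_degraded']:>18.4f}",
                f"{'SSIM restored':<28}{ev['ssim_restored']:>18.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        save_checkpoint(
            path,
            self.network,
            alpha_schedule(self.train_config.T),
            extra={"scheme": self.scheme_name, "train_config": self.train_config.to_dict()},
        )
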