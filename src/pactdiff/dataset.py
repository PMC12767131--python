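"""Paired full/subsampled reconstruction datasets for training and testing.

Each pair starts from one simulated RF frame: the full-array reconstruction
is the clean target x0 and the subsampled-array reconstruction of the same
frame on the same grid is the degraded endpoint xT.  Both are normalized
jointly (one shared min-max scale per pair) so intensities stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .geometry import ArrayGeometry, build_hemisphere_geometry
from .phantom import generate_vascular_phantom
from .reconstruct import das_reconstruct
from .simulate import SubsampleScheme, select_elements, simulate_pa_rf
from .volume import VolumeImage, joint_minmax_normalize

__all__ = ["SimConfig", "VolumePair", "PairedDataset", "make_paired_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Simulator configuration.

    Defaults match the emulated acquisition: a 1024-element hemispherical
    array at 2.02 MHz center frequency and 54% fractional bandwidth, a
    12.8 mm cubic field of view, 1.5 mm/us speed of sound and 40 MHz
    sampling.  Radius and sampling constants are configurable; scaled-down
    configurations (fewer elements, smaller grids) keep the same physics.
    """

    n_elements: int = 1024
    radius: float = 60.0  # mm
    sampling_rate: float = 40e6  # Hz
    center_freq: float = 2.02e6  # Hz
    fractional_bandwidth: float = 0.54
    speed_of_sound: float = 1.5  # mm/us
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing: float = 0.1  # mm (12.8 mm FOV at the default grid)
    n_branches: int = 6

    def build_geometry(self) -> ArrayGeometry:
        return build_hemisphere_geometry(self.n_elements, self.radius)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VolumePair:
    """One aligned (clean, degraded) reconstruction pair in [0, 1]."""

    full: VolumeImage
    degraded: VolumeImage
    seed: int
    scheme_name: str

    def __post_init__(self) -> None:
        if self.full.shape != self.degraded.shape:
            raise ValueError("pair volumes must share one grid")


@dataclass
class PairedDataset:
    pairs: list[VolumePair]
    scheme: SubsampleScheme
    config: SimConfig
    seed: int
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> VolumePair:
        return self.pairs[i]


def make_paired_dataset(
    n_pairs: int,
    scheme: SubsampleScheme,
    config: SimConfig | None = None,
    seed: int = 0,
    geometry: ArrayGeometry | None = None,
) -> PairedDataset:
    """Simulate ``n_pairs`` phantoms and reconstruct each fully and subsampled.

    Pair i uses phantom seed ``seed + i``, so the dataset is bit-reproducible
    for a given (n_pairs, scheme, config, seed).
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    cfg = config or SimConfig()
    geom = geometry if geometry is not None else cfg.build_geometry()
    scheme.retained_indices(geom.n_elements)  # validate early
    grid = VolumeImage.centered(cfg.grid_shape, cfg.voxel_spacing)
    pairs = []
    for i in range(n_pairs):
        ph = generate_vascular_phantom(
            cfg.grid_shape,
            voxel_spacing=cfg.voxel_spacing,
            n_branches=cfg.n_branches,
            seed=seed + i,
        )
        frame = simulate_pa_rf(
            ph,
            geom,
            sampling_rate=cfg.sampling_rate,
            center_freq=cfg.center_freq,
            fractional_bandwidth=cfg.fractional_bandwidth,
            speed_of_sound=cfg.speed_of_sound,
        )
        rec_full = das_reconstruct(frame, geom, grid)
        rec_sub = das_reconstruct(select_elements(frame, geom, scheme), geom, grid)
        v_full, v_sub = joint_minmax_normalize(rec_full.voxels, rec_sub.voxels)
        pairs.append(
            VolumePair(
                full=grid.like(v_full),
                degraded=grid.like(v_sub),
                seed=seed + i,
                scheme_name=scheme.name,
            )
        )
    return PairedDataset(pairs=pairs, scheme=scheme, config=cfg, seed=seed)
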