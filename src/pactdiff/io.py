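"""Volume file IO: HDF5 (canonical), multi-page TIFF, NIfTI (read-only)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .volume import VolumeImage

__all__ = ["save_volume", "load_volume"]


def save_volume(path: str | Path, volume: VolumeImage) -> None:
    """Write a volume; format chosen by suffix (.h5/.hdf5 or .tif/.tiff).

    HDF5 layout: dataset ``/volume`` with attrs ``spacing_mm`` (dz, dy, dx)
    and ``origin_mm`` (x, y, z).  TIFF stores slices as pages with the grid
    metadata JSON-encoded in the image description.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("volume", data=volume.voxels)
            d.attrs["spacing_mm"] = np.asarray(volume.voxel_spacing)
            d.attrs["origin_mm"] = np.asarray(volume.origin)
    elif suffix in (".tif", ".tiff"):
        meta = {"spacing_mm": list(volume.voxel_spacing), "origin_mm": list(volume.origin)}
        tifffile.imwrite(
            path,
            volume.voxels.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        raise ValueError(f"unsupported output format {suffix!r}")


def load_volume(path: str | Path) -> VolumeImage:
    """Read a volume from HDF5, TIFF, or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            d = f["volume"]
            spacing = tuple(d.attrs.get("spacing_mm", (1.0, 1.0, 1.0)))
            origin = tuple(d.attrs.get("origin_mm", (0.0, 0.0, 0.0)))
            return VolumeImage(d[...], spacing, origin)
    if name.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        return VolumeImage(
            data,
            tuple(meta.get("spacing_mm", (1.0, 1.0, 1.0))),
            tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
        )
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return VolumeImage(np.asarray(img.dataobj, dtype=float), tuple(zooms))
    raise ValueError(f"unrecognized volume format: {path.name}")
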