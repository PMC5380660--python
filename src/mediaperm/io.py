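"""TIFF + JSON-sidecar I/O for image volumes and binary masks.

Volumes are written as multi-page TIFF stacks, one page per slice along
the depth axis, with voxel spacing and axis metadata in a JSON sidecar
(`<file>.json`). Masks are 8-bit (0/255).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import BinaryMicrostructure, ImageVolume


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(vol: ImageVolume, path) -> None:
    path = Path(path)
    pages = np.moveaxis(vol.intensity.astype(np.float32), vol.depth_axis, 0)
    tifffile.imwrite(path, pages)
    meta = {"voxel_spacing_um": list(vol.voxel_spacing),
            "depth_axis": vol.depth_axis,
            "axes": list(vol.axes),
            "kind": "intensity"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_volume(path) -> ImageVolume:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path)
    data = np.moveaxis(pages, 0, meta["depth_axis"])
    return ImageVolume(np.asarray(data, dtype=float),
                       tuple(meta["voxel_spacing_um"]),
                       depth_axis=int(meta["depth_axis"]),
                       axes=tuple(meta["axes"]))


def save_mask(micro: BinaryMicrostructure, path, depth_axis: int = 2) -> None:
    path = Path(path)
    pages = np.moveaxis(np.where(micro.mask, 255, 0).astype(np.uint8),
                        depth_axis, 0)
    tifffile.imwrite(path, pages)
    meta = {"voxel_spacing_um": list(micro.voxel_spacing),
            "depth_axis": depth_axis,
            "axes": list(micro.axes),
            "kind": "mask"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_mask(path) -> BinaryMicrostructure:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    pages = tifffile.imread(path)
    data = np.moveaxis(pages, 0, meta["depth_axis"])
    return BinaryMicrostructure(data > 0, tuple(meta["voxel_spacing_um"]),
                                axes=tuple(meta["axes"]))
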