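"""Shared containers for medial microstructure and image volumes.

Arrays are indexed (r, z, theta) unless the ``axes`` labels say otherwise:
axis 0 is the radial (transmural) direction, axis 1 the longitudinal axis of
the vessel and axis 2 the circumferential direction. Voxel spacing is in
micrometres per voxel along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_LABELS = ("r", "z", "theta")

_ALIASES = {"r": "r", "z": "z", "theta": "theta", "t": "theta", "θ": "theta"}


def axis_index(label: str, axes: tuple[str, ...] = AXIS_LABELS) -> int:
    """Map an axis label ('r', 'z', 'theta'/'θ') to its array axis."""
    canon = _ALIASES.get(label)
    if canon is None or canon not in axes:
        raise ValueError(f"unknown axis label {label!r}; expected one of {axes}")
    return axes.index(canon)


@dataclass
class BinaryMicrostructure:
    """3D two-phase medial geometry: True = ECM pore space, False = SMC/fibre."""

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if sorted(self.axes) != sorted(AXIS_LABELS):
            raise ValueError(f"axes must be a permutation of {AXIS_LABELS}")

    @property
    def phi_ecm(self) -> float:
        """ECM volume fraction by exact voxel counting."""
        return float(np.count_nonzero(self.mask)) / self.mask.size

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return float(np.prod(self.voxel_spacing))


@dataclass
class ImageVolume:
    """3D scalar intensity grid emulating (or holding) a confocal stack."""

    intensity: np.ndarray
    voxel_spacing: tuple[float, float, float]
    depth_axis: int = 2
    axes: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.depth_axis not in (0, 1, 2):
            raise ValueError("depth_axis must be 0, 1 or 2")
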