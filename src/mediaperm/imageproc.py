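"""Confocal-stack processing for the arterial media.

Covers the image-analysis steps between acquisition and flow simulation:
depth-attenuation correction, rotation of the imaging axes onto the
cylindrical (r, z, theta) coordinates of the vessel, intensity thresholding
into ECM vs SMC/fibre compartments, ECM volume-fraction and volumetric
strain, medial thickness, and per-slice watershed segmentation of smooth
muscle cells with aspect-ratio statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import BinaryMicrostructure, ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "EcmFractionResult",
    "SegmentationResult",
    "MedialGeometry",
    "correct_attenuation",
    "rotate_to_cylindrical",
    "threshold_volume",
    "compute_ecm_fraction",
    "segment_smcs",
    "measure_medial_thickness",
]

N_AR_BINS = 50  # fixed histogram binning of aspect ratios over [0, 1]


@dataclass
class EcmFractionResult:
    """ECM volume fraction phi = V_ECM / V of a medial block, with the
    volumetric strain J = phi / phi_baseline when a baseline is supplied."""

    phi_ecm: float
    v_ecm: float  # um^3
    v_total: float  # um^3
    threshold_used: float | None = None
    j_strain: float | None = None


@dataclass
class SegmentationResult:
    """Per-slice watershed segmentation of SMCs with aspect-ratio stats."""

    labels: list[np.ndarray]
    cells: list[dict]
    histogram: np.ndarray  # counts, 50 bins over AR in [0, 1]
    bin_edges: np.ndarray
    median_ar: float


@dataclass
class MedialGeometry:
    thickness_um: float
    method: str


def _slice_means(intensity: np.ndarray, depth_axis: int) -> np.ndarray:
    other = tuple(i for i in range(3) if i != depth_axis)
    return intensity.mean(axis=other)


def correct_attenuation(vol: ImageVolume, model: str = "per-slice-mean") -> ImageVolume:
    """Undo intensity attenuation with imaging depth.

    'per-slice-mean' rescales every depth slice to the mean of the
    shallowest slice (no optics model assumed); 'exponential' fits a single
    exponential decay to the per-slice means and divides it out. Both leave
    the depth profile of per-slice means flat (slope ~ 0).
    """
    means = _slice_means(vol.intensity, vol.depth_axis)
    if np.any(means == 0):
        raise ValueError("attenuation correction undefined: volume contains "
                         "an all-zero (or zero-mean) depth slice")
    depth = np.arange(means.size) * vol.voxel_spacing[vol.depth_axis]

    if model == "per-slice-mean":
        gain = means[0] / means
    elif model == "exponential":
        if np.any(means <= 0):
            raise ValueError("exponential model requires positive slice means")
        slope, intercept = np.polyfit(depth, np.log(means), 1)
        gain = np.exp(-(slope * depth))  # normalised to unity at depth 0
    else:
        raise ValueError("model must be 'per-slice-mean' or 'exponential'")

    shape = [1, 1, 1]
    shape[vol.depth_axis] = -1
    corrected = vol.intensity * gain.reshape(shape)
    return ImageVolume(corrected, vol.voxel_spacing,
                       depth_axis=vol.depth_axis, axes=vol.axes)


def _rot90_steps(angle: float) -> int | None:
    """Number of quarter turns if angle is an exact multiple of 90 deg."""
    k = angle / 90.0
    return int(round(k)) % 4 if np.isclose(k, round(k)) else None


def rotate_to_cylindrical(vol: ImageVolume,
                          angles: tuple[float, float, float],
                          order: int = 1) -> ImageVolume:
    """Apply three successive in-plane rotations aligning the imaging axes
    with the cylindrical (r, z, theta) coordinates of the vessel.

    angles[i] rotates about array axis i, i.e. within the plane of the
    other two axes. Multiples of 90 degrees are applied lattice-exactly
    (pure index permutation/flip); other angles use spline interpolation of
    the given order. Output axes are relabelled (r, z, theta).
    """
    if not all(np.isfinite(a) for a in angles):
        raise ValueError("rotation angles must be finite")
    out = vol.intensity
    planes = [(1, 2), (0, 2), (0, 1)]
    for axis, angle in enumerate(angles):
        if angle == 0:
            continue
        plane = planes[axis]
        k = _rot90_steps(angle)
        if k is not None:
            # scipy's positive in-plane angle matches np.rot90 from the
            # second plane axis toward the first
            out = np.rot90(out, k=k, axes=plane[::-1])
        else:
            out = ndi.rotate(out, angle, axes=plane, reshape=False,
                             order=order, mode="constant", cval=0.0)
    return ImageVolume(out, vol.voxel_spacing, depth_axis=vol.depth_axis)


def threshold_volume(vol: ImageVolume, method: str = "otsu",
                     value: float | None = None) -> BinaryMicrostructure:
    """Split the volume into tracer-bright ECM (True) and dark SMC/fibre
    (False) compartments by intensity thresholding."""
    inten = vol.intensity
    lo, hi = float(inten.min()), float(inten.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant volume: no intensity "
                         "contrast between compartments")
    if method == "otsu":
        thr = float(threshold_otsu(inten))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        if not lo <= value <= hi:
            raise ValueError(f"threshold {value} outside intensity range "
                             f"[{lo}, {hi}]")
        thr = float(value)
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    micro = BinaryMicrostructure(inten > thr, vol.voxel_spacing, axes=vol.axes)
    micro.threshold_used = thr
    return micro


def compute_ecm_fraction(micro: BinaryMicrostructure,
                         baseline_phi: float | None = None) -> EcmFractionResult:
    """ECM volume fraction by exact voxel counting; optionally the
    volumetric strain J relative to a baseline fraction."""
    if micro.mask.size == 0:
        raise ValueError("empty mask")
    n_true = int(np.count_nonzero(micro.mask))
    vv = micro.voxel_volume
    phi = n_true / micro.mask.size
    j = None
    if baseline_phi is not None:
        if baseline_phi <= 0:
            raise ValueError("baseline phi must be positive")
        j = phi / baseline_phi
    return EcmFractionResult(
        phi_ecm=phi,
        v_ecm=n_true * vv,
        v_total=micro.mask.size * vv,
        threshold_used=getattr(micro, "threshold_used", None),
        j_strain=j,
    )


def _segment_slice(cell_phase: np.ndarray, spacing: tuple[float, float],
                   min_distance_px: int, smooth_px: float = 1.0) -> np.ndarray:
    """Watershed split of touching cells in one binary slice.

    The distance of every cell pixel to the nearest ECM pixel is computed;
    inverted, the cells appear as basins separated by ridges, and flooding
    from the distance maxima partitions apparently-connected cells.
    Markers are local maxima of the (lightly smoothed, to suppress
    voxelisation bumps) distance transform with a minimum separation of
    half the expected cell minor axis."""
    distance = ndi.distance_transform_edt(cell_phase, sampling=spacing)
    smoothed = ndi.gaussian_filter(distance, smooth_px)
    peaks = peak_local_max(smoothed, min_distance=min_distance_px,
                           labels=cell_phase, exclude_border=False)
    markers = np.zeros(cell_phase.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-distance, markers, mask=cell_phase)


def segment_smcs(micro: BinaryMicrostructure,
                 expected_minor_um: float = 5.0,
                 min_area_um2: float = 4.0,
                 slice_axis: int = 2) -> SegmentationResult:
    """Per-slice SMC segmentation and aspect-ratio statistics.

    Slices are taken in the r-z plane (one per theta index by default).
    In each slice the cell phase (mask == False) is partitioned by
    watershed on the inverted distance transform; each labelled region is
    measured by its second-moment equivalent ellipse, and the aspect ratio
    AR = minor diameter / major diameter is histogrammed into 50 bins over
    [0, 1]. Regions touching the slice border or smaller than the area
    floor are excluded (censored diameters).
    """
    sp = [micro.voxel_spacing[i] for i in range(3) if i != slice_axis]
    min_sep_px = max(1, int(round(expected_minor_um / 2.0 / min(sp))))
    labels_out: list[np.ndarray] = []
    cells: list[dict] = []

    n_slices = micro.mask.shape[slice_axis]
    for k in range(n_slices):
        sl = np.take(micro.mask, k, axis=slice_axis)
        cell_phase = ~sl
        if not cell_phase.any():
            logger.info("slice %d has no cell phase; contributing zero cells", k)
            labels_out.append(np.zeros(sl.shape, dtype=int))
            continue
        labels = _segment_slice(cell_phase, tuple(sp), min_sep_px)
        labels_out.append(labels)
        h, w = labels.shape
        for rp in regionprops(labels, spacing=tuple(sp)):
            rmin, cmin, rmax, cmax = rp.bbox
            if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
                continue  # censored at the slice border
            if rp.area < min_area_um2:
                continue
            major = rp.axis_major_length
            minor = rp.axis_minor_length
            if major <= 0:
                continue
            ar = min(minor / major, 1.0)
            if ar <= 0:
                continue
            cells.append({"slice_index": k, "label": int(rp.label),
                          "minor_um": float(minor), "major_um": float(major),
                          "aspect_ratio": float(ar)})

    ars = np.array([c["aspect_ratio"] for c in cells])
    hist, edges = np.histogram(ars, bins=N_AR_BINS, range=(0.0, 1.0))
    # AR = 1.0 falls in the last bin (histogram's closed right edge)
    median = float(np.median(ars)) if ars.size else float("nan")
    return SegmentationResult(labels=labels_out, cells=cells,
                              histogram=hist, bin_edges=edges,
                              median_ar=median)


def measure_medial_thickness(tissue, voxel_spacing=None,
                             background_fraction: float = 0.1) -> MedialGeometry:
    """Medial thickness as the mean radial extent of tissue signal.

    Accepts a boolean tissue-presence mask (3D, radial axis first), a
    BinaryMicrostructure-like object, or an ImageVolume (thresholded at
    background_fraction of its maximum). For every (z, theta) column the
    extent from the first to the last tissue voxel along r is measured;
    the thickness is the mean over columns containing tissue. Fails if
    half or more of the columns carry no signal.
    """
    if isinstance(tissue, ImageVolume):
        arr = tissue.intensity > background_fraction * tissue.intensity.max()
        spacing = tissue.voxel_spacing
    elif isinstance(tissue, BinaryMicrostructure):
        arr = tissue.mask
        spacing = tissue.voxel_spacing
    else:
        arr = np.asarray(tissue, dtype=bool)
        if voxel_spacing is None:
            raise ValueError("voxel_spacing required for a bare mask")
        spacing = voxel_spacing
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")

    any_tissue = arr.any(axis=0)
    n_cols = any_tissue.size
    n_hit = int(np.count_nonzero(any_tissue))
    if n_hit <= n_cols // 2:
        raise ValueError(f"no tissue signal in {n_cols - n_hit}/{n_cols} "
                         "columns; cannot measure thickness")

    nr = arr.shape[0]
    first = np.argmax(arr, axis=0)
    last = nr - 1 - np.argmax(arr[::-1], axis=0)
    extent = (last - first + 1) * spacing[0]
    thickness = float(extent[any_tissue].mean())
    return MedialGeometry(thickness_um=thickness,
                          method="mean radial extent over (z, theta) columns")
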