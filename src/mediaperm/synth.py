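"""Synthetic medial microstructures and emulated confocal volumes.

The arterial tunica media is modelled as fusiform (spindle-shaped) smooth
muscle cells embedded in extracellular matrix (ECM). Cells are tapered
ellipsoids whose long axes lie in the z-theta plane at a helical pitch
angle; vasoconstriction shortens the long axis, widens the transverse axes
and flattens cells radially, while the medial ECM dilates. The generator
packs cells sequentially (overlap allowed, so cells can touch) and adjusts
the cell count greedily until the ECM volume fraction lands within +/-0.02
of the requested target.

Two presets ship with the package: ``baseline`` (phi_ECM 0.60) and
``constricted`` (derived from baseline by :func:`apply_contraction`,
phi_ECM 0.68). Preset cell dimensions and helix angle are calibration —
plausible rat-aorta SMC geometry chosen to reproduce the documented volume
fractions and per-slice aspect-ratio medians — not measured ground truth.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage as ndi

from .core import AXIS_LABELS, BinaryMicrostructure, ImageVolume

__all__ = [
    "SynthParams",
    "ContractionScales",
    "ConfocalEmulationParams",
    "generate_microstructure",
    "apply_contraction",
    "render_confocal",
    "load_presets",
    "preset_params",
    "make_medial_slab",
]

PHI_TOLERANCE = 0.02  # accepted half-width of the achieved-fraction band

# taper exponent q: transverse radius scales as (1-s^2)^q along the long
# axis; q=0.5 is an ellipsoid, q=0.75 gives the tapered fusiform profile
TAPER_EXPONENT = 0.75


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic medial block.

    grid_shape / voxel_spacing are ordered (r, z, theta); cell_semi_axes is
    (long axis, radial transverse, in-plane transverse) in micrometres.
    helix_angle is the angle (degrees) of the cell long axis from the z axis
    within the z-theta plane. radial_flattening <= 1 additionally scales the
    radial semi-axis (constriction flattens cells radially).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.25, 1.25, 1.25)
    target_phi_ecm: float = 0.60
    cell_semi_axes: tuple[float, float, float] = (24.0, 2.6, 2.6)
    helix_angle: float = 29.0
    radial_flattening: float = 1.0
    placement_jitter: float = 3.0
    seed: int = 0
    periodic: bool = False

    def validate(self) -> None:
        if not 0.0 < self.target_phi_ecm < 1.0:
            raise ValueError("target_phi_ecm must lie strictly in (0, 1)")
        if any(a <= 0 for a in self.cell_semi_axes):
            raise ValueError("all cell semi-axes must be positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if not 0.0 < self.radial_flattening <= 1.0:
            raise ValueError("radial_flattening must lie in (0, 1]")
        if self.placement_jitter < 0:
            raise ValueError("placement_jitter must be nonnegative")


@dataclass(frozen=True)
class ContractionScales:
    """Shape transform of SMC contraction: shorten along the long axis,
    widen transversely, flatten radially; the media thickens by
    thickness_scale, diluting the solid phase."""

    long_axis_scale: float = 0.8
    transverse_scale: float = 1.224
    radial_flattening: float = 0.80
    thickness_scale: float = 33.2 / 27.7

    def validate(self) -> None:
        for name in ("long_axis_scale", "transverse_scale",
                     "radial_flattening", "thickness_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.long_axis_scale < 1.0 <= self.transverse_scale:
            # identity transform (all ones) is explicitly allowed
            if not (self.long_axis_scale == self.transverse_scale
                    == self.radial_flattening == self.thickness_scale == 1.0):
                raise ValueError(
                    "contraction requires long_axis_scale < 1 <= transverse_scale")

    @property
    def cell_volume_factor(self) -> float:
        return (self.long_axis_scale * self.transverse_scale ** 2
                * self.radial_flattening)


@dataclass(frozen=True)
class ConfocalEmulationParams:
    """Acquisition model for rendering a mask as a confocal-like stack:
    tracer-filled ECM is bright, cells dark; intensity decays exponentially
    with imaging depth; a Gaussian blur stands in for the point-spread
    function; additive Gaussian (optionally signal-dependent) noise."""

    attenuation_length: float = 60.0  # um
    noise_sd: float = 10.0
    blur_sigma: float = 0.6  # um
    ecm_intensity: float = 200.0
    cell_intensity: float = 60.0
    seed: int = 0
    depth_axis: int = 2
    noise_model: str = "gaussian"  # or "poisson-like"

    def validate(self) -> None:
        if not self.attenuation_length > 0:
            raise ValueError("attenuation_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be nonnegative")
        if not self.ecm_intensity > self.cell_intensity:
            raise ValueError("ecm_intensity must exceed cell_intensity "
                             "(tracer fills the ECM)")
        if self.noise_model not in ("gaussian", "poisson-like"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson-like'")


def _cell_frame(helix_angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal cell frame: long axis d in the z-theta plane at the helix
    angle from z; e_r radial; e_t the in-plane transverse direction."""
    a = np.deg2rad(helix_angle_deg)
    d = np.array([0.0, np.cos(a), np.sin(a)])
    e_r = np.array([1.0, 0.0, 0.0])
    e_t = np.array([0.0, -np.sin(a), np.cos(a)])
    return d, e_r, e_t


def _cell_voxels(params: SynthParams, center: np.ndarray,
                 semi_axes: tuple[float, float, float]) -> tuple[np.ndarray, ...]:
    """Voxel indices (r, z, t arrays) inside one fusiform cell at `center`
    (um). Clipped at grid faces, or wrapped if params.periodic."""
    shape = np.asarray(params.grid_shape)
    sp = np.asarray(params.voxel_spacing, dtype=float)
    a, br, bt = semi_axes
    d, e_r, e_t = _cell_frame(params.helix_angle)

    # conservative per-axis half-extent of the (untapered) ellipsoid
    half = np.sqrt((a * d) ** 2 + (br * e_r) ** 2 + (bt * e_t) ** 2)
    lo = np.floor((center - half) / sp).astype(int)
    hi = np.ceil((center + half) / sp).astype(int) + 1
    if not params.periodic:
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(hi <= lo):
            return (np.empty(0, int),) * 3

    idx = [np.arange(lo[i], hi[i]) for i in range(3)]
    coords = [(ix + 0.5) * sp[i] - center[i] for i, ix in enumerate(idx)]
    dr, dz, dt = np.meshgrid(*coords, indexing="ij", sparse=True)

    xi = dz * d[1] + dt * d[2]          # along the long axis
    eta = dr                            # radial offset (e_r = r-hat)
    zeta = dz * e_t[1] + dt * e_t[2]    # in-plane transverse offset

    s2 = (xi / a) ** 2
    profile = np.where(s2 < 1.0, (1.0 - np.minimum(s2, 1.0)) ** (2 * TAPER_EXPONENT), 0.0)
    inside = (eta / br) ** 2 + (zeta / bt) ** 2 <= profile
    rr, zz, tt = np.nonzero(inside)
    rr, zz, tt = rr + lo[0], zz + lo[1], tt + lo[2]
    if params.periodic:
        rr, zz, tt = rr % shape[0], zz % shape[1], tt % shape[2]
        if np.any(hi - lo > shape):
            # cell wider than the box: wrapped indices may collide
            flat = np.unique(np.ravel_multi_index((rr, zz, tt), tuple(shape)))
            rr, zz, tt = np.unravel_index(flat, tuple(shape))
    return rr, zz, tt


def _effective_semi_axes(params: SynthParams) -> tuple[float, float, float]:
    a, br, bt = params.cell_semi_axes
    return a, br * params.radial_flattening, bt


def _candidate_centers(params: SynthParams, n_needed: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice candidate cell centres (um), shuffled. Layers are
    stacked along r at roughly one flattened cell diameter, emulating the
    lamellar organisation of the media."""
    box = np.asarray(params.grid_shape) * np.asarray(params.voxel_spacing)
    _, br, _ = _effective_semi_axes(params)
    n_r = max(1, int(round(box[0] / (2.4 * br))))
    per_layer = max(1, -(-n_needed // n_r))
    n_z = max(1, int(np.ceil(np.sqrt(per_layer * box[1] / box[2]))))
    n_t = max(1, -(-per_layer // n_z))
    grids = [
        (np.arange(n) + 0.5) * L / n
        for n, L in zip((n_r, n_z, n_t), box)
    ]
    centers = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = centers + rng.normal(0.0, params.placement_jitter, centers.shape)
    centers %= box  # keep centres inside the block
    rng.shuffle(centers)
    return centers


def _fusiform_volume(semi_axes: tuple[float, float, float]) -> float:
    """Closed-form volume of the tapered cell, um^3 (integral of the
    elliptical cross-section along the axis)."""
    from scipy.special import beta

    a, br, bt = semi_axes
    # int_{-1}^{1} (1-s^2)^{2q} ds = B(1/2, 2q+1)
    integral = beta(0.5, 2 * TAPER_EXPONENT + 1)
    return float(np.pi * br * bt * a * integral)


def generate_microstructure(params: SynthParams) -> BinaryMicrostructure:
    """Pack fusiform cells into an all-ECM block until the ECM volume
    fraction is within the tolerance band of ``target_phi_ecm``.

    Deterministic: identical params (including seed) give a bit-identical
    mask. Raises ValueError if the target fraction is unreachable with the
    given cell size (each candidate either overshoots the band or the
    candidate supply is exhausted).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ecm = np.ones(params.grid_shape, dtype=bool)
    n_vox = ecm.size
    target = params.target_phi_ecm

    phi = 1.0
    if phi - target <= PHI_TOLERANCE:
        # target close enough to 1: the empty-inclusion block already passes
        return BinaryMicrostructure(ecm, params.voxel_spacing)

    semi = _effective_semi_axes(params)
    box_volume = float(np.prod(np.asarray(params.grid_shape)
                               * np.asarray(params.voxel_spacing)))
    n_needed = int(np.ceil(3.5 * (1 - target) * box_volume
                           / _fusiform_volume(semi)))
    centers = _candidate_centers(params, n_needed, rng)

    true_count = n_vox
    i = 0
    while phi > target:
        if i >= len(centers):
            raise ValueError(
                f"target phi_ecm={target} unreachable: candidate cells "
                f"exhausted at phi={phi:.4f} (cells too large or too few "
                "candidate positions for this grid)")
        voxels = _cell_voxels(params, centers[i], semi)
        i += 1
        if voxels[0].size == 0:
            continue
        sel = ecm[voxels]
        delta = int(np.count_nonzero(sel))
        new_phi = (true_count - delta) / n_vox
        if new_phi < target - PHI_TOLERANCE:
            continue  # this cell would overshoot the band; try the next one
        ecm[voxels] = False
        true_count -= delta
        phi = new_phi

    assert abs(phi - target) <= PHI_TOLERANCE
    return BinaryMicrostructure(ecm, params.voxel_spacing)


def apply_contraction(base: SynthParams,
                      contraction: ContractionScales | None = None) -> SynthParams:
    """Derive constricted-state parameters from a baseline parameter set.

    Cell shape: long axis shortened, transverse axes widened, radial axis
    flattened. The ECM target fraction follows from conservation of cell
    material in a thickening media: the solid fraction scales by the cell
    volume factor divided by the thickness scale,

        1 - phi_c = (1 - phi_b) * (ls * ts^2 * rf) / th,

    so ECM dilates (phi rises) when the media thickens faster than the
    cells swell. Identity scales return parameters equal to the baseline.
    """
    base.validate()
    if contraction is None:
        contraction = ContractionScales()
    contraction.validate()

    solid_factor = contraction.cell_volume_factor / contraction.thickness_scale
    phi_new = 1.0 - (1.0 - base.target_phi_ecm) * solid_factor
    if not 0.0 < phi_new < 1.0:
        raise ValueError(
            f"contraction scales drive phi_ecm to {phi_new:.3f}, outside (0, 1)")

    a, br, bt = base.cell_semi_axes
    return dataclasses.replace(
        base,
        target_phi_ecm=phi_new,
        cell_semi_axes=(a * contraction.long_axis_scale,
                        br * contraction.transverse_scale,
                        bt * contraction.transverse_scale),
        radial_flattening=base.radial_flattening * contraction.radial_flattening,
    )


def render_confocal(micro: BinaryMicrostructure,
                    emu: ConfocalEmulationParams) -> ImageVolume:
    """Render a binary microstructure as an emulated confocal stack:
    phase intensities, exponential depth attenuation, PSF blur, noise."""
    emu.validate()
    rng = np.random.default_rng(emu.seed)
    img = np.where(micro.mask, emu.ecm_intensity, emu.cell_intensity).astype(float)

    depth = (np.arange(micro.mask.shape[emu.depth_axis])
             * micro.voxel_spacing[emu.depth_axis])
    atten = np.exp(-depth / emu.attenuation_length)
    shape = [1, 1, 1]
    shape[emu.depth_axis] = -1
    img *= atten.reshape(shape)

    if emu.blur_sigma > 0:
        sigma_vox = [emu.blur_sigma / s for s in micro.voxel_spacing]
        img = ndi.gaussian_filter(img, sigma=sigma_vox)

    if emu.noise_sd > 0:
        if emu.noise_model == "gaussian":
            img = img + rng.normal(0.0, emu.noise_sd, img.shape)
        else:  # Poisson-like: sd grows with the square root of the signal
            scale = np.sqrt(np.maximum(img, 0.0) / emu.ecm_intensity)
            img = img + rng.normal(0.0, 1.0, img.shape) * emu.noise_sd * scale

    return ImageVolume(img, micro.voxel_spacing, depth_axis=emu.depth_axis)


# ---------------------------------------------------------------------------
# presets

def load_presets() -> dict:
    """Load the versioned preset configuration shipped with the package."""
    text = (importlib.resources.files("mediaperm") / "data" / "presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_params(name: str, seed: int = 0, *, periodic: bool = False,
                  grid_shape: tuple[int, int, int] | None = None) -> SynthParams:
    """Build SynthParams for a named preset ('baseline' or 'constricted').

    The constricted preset is derived from baseline via apply_contraction
    with the preset contraction scales, so its target fraction comes from
    the conservation rule rather than a hard-coded number.
    """
    cfg = load_presets()
    base_cfg = cfg["baseline"]
    base = SynthParams(
        grid_shape=tuple(base_cfg["grid_shape"]),
        voxel_spacing=tuple(base_cfg["voxel_spacing"]),
        target_phi_ecm=float(base_cfg["target_phi_ecm"]),
        cell_semi_axes=tuple(base_cfg["cell_semi_axes"]),
        helix_angle=float(base_cfg["helix_angle"]),
        radial_flattening=float(base_cfg["radial_flattening"]),
        placement_jitter=float(base_cfg["placement_jitter"]),
        seed=seed,
        periodic=periodic,
    )
    if grid_shape is not None:
        # keep the physical block size fixed: coarser grids get larger voxels
        spacing = tuple(s * n0 / n for s, n0, n in
                        zip(base.voxel_spacing, base.grid_shape, grid_shape))
        base = dataclasses.replace(base, grid_shape=tuple(grid_shape),
                                   voxel_spacing=spacing)
    if name == "baseline":
        return base
    if name == "constricted":
        c = cfg["contraction"]
        scales = ContractionScales(
            long_axis_scale=float(c["long_axis_scale"]),
            transverse_scale=float(c["transverse_scale"]),
            radial_flattening=float(c["radial_flattening"]),
            thickness_scale=float(c["thickness_scale"]),
        )
        return apply_contraction(base, scales)
    raise ValueError(f"unknown preset {name!r}; expected 'baseline' or 'constricted'")


def preset_thickness(name: str) -> float:
    """Documented medial thickness (um) associated with a preset."""
    cfg = load_presets()
    if name == "baseline":
        return float(cfg["baseline"]["medial_thickness_um"])
    if name == "constricted":
        return (float(cfg["baseline"]["medial_thickness_um"])
                * float(cfg["contraction"]["thickness_scale"]))
    raise ValueError(f"unknown preset {name!r}")


def make_medial_slab(thickness_um: float,
                     grid_shape: tuple[int, int, int] = (64, 48, 48),
                     voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     ripple_amplitude_um: float = 0.0,
                     ripple_period_vox: int = 16) -> np.ndarray:
    """Tissue-presence mask of a medial slab of given thickness along r,
    centred in the grid, with an optional sinusoidal surface ripple.

    Used as a fixture for medial-thickness measurement; the flow-simulation
    blocks themselves are fully tissue-filled medial interiors.
    """
    if thickness_um <= 0:
        raise ValueError("thickness must be positive")
    nr, nz, nt = grid_shape
    sp_r = voxel_spacing[0]
    r = (np.arange(nr) + 0.5) * sp_r
    z = np.arange(nz)
    t = np.arange(nt)
    zz, tt = np.meshgrid(z, t, indexing="ij")
    ripple = ripple_amplitude_um * np.sin(2 * np.pi * zz / ripple_period_vox)
    mid = nr * sp_r / 2.0
    lower = mid - thickness_um / 2.0 + ripple
    upper = mid + thickness_um / 2.0 + ripple
    mask = (r[:, None, None] > lower[None]) & (r[:, None, None] <= upper[None])
    return mask
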