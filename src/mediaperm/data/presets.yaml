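# Versioned preset configuration for synthetic medial microstructures.
#
# Documented targets: ECM volume fraction 0.60 (baseline) / 0.68
# (constricted), medial thickness 27.7 / 33.2 um, per-slice aspect-ratio
# medians ~0.52 / ~0.42. Cell semi-axes and helix angle are calibration
# (plausible rat-aorta SMC geometry reproducing those targets), not
# measured ground truth.
version: 1

baseline:
  grid_shape: [64, 64, 64]
  voxel_spacing: [1.25, 1.25, 1.25]   # um per voxel (r, z, theta)
  target_phi_ecm: 0.60
  cell_semi_axes: [24.0, 2.6, 2.6]    # um: long, radial, in-plane transverse
  helix_angle: 29.0                   # degrees from z within the z-theta plane
  radial_flattening: 1.0
  placement_jitter: 3.0               # um, Gaussian jitter on lattice centres
  medial_thickness_um: 27.7

# Default constriction transform (applied to baseline to derive the
# constricted preset). Cells shorten along the long axis, widen
# transversely, flatten radially; the media thickens by thickness_scale.
# The constricted target phi follows from conservation:
#   1 - phi_c = (1 - phi_b) * ls * ts^2 * rf / th  ->  phi_c ~ 0.68
contraction:
  long_axis_scale: 0.80
  transverse_scale: 1.224
  radial_flattening: 0.80
  thickness_scale: 1.19856            # 33.2 / 27.7

# Reference aspect-ratio medians for direction checks (calibration targets)
ar_medians:
  baseline: 0.5232
  constricted: 0.4163
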