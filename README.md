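# mediaperm

Hydraulic permeability of the arterial media, from microstructure to
wall-resistance budget.

The tunica media — smooth muscle cells (SMCs) embedded in extracellular
matrix (ECM) — dominates water transport across large-artery walls, and
changes in its microstructure (for instance under vasoconstriction) change
where the wall's hydraulic resistance sits. `mediaperm` implements the
computational half of a combined experimental/numerical workflow for
studying this:

1. **Microstructure** — seeded synthetic 3D medial blocks of fusiform,
   helically oriented SMCs in ECM, with presets for a relaxed (*baseline*,
   ECM volume fraction φ_ECM ≈ 0.60) and a vasoconstricted (*constricted*,
   φ_ECM ≈ 0.68) state, plus an emulated confocal renderer (depth
   attenuation, PSF blur, noise) so the whole image-processing chain is
   testable without microscope data.
2. **Image processing** — attenuation correction, rotation onto cylindrical
   (r, z, θ) vessel coordinates, Otsu/fixed thresholding into ECM vs cell
   compartments, exact voxel-count volume fractions φ_ECM = V_ECM/V and
   volumetric strain J = φ/φ_B, medial thickness, and per-slice watershed
   segmentation of SMCs with aspect-ratio (minor/major) histograms.
3. **Flow** — steady Brinkman flow, μ∇²u − (μ/k(x))u − ∇p + f = 0 with
   ∇·u = 0, on the voxel grid; impermeable cells are handled by a penalty
   (k drops by 10⁶ inside cells) so flow goes around them. Periodic
   homogenisation cell with the macroscopic gradient as a body force.
4. **Homogenisation** — volume averages ⟨u⟩, ⟨∇p⟩ from three directional
   solves feed Darcy's law ⟨u⟩ = (k/μ)⟨∇p⟩; the symmetric permeability
   tensor k is fit by least squares (9 equations, 6 unknowns) and
   diagonalised into principal permeabilities K11 (radial), K12, K13
   (transverse).
5. **Resistance** — with measured hydraulic conductance Lp and medial
   thickness T: R_WALL = 1/Lp, R_MED = μT/K11, R_INT = R_WALL − R_MED
   (layers in series), plus group statistics (mean ± SEM, paired/unpaired
   t-tests) and a ±20% k_ECM sensitivity sweep.

## Worked example

One command runs the whole chain on synthetic specimens (3 per condition,
seeded, ~90 s on one core):

```bash
mediaperm demo --out demo_out --seed 1
```

prints

```
baseline: phi=0.599 K11=2.839e-19 m^2 T=26.7 um
constricted: phi=0.679 K11=4.019e-19 m^2 T=32.0 um
manifest e6627859ead9 -> demo_out
```

Reading this: the baseline group's synthetic blocks measured φ_ECM ≈ 0.60
and homogenised to a radial permeability K11 ≈ 0.28 × 10⁻¹⁸ m² (about a
fifth of the ECM's intrinsic k_ECM = 1.32 × 10⁻¹⁸ m² — the cells obstruct
most radial paths). Constriction dilates the ECM (φ → 0.68) and raises K11
by ~40%, while the media thickens ~20%. `demo_out/` then contains
`results.csv` (per specimen), `decomposition.csv` (R_WALL/R_MED/R_INT per
specimen: the medial fraction of wall resistance falls from ~0.59 to ~0.33
and intimal resistance rises ~2.4-fold with the packaged demo Lp values),
`summary.json` (group statistics), `sensitivity.csv` (k_ECM sweep) and
`manifest.json` (config hash + seeds; reruns are bit-identical).

Every stage is also a library call (`generate_microstructure`,
`render_confocal`, `correct_attenuation`, `threshold_volume`,
`segment_smcs`, `BrinkmanSolver.solve`, `solve_permeability_tensor`,
`decompose_resistance`, ...) and a CLI subcommand (`mediaperm synth
generate`, `mediaperm brinkman solve --mask ...`, `mediaperm homogenize
fit`, `mediaperm resistance decompose --specimens file.csv`, `mediaperm
run --config run.yaml`).

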