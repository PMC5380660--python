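# Methods

`mediaperm` models water transport through the arterial tunica media — smooth
muscle cells (SMCs) embedded in extracellular matrix (ECM) — and decomposes
whole-wall hydraulic resistance into medial and intimal parts. This note
documents the models, the synthetic data they are exercised on, the numerical
choices, and their limits.

## Synthetic medial microstructure

Real medial geometry comes from confocal stacks of a tracer that fills the
ECM but is excluded from SMCs and impervious fibres. No such volumes ship
with this package; the `synth` module generates substitutes with the
structural features that matter for flow:

- **Cell shape.** Fusiform (spindle) cells are tapered ellipsoids: in cell
  coordinates a point is inside when
  `(eta/b_r)^2 + (zeta/b_t)^2 <= (1 - (xi/a)^2)^(2q)` with taper exponent
  `q = 0.75` (an ellipsoid at `q = 0.5`, a sharp spindle as `q -> 1`).
  Baseline semi-axes are 24 x 2.6 x 2.6 um — SMC-scale dimensions.
- **Orientation.** Long axes lie in the z–theta plane at a helical pitch
  angle (29 degrees from z); medial SMCs are helically, not
  circumferentially, arranged.
- **Packing.** Cells are placed sequentially on a jittered lattice (layers
  stacked radially, emulating lamellae). Overlap is allowed so cells touch —
  deliberately, so watershed splitting has realistic work to do. Cells are
  added until the measured ECM fraction is within +/-0.02 of the target;
  candidates that would overshoot the band are skipped.
- **Presets.** `baseline` targets phi_ECM = 0.60. `constricted` is *derived*
  from baseline by the contraction transform: long axis x0.80, transverse
  axes x1.224, radial axis additionally x0.80, medial thickness x1.1986.
  The constricted ECM target follows from conservation of cell material in
  a thickening media, `1 - phi_c = (1 - phi_b) * ls * ts^2 * rf / th`, which
  yields 0.68.
- **Calibration, not ground truth.** Cell dimensions, helix angle and
  contraction scales were calibrated once so that the presets reproduce the
  documented volume fractions (0.60 / 0.68), thickness ratio (~1.2) and
  per-slice aspect-ratio medians (~0.52 / ~0.42-0.44). They should not be
  read as measured SMC geometry.

The confocal emulator renders a mask as `intensity = phase mean x
exp(-depth / L)` (default attenuation length 60 um along theta, the
imaging-depth axis), blurs with an isotropic Gaussian PSF stand-in
(sigma 0.6 um) and adds Gaussian noise (sd 10 at an ECM/cell contrast of
200/60); a signal-dependent Poisson-like noise mode is available. What the
emulator does *not* model: anisotropic PSFs, photobleaching, fibre texture
inside the "cell" phase, registration error between blocks. Passing the
round-trip tests therefore shows the processing chain is self-consistent on
idealised stacks, not that it is robust to every real-world artefact.

## Image processing

- **Attenuation correction** (default `per-slice-mean`) rescales each depth
  slice to the shallowest slice's mean — it reproduces the required outcome
  (depth-flat intensity) with no optics assumptions. An `exponential` mode
  fits a single decay to the per-slice means instead.
- **Rotation to cylindrical axes** applies three in-plane rotations; exact
  multiples of 90 degrees are index permutations (lattice-exact), other
  angles use spline interpolation of configurable order.
- **Thresholding** defaults to Otsu with a manual (`fixed`) override. The
  ~2% inter-observer sensitivity of manual thresholding becomes an automated
  check: +/-5% threshold shifts must move phi_ECM by <= 0.03.
- **phi_ECM** is exact voxel counting (`phi = V_ECM / V`); the volumetric
  strain is `J = phi / phi_baseline`. No tolerance is applied: counting is
  integer arithmetic.
- **SMC segmentation** works per r–z slice. The cell phase's Euclidean
  distance transform is inverted so cells are basins; markers are distance
  maxima with minimum separation of half the expected cell minor axis
  (5 um default), found on a 1-px-smoothed distance map (the smoothing
  suppresses voxelisation bumps that would otherwise over-split elongated
  fusiform cross-sections). Aspect ratio is the second-moment equivalent
  ellipse's minor/major diameter; cells touching slice borders or below a
  4 um^2 floor are censored. Histograms use 50 fixed bins over [0, 1].
- **Medial thickness** is the mean radial extent of tissue signal over all
  (z, theta) columns; it errors when half or more of the columns carry no
  signal.

## Brinkman flow and homogenisation

Interstitial flow obeys the Brinkman momentum balance
`mu lap(u) - (mu/k(x)) u - grad p + f = 0` with `div u = 0`, where
`k = k_ECM` (default 1.32e-18 m^2, a literature mean for arterial ECM) in
the pore phase and `k_ECM / penalty_ratio` (default 1e6) inside cells — the
penalty makes flow go around, not through, the solid phase. The macroscopic
gradient G enters as a body force under fully periodic boundary conditions
(standard homogenisation practice); a `fixed-pressure-faces` mode (pressure
drop across the driven faces, impermeable lateral walls) is the alternative.

Discretisation is a cell-centred finite volume for pressure with face-normal
(MAC) velocities and harmonic-mean face mobilities. Key numerical choices:

- **Drag-dominated splitting.** At micrometre voxels,
  `mu lap(u) ~ (k_ECM/h^2) * drag ~ 1e-6 * drag`, so the viscous term is
  treated by Picard lagging: each sweep solves one variable-coefficient
  Poisson problem `div(lambda (G + mu lap u_prev - grad p)) = 0` and the
  iteration contracts with ratio ~ k_ECM/h^2 (2–3 sweeps to machine level).
- **One factorisation per microstructure.** The pressure operator depends
  only on the geometry; it is LU-factorised once (SuperLU, MMD_AT_PLUS_A
  ordering — ~3.5x faster than the default on this operator) and reused for
  all three gradient directions and all Picard sweeps. The constant
  pressure nullspace is pinned at one cell; the discrete system is
  compatible, so the dropped continuity row is satisfied automatically
  (verified: relative divergence <= 1e-9 is enforced on every solution).
- **Validity envelope.** Grid convergence (<5% coarse-vs-2x), penalty
  convergence (<1% from 1e6 to 1e8), linearity, flux monotonicity under
  added inclusions and r–z swap symmetry are all asserted in the suite.
  The analytic all-ECM limit reproduces `u = k_ECM G / mu` to 1e-6.

Volume averages `<u>` (whole-cell mean, solids included where u ~ 0) and
`<grad p>` = G from three directional solves feed Darcy's law
`<u> = (k/mu) <grad p>` parameterised by the six components of the
symmetric permeability tensor: 9 equations, 6 unknowns, solved by least
squares (symmetry by parameterisation, not post-hoc). Diagonalisation gives
principal permeabilities; K11 is the eigenvalue whose eigenvector is most
radial (ties break toward the smaller eigenvalue), K12 >= K13 the
transverse pair. Internally everything is SI (m^2, Pa, dynamic viscosity
mu = 6.913e-4 Pa s, water at 37 C; the kinematic form nu = mu/rho with
rho = 993 kg m^-3 is available where pressure arrives in kinematic units).

On synthetic blocks K11 ~ 0.2 k_ECM at phi = 0.60 and rises steeply with
phi; transverse permeabilities exceed the radial one by ~2x because the
helical cells obstruct radial paths most. Published per-block permeability
tables in this problem domain print values without units whose magnitude
(4–7) exceeds k_ECM on the 1e-18 m^2 scale; since an effective permeability
cannot exceed the matrix permeability with impermeable inclusions, such
values are plausibly on the 1e-19 m^2 scale. This package reports tensor
components in m^2 and leaves unit interpretation of external tables to the
user.

## Resistance decomposition and statistics

Wall layers act in series: `R_WALL = 1/Lp`, `R_MED = mu T / K11`,
`R_INT = R_WALL - R_MED` (additivity holds by construction). A negative
R_INT means the computed medial resistance exceeds the measured whole-wall
resistance — physically inconsistent inputs; it is reported with a warning,
never clamped, so bad input combinations stay visible. Hydraulic
conductance Lp is an experimental input the simulations cannot produce; the
packaged `demo_lp.csv` / `demo_specimens.csv` values are synthetic,
labelled as such, and chosen to be internally consistent with the
permeability scale they are paired with.

Group summaries report mean +/- SEM (n-1 sample SD) and two-sided t-tests —
paired when specimen identities match across conditions, classical unpaired
otherwise (Welch available via `equal_var=False`; on the packaged
permeability table both variants give p << 1e-6).

The k_ECM sensitivity sweep scales K11 proportionally with k_ECM (the
Brinkman problem is linear in k_ECM at fixed geometry up to penalty
effects; a full re-solve on a test fixture matches the proportional rule
within 2%) and reports group-mean medial/intimal fractions for scalings
{0.8, 1.0, 1.2}.

## Pipeline and problem sizes

`run_pipeline` chains: generate (periodic preset block) -> render confocal
-> correct attenuation -> Otsu threshold -> measure phi -> solve flow in
r, z, theta -> fit tensor -> measure slab thickness (preset group mean with
~5% seeded per-specimen variability) -> attach Lp -> decompose resistance
-> group statistics and sensitivity. All randomness flows from named
per-specimen seeds; the manifest records the configuration hash, seeds,
results hash and library versions, and reruns are bit-identical. Specimens
are processed independently, so results do not depend on processing order.

Default problem sizes are chosen for desk-scale runs: presets generate
64^3 voxel blocks (80 um cubes at 1.25 um voxels) for geometry statistics,
while flow solves run on 32^3 re-voxelisations of the same physical block
(the all-ECM Darcy limit is grid-independent, and obstacle cases converge
within 5% between successive refinements at these sizes). A full demo
(3 + 3 specimens) takes about a minute and a half on one core.

## Known limitations

- Cells are convex tapered ellipsoids; real SMCs branch and interdigitate.
- No elastin/collagen fibre architecture: impervious fibres are absorbed
  into the cell phase, exactly as intensity thresholding of tracer images
  does.
- Segmentation is per-slice (2D), matching the aspect-ratio analysis it
  supports; no volumetric cell reconstruction.
- The fixed-pressure flow mode omits the (negligible at these scales)
  viscous correction; the periodic mode retains it.
- k_ECM is treated as condition-independent; the sensitivity sweep brackets
  that assumption rather than removing it.
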