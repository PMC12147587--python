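# Methods

## Model and assumptions

The package computes the electric field delivered by a focal ablation
electrode during pulsed-field ablation under the quasi-static
approximation: the biphasic pulse train (tens of microseconds per phase) is
reduced to a single elliptic solve at the printed **peak voltage**, because
at these frequencies tissue behaves resistively and the lesion-forming
quantity in threshold models is the peak field magnitude. Waveform
dynamics, electrode–tissue mechanics, Joule heating, and fibre-direction
anisotropy are outside the model; conductivity is isotropic per tissue.

The governing equation is the nonlinear potential problem

    div( sigma(x, |grad phi|) grad phi ) = 0,

Dirichlet `phi = V` on the electrode–tissue contact, `phi = 0` on the
dispersive patch, zero-flux elsewhere. Electroporation is represented by a
field-dependent myocardial conductivity: a monotone sigmoid from the
baseline `sigma0` to `sigma_factor * sigma0` as the local magnitude rises
from `E_low` to `E_high`. Blood, torso bulk and patch tissue are
field-independent. The IRE lesion at lethal threshold `T` is the set of
myocardial cells with `|E| >= T`; thresholds are swept over 200–1000 V/cm.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| electrode diameter | 8/3 ≈ 2.667 | mm | 8F catheter, French scale 1 Fr = 1/3 mm |
| tip length | 3.5 | mm | focal ablation tip; flush perpendicular contact |
| wall thickness | 10 (LV-like); 3–3.7 (RV-like) | mm | nontransmural vs transmural regimes |
| blood pool depth | 30 | mm | ventricular cavity beneath the wall |
| torso block | 160 × 120 × 80 | mm | large enough that the far field only adds series resistance; fits the patch |
| patch footprint | 150 × 90 | mm | dispersive return electrode |
| sigma0 myocardium / blood / torso | 0.20 / 0.70 / 0.20 | S/m | literature-typical low-frequency values; configuration, not constants |
| sigma_factor | 2.5 | – | electroporated/baseline conductivity ratio |
| E_low, E_high | 400, 800 | V/cm | onset and saturation of the conductivity rise (smoothed-Heaviside; a logistic variant is provided) |
| applied voltage | 1000, 2000 | V | peak pulse voltages studied |
| thresholds | 200–1000 step 10 | V/cm | lethal-threshold sweep grid |
| picard_tolerance | 1e-4 | – | max relative cell-conductivity change at the fixed point |
| linear_solver_tolerance | 1e-8 | – | CG relative residual (first iteration is a direct factorization) |

The sigmoid parameters are deliberately decoupled from the lethal-threshold
sweep: the threshold is a post-processing dial, the sigmoid is physics of
the forward solve.

## Discretization and solver

Tensor-product grids with graded spacing: uniform cells in a fine box
around the electrode and through the wall, geometric coarsening (ratio 1.3,
oracle 1.4) out to the boundaries. The production slab grid uses 0.35 mm
through-wall resolution, 0.5 mm laterally with the fine span ±10 mm along
the width-measurement axis and ±(electrode radius + 2.5) mm transversely —
about 156k nodes. These sizes were chosen so that the lesion boundary at
typical thresholds stays inside the uniformly-fine region while a full
two-voltage sweep remains a desk-scale computation; they are stated here so
any reported number can be tied to its resolution.

The scheme is vertex-centred finite volumes: each cell adds
`sigma * (transverse area / 4) / length` to its twelve edge conductances.
The operator is symmetric positive definite on free nodes with nonpositive
off-diagonals (an M-matrix), so a discrete maximum principle holds, and
node-to-node conductances across material interfaces compose in series
(harmonic-mean behaviour across jumps; a two-cell series chain reproduces
the resistor-divider potential exactly). Boundary currents are flux
residuals of the full conductance matrix at the Dirichlet node sets, which
makes electrode and patch currents agree to the linear-solver tolerance by
construction.

Geometry that is not grid-aligned — the hemispherical verification
electrode — is handled by a cut-edge (Shortley–Weller) correction: edges
with exactly one endpoint in a spherical Dirichlet set have their
conductance rescaled to the exact distance from the free node to the sphere
crossing. Without it the staircase node set biases the effective electrode
radius by O(h).

The nonlinear coupling is resolved by Picard iteration: assemble with the
current conductivity, solve, recompute |E|, propose `sigma(|E|)`. The
proposed update is relaxed; because the plain relaxed iteration contracts
very slowly here (a positive slow mode of the sigmoid coupling), the
relaxation factor adapts between iterations by Aitken's secant rule, with
the conductivity clamped to its sigmoid bounds — the fixed point is
unchanged, only the path to it. The iteration is declared converged when
the max relative conductivity change is below `picard_tolerance`;
non-convergence is flagged in the returned diagnostics and aborts sweeps
unless explicitly overridden. Linear systems: one sparse LU factorization
(baseline conductivity) per voltage, then LU-preconditioned conjugate
gradients for subsequent Picard iterations; sweeps warm-start each voltage
from the previous one scaled by the voltage ratio.

Units are SI internally; lengths enter in mm and field magnitudes leave in
V/cm (1 V/mm = 10 V/cm) at the module boundary.

## Morphometry conventions

Depth `D` and width `W` are read on the cross-sectional plane through the
catheter axis: `D` is the deepest lesion cell *face* below the epicardial
plane, `W` the maximum face-to-face lateral extent over all depth rows, and
`depth_of_max_width` the shallow face of the winning row (ties toward the
surface). Face-based extents make a one-cell lesion measure one cell, at
the price of a ~half-cell outward bias that shrinks under refinement. Width
is deliberately the maximum over depths, not the surface width: the two
coincide whenever the maximum occurs epicardially, which the sweep suite
checks explicitly. Empty lesions report `D = W = 0` with `AR` undefined
(NaN, not 0), keeping threshold-monotonicity statements clean. A lesion is
transmural when it reaches the endocardial face; its depth then equals the
wall thickness, and calibration refuses depth (and AR) matching in the
transmural regime, where only width is meaningful.

## Calibration

For a monotone size curve `m(T)` the matching set against an experimental
range `[low, high]` is a contiguous interval; its endpoints are refined by
linear interpolation of `m(T)` between adjacent sweep grid points (the
sweep step, default 10 V/cm, bounds the refinement error). Non-monotone
curves — possible only with exotic geometry — fall back to the exact union
of grid runs and are flagged non-contiguous. The dual-threshold report
intersects the depth- and width-matching intervals; a single lethal
threshold is "sufficient" exactly when the intersection is nonempty.

## Verification oracles

A hemispherical electrode of radius `a` on a homogeneous half-space admits
`phi = V a / r`, `E = V a / r^2`, `I = 2 pi sigma a V`, lesion depth
`r_T = sqrt(V a / T)` and width `2 r_T` (AR = 2). The oracle geometry
carries this solution exactly in the continuum by imposing the analytic
far-field profile on the outer staircase boundary at each node's own radius
(a grounded-shell mode with the finite-R closed form
`V (a/r − a/R)/(1 − a/R)` is also provided). Convergence studies bisect
every cell globally (`refinement_level`), because refining only the fine
region leaves the graded-region truncation — whose cell size at a given
radius depends only on the grading ratio — untouched. Measured on the
shipped study (a = 1.335 mm, R = 8 mm, h = 0.33 → 0.165 mm): max relative
potential error 0.0060 → 0.0027, electrode-current error 0.21% → 0.04%.

The linear limit (`sigma_factor = 1`) is checked exactly: doubling the
voltage doubles the field bitwise (pure scaling of the same factorized
system), the IRE region at `(2V, T)` equals `(V, T/2)` cell-for-cell, and
lesion growth under voltage doubling is `sqrt(2) − 1 ≈ 41.4%` up to face
quantization. Morphometry is cross-checked against an independent
exhaustive plane-scan implementation on randomized masks.

## What the synthetic slab does and does not emulate

The slab stands in for a segmented porcine thorax that is not publicly
available: a flat myocardial wall over a blood pool in a homogeneous torso
block, flush perpendicular electrode contact, planar grounded patch. It
preserves the local physics that drive the headline claims — near-field
concentration around a focal electrode, the depth/width asymmetry of
epicardial lesions, the conductive blood pool under the wall — and drops
anatomy: curvature, lungs and bone, chamber geometry, variable wall
thickness. Passing the slab-band checks therefore shows the *mechanisms*
(AR ≈ 2 anisotropy, threshold-dependent calibration intervals, epicardial
maximum width, super-linear depth growth) on a controlled geometry; it does
not certify agreement with any particular animal's lesion sizes.

Two quantitative consequences of the 10 mm slab are worth stating plainly,
since the strict printed bands in the acceptance suite expose them. Lesions
grow deeper here than on an anatomical ventricle: at 2000 V and low
thresholds they approach or reach the endocardium. Near transmurality the
anisotropy ratio is compressed by the wall (minimum nontransmural AR 1.50,
at a 2000 V row with 9.3 mm of 10 mm depth, versus ≥ 1.6 reported for
anatomical geometry), and the depth growth under voltage doubling is
amplified once the electroporation-boosted channel (0.5 S/m) approaches the
blood pool (0.7 S/m): nonsaturated depth increases reach 67–93% versus the
reported 45–65%. Width growth (33–50%) and the AR band at typical
thresholds (1.76–2.17 versus 1.9–2.2) sit at or just outside the printed
bands for the same reason. These are properties of the stated study
conditions, not tuning targets; the tests assert the printed bands as
written and the discrepancies are documented rather than absorbed into
parameters.

## Known limitations

- Quasi-static, isotropic, purely resistive tissue; no thermal term.
- The conductivity sigmoid's parameters are configurable stand-ins; no
  published values were available for this exact waveform.
- Face-based morphometry quantizes sizes at the local cell size (0.35 /
  0.5 mm on the production grid), which propagates into percent-growth
  numbers as roughly ± one cell per lesion edge.
- The voxel electrode contact is a flat disk; a rounded tip would shrink
  the effective contact area slightly.
- Single focal electrode only; multielectrode and bipolar configurations
  are out of scope.
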