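# Methods

`sarcomech` has three layers: a synthetic-microscopy generator that
produces ground-truthed images of striated, micropatterned
cardiomyocytes; an image-analysis chain that measures per-sarcomere
spacing, orientation, nematic order and ratiometric FRET; and a
chemo-mechanical contractility model solved on 3-D cell-on-substrate
geometries.  This note records the models, the numerical choices, and
the limits of what the synthetic tests demonstrate.

## Synthetic microscopy

**What is emulated.** Single cardiomyocytes on rectangular (17 × 118 μm,
1:7 aspect) or circular (50 μm diameter) adhesive patterns, imaged in
two channels (donor/acceptor of an α-actinin-2 tension sensor).
Z-disks appear as bright ridges perpendicular to the local myofibril
axis with a spacing of one sarcomere length.

**Forward model.** Z-lines are painted explicitly: along each
orientation domain's axis, successive gaps are drawn from
N(spacing_mean, spacing_sd) (floored at 0.8 μm so ridges cannot
coincide); each z-line is a straight Gaussian-profile ridge (FWHM
0.35 μm — chosen to give discrete, segmentable z-disks rather than a
sinusoid) tilted to the local field orientation.  A sarcomere with FRET
index *f* emits fraction *f*/100 of its photons into the acceptor
channel and 1 − *f*/100 into the donor, so 100·A/(D+A) equals *f* at
its pixels before blur and noise.  Both channels receive a Gaussian PSF
(σ = 0.15 μm, a confocal 63×/1.46 scale), a uniform background
(100 counts), Poisson shot noise and Gaussian read noise (SD
10 counts).  Peak signal is 1000 counts.  Pixel size defaults to
0.1 μm/px.  Every output is a pure function of (configuration, seed).

**Presets.** The literature-derived presets carry published cohort
values for rectangular patterned hiPSC-CMs:
sarcomere spacing 1.63 ± 0.15 μm (live contracted), 1.73 ± 0.14
(live relaxed), 1.61 ± 0.15 / 1.74 ± 0.24 (fixed), and per-cell median
FRET indices 44.21 (contracted) and 51.70 (relaxed) on the percent-like
100·A/(D+A) scale.  Circle and day-1 presets are qualitative: circles
get multidomain orientations, slightly longer spacing and a contracted
FRET median near the relaxed value (circular cells do not build z-disk
tension); day-1 presets get longer spacing, lower contrast, multidomain
order even on rectangles, and a smaller FRET spread (dispersion grows
with maturation).  No published day-1 numbers are claimed.

**Orientation fields.** Angles are unsigned line directions in [0, π);
all statistics are nematic.  Uniaxial fields add a spatially correlated
Gaussian jitter (exact marginal SD = the preset jitter) to the pattern
long axis.  Multidomain fields use Voronoi domains with
farthest-point-sampled seeds and *stratified, area-balanced* angles:
bins jittered across [0, π), the largest domains receiving maximally
separated bins, smoothed across boundaries in the doubled-angle
representation.  Independent uniform angles were rejected because a
single draw can accidentally align several domains; stratification
guarantees the defining property of the disordered phenotype (field
order parameter well below 0.5 for every seed) while remaining random
in the details.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spectral bleed-through, depth-dependent
PSF, beating motion, myofibril branching and curvature within a domain,
intensity variation along a z-line, uneven illumination, and
camera-specific noise beyond the Poisson + Gaussian model.

## Image analysis

1. **Preprocess**: white top-hat with a disk of radius 0.8 μm (half the
   minimum spacing window; removes diffuse background while preserving
   z-lines), then a linear rescale saturating the bottom and top 1% of
   pixels.  A constant post-top-hat raster returns zeros with a warning.
2. **Segmentation**: at two physical scales (2 μm and 10 μm) the image
   is compared against its local *median*; a pixel is foreground when it
   exceeds the median by both `k·σ̂` (k = 3, σ̂ = 1.4826·MAD of the
   residual; rejects pure noise) and half the local peak-to-median
   amplitude (matches the ridge half-maximum width).  The two scales are
   combined by intersection.  Median neighbourhoods make the operator
   polarity-sensitive: wide bright plateaus sit at their own median and
   are rejected, so inverted-contrast images yield a near-empty mask.
   Large-window medians are computed on a 4× block-reduced image.
3. **Detection**: 8-connected components, area ≥ 0.2 μm²,
   intensity-unweighted centroids in μm.
4. **Spacing/orientation**: an 8 μm patch (≈3× the maximum spacing,
   reflection-padded at borders) around each centroid is mean-subtracted
   and autocorrelated by FFT with zero padding and division by the
   triangular overlap window (an unbiased estimate — the biased form
   drags long periods toward zero lag).  Radial profiles are sampled at
   0.05 μm in directions 0…π (2° steps, cubic interpolation).  A valid
   periodicity peak must rise ≥ 0.05 above its local trough *and* reach
   ≥ 0.1 of the zero-lag value (the absolute floor rejects white-noise
   wander in the unbiased tail).  Only first peaks inside the
   1.2–2.8 μm window count; the myofibril axis is the direction whose
   first peak radius (parabolic-refined) is smallest, because any
   off-axis direction sees the projected, longer period p/cos Δθ.
   Emitted spacings are clamped to the window — a hard postcondition.
5. **FRET index**: per component, 100·Ā/(D̄+Ā) with per-channel
   background (median outside the cell mask) subtracted; ratio of means
   by default (mean of ratios available).  Acceptor-photobleaching
   efficiency is E = 1 − F̄_DA/F̄_D per region, clamped to [0, 1].
6. **Order parameter**: S = ⟨(3cos²(θ−n̂)−1)/2⟩ with the director n̂
   from the principal eigenvector of the 2-D nematic tensor
   ⟨2u⊗u−I⟩; S is then evaluated by the averaging formula.  Perfect
   alignment gives 1; 2-D isotropy gives 0.25 (⟨cos²θ⟩ = ½ in the
   plane).  Degenerate tensors break the tie toward the smaller angle.
7. **Summaries**: per cell, mean spacing over valid records, median and
   IQR (type-7 linear-interpolation quantiles) of the FRET index, S and
   n̂.  The FRET index is reported on the raw percent-like scale; a
   cohort-normalised variant (divide by a relaxed-cohort median) can be
   formed downstream when a unit-free scale is wanted.

## Chemo-mechanical contractility model

Contractility is a tensor ρ coupled to stress by mechanosensitive
feedback.  The free-energy density (strain energy + external work at
fixed external stress + motor binding + ATP hydrolysis coupled to
feedback + motor work) is quadratic in (ε, ρ); minimising at fixed
external stress yields linear steady-state relations with
feedback-renormalised moduli

K̄ = K(β−1)/(β−α), μ̄ = μ(β−1)/(β−α),
3ρ̄ᵥ = 3βρ₀/(β−α) + αₐ/(β−α)·tr σᵃ, 2ρ̄ₐ = αₐ/(β−α),

where the stress-anisotropy tensor σᵃ = H(σ₁/σ₂−1)·σ₁·(n⊗n) activates
aligned (sarcomeric) contractility along the first principal stress
direction.  An elastic α-actinin element in series (moduli K_α, μ_α,
defaulting to the cytoskeletal values) gives the effective sarcomere
law σᵏᵏ = 3K_eff ε + 3ρ_eff^v, σ̃ = 2μ_eff ε̃ + 2ρ_eff^a σ̃ᵃ with series
moduli K_eff = K_α K̄/(K_α+K̄) and the active terms scaled by the
stiffness-partition factors K_α/(K_α+K̄), μ_α/(μ̄+μ_α).

**Parameters** (kPa unless noted): α = 1 kPa⁻¹, αₐ = 2 kPa⁻¹,
ρ₀ = 2 (contracted) or 0.01 (relaxed), K = 3.333, μ = 0.3448.  β (the
motor-binding cost) is treated as a plain number in the same
nondimensional slot as α, default 4, chosen to respect the two
stability conditions β > α and αₐ/(β−α) < 1 with margin.  All
quantities are numbers in a consistent nondimensionalised system.

**A units subtlety, documented deliberately.**  Strict stationarity of
the quadratic free energy gives K̄ = (3Kβ−1)/(3(β−α)) — the
conventional "(β−1)" factor is exact only in units where 3K = 2μ = 1 (the
antecedent model's nondimensionalisation).  The package follows the
renormalised-moduli convention above for the material law (with α = 1
the factor cancels and K̄ = K, μ̄ = μ, which is what the simulations
use), and separately exposes the variationally exact steady state
(`stationary_state`); the stationarity test verifies by finite
differences that the closed-form minimiser makes all free-energy
gradients vanish, and that the two conventions coincide at 3K = 2μ = 1.

**Step-function policy.**  The ratio σ₁/σ₂ is ill-defined across zero,
so the hard step uses the sign test (σ₁ > σ₂ and σ₁ > 0); exact
degeneracy σ₁ = σ₂ gives σᵃ = 0.  A logistic variant
H(x) = 1/(1+e^(−x/w)), w = 0.05, is available for continuation but is
not the default (it leaves near-degenerate elements chattering at half
amplitude).

## Cell-on-substrate finite elements

Geometries: the rectangular cell is half of a spherically capped
cylinder, total length 120 μm *including* the caps (straight section
95 μm — the 120 μm figure is read as total length to match the 118 μm
adhesive pattern; a `length_includes_caps` switch records the choice)
and radius 12.5 μm; the circular cell is a half-sphere of equal volume
(radius computed at runtime, ≈ 23.57 μm).  Both rest on a linear
elastic substrate (E = 7.9 kPa, ν = 0.45), lateral extent 3× the cell
footprint, thickness 60 μm, edges and bottom fixed.

Discretisation: a graded tensor-product grid of 8-node hexahedra
(2×2×2 Gauss), target 4 μm in the cell, geometric coarsening (ratio
1.4, cap 12 μm) toward the substrate boundary; ~4000–8000 elements and
~3·10⁴ degrees of freedom per geometry at the defaults — sized so the
full shape × state matrix solves in seconds on one core.  Boundary
elements carry a partial-volume fraction (4³ midpoint subsamples) that
scales their stiffness, load and volume; this keeps the voxelised cell
volume within ~1–2% of the analytic value at the default resolution.
Stray cell fragments not face-connected to the substrate are dropped.

Contractility enters as the eigenstress ρ_eff^v δ + 2ρ_eff^a σ̃ᵃ on
cell elements.  The stiffness matrix is constant, so one sparse LU
factorisation serves the whole self-consistency loop:
solve elasticity → recompute σᵃ element-wise from the cell stress →
repeat, with Anderson acceleration (history 5).  Convergence is the
relative L2 change of σᵃ; the default tolerance is 10⁻³.  A tighter
10⁻⁴ is reachable for the rectangle (≈10 iterations) but not for the
circle: its in-plane stress is nearly axisymmetric, so the anisotropy
direction field carries a near-neutral collective rotation mode
(≈0.02°/iteration drift) that no reasonable iteration count removes,
while amplitudes and every scalar readout are stable to <0.1% well
before 10⁻³.  The iteration log is kept on the solution object.

Readouts:

* **α-actinin volumetric strain** ⟨ε⁽²⁾_kk⟩ = ⟨σ_kk⟩/(3K_α).  The cell
  average of σ_kk is computed through the mean-stress identity
  ⟨σ⟩V = ∮ t⊗x dA — the cell surface is traction-free except at the
  substrate interface, where the consistent nodal tractions are known —
  which is far less sensitive to the voxelised surface than the raw
  element average (both are provided; they agree in the mesh limit).
* **Order parameter** S_sim: Q = (3n⊗n − I)/2 with n the pointwise
  first-principal-stress direction, volume-averaged over the cell;
  S_sim is the largest eigenvalue.  Degenerate principal stresses fall
  back on the deterministic eigensolver tie-break and are counted.
* **Tractions**: the force the cell applies to the substrate at an
  interface node is minus the cell-side internal nodal force; dividing
  by tributary area gives the traction.  This consistent form satisfies
  global force balance to machine precision.

Because the anisotropy update is positively homogeneous of degree one,
the entire solution scales linearly with ρ₀: the relaxed state is the
contracted field scaled by 1/200, and S_sim is identical between
states.  Small-strain kinematics are used throughout even though the
predicted strain magnitudes are large (|ε_kk| ≈ 0.8 for the
unconstrained cell); predictions are reported as-is, as a linearised
model.

**Mesh sensitivity.**  The voxelised surface makes pointwise stresses
near the rim first-order accurate in the element size: on refinement
the element-averaged strain readout moves by several percent per
halving, which is why the boundary-integral form is the default (its
change per halving is ~1–2%).  S_sim retains a slow downward drift with
refinement (staircase noise in principal directions near the curved
surface); the shape ordering S_sim(rect) ≫ S_sim(circ) is far outside
this sensitivity.  The refinement test in the suite runs on a reduced
geometry (40 × 6 μm cell) where a full 2× refinement is affordable.

## Pipeline and statistics

The pipeline (generate → quantify → model → report) is configured by
YAML, writes per-stage manifests into append-only `run-NNN`
directories, and produces a cohort report whose every number is
recomputable from the per-sarcomere/per-cell CSVs.  Identical
(config, seed) pairs give byte-identical reports.  Group comparisons
are descriptive only: differences of medians / mean IQRs / mean S with
seeded percentile-bootstrap 95% intervals (2000 resamples by default);
no hypothesis testing is performed.

## Problem sizes used in validation

Cohort recovery runs use 40 cells per spacing preset and 30 per FRET
preset at the default image size (280 × 1280 px rectangles, 0.1 μm/px),
each cell carrying ~70 sarcomeres; grating sweeps cover 0.8–3.6 μm in
0.1 μm steps.  FEM checks run the default meshes for all four
shape × state combinations and a reduced geometry for the refinement
study.  These sizes were chosen so that Monte-Carlo error is well below
each comparison tolerance (the SE of a 40-cell grand mean of per-cell
mean spacing is ≈0.003 μm against a ±0.05 μm band).

## Known limitations

* The generator's realism limits are listed above; in particular the
  FRET index scale is the raw acceptor fraction, not the
  cohort-normalised unit-free scale some reports use (values ~0.83–0.98
  relative to a relaxed cohort).
* The sensor-level relation between z-disk force and FRET is not
  modelled; presets pin index distributions, not forces.
* Linear kinematics at large predicted strains (above).
* The FEM is a voxel method: pointwise surface stresses are noisy and
  only volume/boundary-integrated readouts should be interpreted.
* Relative σᵃ convergence below 10⁻³ is not attainable for the
  axisymmetric geometry (above); the tolerance is an argument, not a
  constant.
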