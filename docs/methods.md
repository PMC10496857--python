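# Methods

## Problem and scope

Transmission Mueller-matrix microscopy of thin brain-tissue sections measures,
per pixel, a real 4×4 matrix **M** mapping input to output Stokes vectors
(I, Q, U, V). For white matter the dominant signal is the linear (form)
birefringence of aligned myelinated fibers: the scalar retardance tracks the
optical path through oriented tissue and the azimuth of the optical axis
tracks the in-plane fiber direction. `muellerpol` implements the standard
post-processing chain — physical-realizability filtering, pixel-wise
decomposition by two routes, and map-level statistics — plus a forward
simulator of one- and two-layer fiber stacks that provides ground truth for
every stage. The scientific question the analysis scripts address is how a
*crossing* of fiber layers inside the probed volume shows up in the
retardance, azimuth and depolarization maps.

Conventions used throughout: Stokes order (I, Q, U, V); azimuths measured
counterclockwise from the laboratory x-axis looking toward the source,
reported in degrees on [0°, 180°); Mueller elements written m11…m44
(1-based) in documentation and mapped to native 0-based indexing once, at
the I/O boundary; all retardances are cumulative over the sample (the
geometric path length is absorbed into the decomposition products; per-μm
rates live only in the simulator's `LayerSpec`).

## Pipeline

1. **m11 normalization** (`io.normalize_m11`): M → M/m11. This is what makes
   the isotropic-absorption term of the differential decomposition vanish
   (α₀ = 0). Pixels with m11 ≤ 0 are degenerate and masked.
2. **Substrate correction** (`io.substrate_correct`): the blank glass
   substrate is factored out by right-multiplication, M·M_ref⁻¹, because in
   transmission the light traverses glass and sample in sequence. The
   measured glass response is within 1% of the identity, so a full matrix
   correction and a simple intensity normalization are nearly equivalent;
   the matrix form was chosen because it is exact for the simulated
   sequences and reduces to the intensity form for a scaled identity.
3. **Cloude filtering** (`cloude`): M is physical iff its Hermitian coherency
   matrix H = ¼ Σᵢⱼ mᵢⱼ (σᵢ ⊗ σⱼ*) is positive semidefinite (σ₀…σ₃ the
   identity and Pauli matrices in the (I,Q,U,V) order). Measurement noise
   pushes eigenvalues slightly negative; the filter clamps negatives to zero
   in the eigenbasis and maps back. Default is the pure zero-clamp (never
   adds energy); a trace-renormalizing variant is available by flag.
   Tolerance: an eigenvalue is accepted down to −10⁻⁶·tr H, well below the
   instrument-grade 1% element accuracy. The filter is idempotent and leaves
   physical matrices bit-identical.
4. **Decomposition**, both routes below, applied pixel-wise.
5. **Statistics** (`maps`): Tukey box-whisker summaries, azimuth statistics
   behind a low-retardance floor, quiver export, cross-method diagnostics.

## Differential decomposition

For a medium acting continuously along z, dM = mM dz, so L = ln M
accumulates the differential matrix over the path. With the Minkowski metric
G = diag(1, −1, −1, −1):

    mm = (L − G Lᵀ G)/2   (G-antisymmetric: mean polarization properties)
    mu = (L + G Lᵀ G)/2   (G-symmetric: depolarization + uncertainties)

mm carries linear dichroism p1 (x–y) and p2 (±45°), circular dichroism p3,
linear birefringence p4 (x–y) and p5 (±45°), circular birefringence p6; mu
carries the depolarizing factors α₀…α₃ on its diagonal (α₀ = 0 after
normalization; α₁…α₃ ≤ 0 for physical media) and the uncertainties d1…d6.
Summaries:

    Rt = √(p4² + p5² + p6²)        (degrees)
    αt = |α₁ + α₂ + α₃| / 3
    θ  = ½ atan2(p5, p4)  mod 180°

**Sign conventions.** Printed layouts of the polarizing tensor in the
literature are not mutually consistent about where the sign flips sit in the
birefringence block, and the θ formula is sometimes printed with p6 in the
denominator although p6 is *circular* birefringence. Both choices here are
fixed by one identity: a pure linear retarder of retardance δ at azimuth θ
must give (p4, p5) = δ(cos 2θ, sin 2θ), so that tan 2θ = p5/p4 and the
azimuth agrees with the one read from the polar-decomposition retarder
factor. Under the retarder handedness used by the simulator (QUV block =
rotation by +δ about the equatorial Poincaré axis (cos 2θ, sin 2θ, 0)) this
pins the extraction positions to p4 = mm(4,3), p5 = mm(2,4), p6 = mm(2,3).
The two-argument arctangent resolves the quadrant; θ is reported NaN when
Rt < 10⁻⁶ ° (axis undefined).

**Matrix logarithm.** The log is computed from the eigen-decomposition,
L = V diag(ln dᵢ) V⁻¹, with complex-conjugate eigenvalue pairs recombining
to a real L (imaginary residue checked against 10⁻⁹ and discarded). Two
guarded failure paths:

- an eigenvalue on the closed negative real axis (retardance at the 180°
  branch point, or strongly scattering media) has no real principal log:
  the pixel is flagged `decomposition-failed`, never unwrapped;
- an ill-conditioned eigenbasis (cond(V) > 10⁶, i.e. defective or nearly
  defective M) silently corrupts the eigen-route — for *repeated*
  eigenvalues it can return a plausible but wrong real matrix — so such
  pixels are rerouted to the Schur-based inverse-scaling-and-squaring
  routine (`scipy.linalg.logm`), which also serves as the independent
  oracle in the tests.

The z-dependence of the continuous model (mean vs. mean-square split along
depth) is deliberately not separated: a single measurement cannot
distinguish them, so all reported properties are cumulative, exactly as the
per-pixel maps are.

## Lu–Chipman (forward polar) decomposition

M = M_Δ · M_R · M_D, i.e. diattenuator first along the beam. Steps:

1. D⃗ = (m12, m13, m14)/m11, P⃗ = (m21, m31, m41)/m11;
   m_D = √(1−D²) I + (1 − √(1−D²)) D̂D̂ᵀ. D ≥ 1 is a singular diattenuator:
   the pixel is masked (cannot occur after Cloude filtering of transmission
   data).
2. M′ = M·M_D⁻¹ = M_Δ·M_R, whose first row is (1, 0, 0, 0).
3. m_Δ = sign(det m′)·(m′m′ᵀ)^{1/2} by eigendecomposition of the symmetric
   m′m′ᵀ (the symmetric factor of the polar decomposition; the sign
   prescription — omitted in some presentations — keeps m_R a proper
   rotation, det = +1). m_R = m_Δ⁻¹ m′. Singular m′ (complete
   depolarization along an axis) leaves the retarder undefined; the
   depolarizer is still returned and the pixel flagged.
4. Summaries: Rt = arccos[tr(M_R)/2 − 1] (clamped to its domain within
   10⁻⁹ against rounding); αt = 1 − (|a|+|b|+|c|)/3 with a, b, c the
   principal values of m_Δ; azimuth from the retardance vector.

**Azimuth extraction.** The retardance vector is taken from the
*antisymmetric* part of m_R — componentwise sin R·n̂, e.g.
n₁ ∝ M_R(4,3) − M_R(3,4) — and θ = ½ atan2(n₂, n₁). For a pure linear
retarder this is ratio-identical to the familiar single-element form
tan 2θ = M_R(2,4)/M_R(4,3). For *elliptical* retarders (a crossed two-layer
stack generates circular retardance) the raw-element form picks up a
(1 − cos R)·nᵢn₃ coupling worth ~0.2° at the retardances simulated here,
while the antisymmetrized form cancels it exactly and agrees with the
differential azimuth identically. The reverse (depolarizer-last)
factorization is intentionally not implemented.

**Cross-method relations** (used as tests): for isotropic depolarization of
strength a composed with any retarder, αt(LC) = 1 − a and αt(diff) = −ln a,
hence αt(diff) = −ln(1 − αt(LC)); the two depolarization maps are strictly
co-monotone, with the bounded Lu–Chipman values sitting below the unbounded
differential ones. Retardance and azimuth agree between methods to numerical
precision on all noiseless simulated scenes.

## Forward simulator: the stated world

Each layer is a linear retarder (per-μm retardance × thickness) combined
with an isotropic diagonal depolarizer exp(−depol_per_um·t) per polarized
component; the two commute, so a homogeneous layer is their product in
either order. Stacks multiply in propagation order (first-traversed layer
acts first on the Stokes vector). Ground truth for composed stacks is
computed by an independent route — quaternion (axis-angle) composition of
the per-layer rotations via `scipy.spatial.transform.Rotation` — never by
the decompositions under test.

Preset parameters (chosen once; anchors in **bold** are the stated
scenario values, the rest are this package's realism choices):

| parameter | value | rationale |
|---|---|---|
| retardance rate | **1.8°/μm** | 10 μm single stripe ⇒ 18° median, the single-layer anchor |
| layer thicknesses | **10 μm; 10+5 μm** | single stripe and two-layer stack arrangements |
| azimuths | **90°** (single), **110°** (stack base) | reported medians of the two sites |
| crossing angles | **0°, 45°, 90°** | top-stripe rotations of the stack arrangements |
| azimuth jitter | 1.5° SD, smoothed (6 px correlation) | corpus callosum is the most coherently oriented tract; sub-mm fields show ~1–2° dispersion |
| retardance CV | 0.05, lognormal, median-preserving | thickness/packing variation of a uniform histological section |
| depolarization | 0.004/μm (single), 0.00733/μm (stack layers) | stack/single ratio 2.75× (differential) and 2.66× (Lu–Chipman), inside the stated 2.5–3× band; the higher stack rate encodes the extra scattering of the thicker, interfaced stack |
| holes | 10% (single), 5% per stack layer, r = 3 px disks | tissue holes; hole pixels respond as bare substrate (identity) |
| element noise σ | 0.0221 | see calibration below |

The parallel-stack retardance median is therefore 27° (= 18 + 9), not the
~35° measured on real tissue, whose second stripe happened to be more
retarding than its nominal thickness suggests; the presets reproduce the
*composition law*, not that specimen's variability, and the gap is
documented rather than tuned away.

**Noise calibration.** The instrument's stated measurement accuracy of
~2–3° retardance is read as the level that noise-induced retardance rarely
exceeds — pixels *below* it are discarded as unreliable — i.e. an upper
envelope, not a typical value. `calibrate_element_sigma` therefore chooses
the per-element noise SD such that the 95th percentile of pipeline-recovered
Rt on blank (identity) pixels equals 2.5°, the middle of the band; the
frozen default is σ = 0.0221, giving a blank-pixel Rt median of ≈1.4° and
~1% of blank pixels above the 3° azimuth floor. Reading the band as a
*median* instead would put roughly a third of pure-noise pixels above the
floor (noise retardance is χ₃-distributed with 95th/50th percentile ratio
≈1.8), which would contradict the observed near-complete exclusion of
crossed-stack azimuth pixels.

**Identical-stripes idealization.** The exact-compensation scenario ("two
identical stripes of equal thickness at 90°") is simulated with
`share_fields=True`: both layers reuse one realization of the jitter,
retardance and hole fields, so compensation is exact up to measurement
noise. With independently drawn fields the residual retardance
(≈ |δ₁−δ₂| ⊕ 4 sin(δ/2)·Δθ) sits at the noise floor and about a third of
pixels would survive the 3° mask — a statement about layer-to-layer tissue
variability, not about the compensation physics.

**What the simulator does not emulate** — and hence what a green test does
not establish: anisotropic or retardance-correlated depolarization,
diattenuation of real tissue (D is computed and stored but all simulated
scenes have D = 0), multiple-scattering blur between layers, the
instrument's spatial PSF and calibration residuals, and any
reflection-geometry effect. Parameter-recovery results on these scenes
validate the algebra and the statistical machinery, not instrument realism.

## Map statistics

- Box-whisker rule fixed at Tukey 1.5×IQR with linear-interpolation
  quartiles (this makes {1,2,3,4,100} yield quartiles 2 and 4 and exactly
  one outlier).
- Azimuth statistics exclude pixels with Rt below a configurable floor
  (default 3°, the conservative top of the 2–3° accuracy band) before
  summarizing; quantiles are linear on [0°, 180°) to match conventional box
  plots, with a 180°-periodic median available by flag since azimuth is
  circular. Setting the floor to 0 reproduces the inclusive behaviour
  (large azimuth spread on noisy scenes).
- Quiver export places one stick per node of a sparse grid (default step
  20 px) at valid pixels, angle = θ, length = Rt/max Rt over valid pixels.
- Cross-method comparison reports per-pixel ΔRt and Δθ (folded to
  [−90°, 90°)) and the Spearman rank correlation of the two depolarization
  maps; depolarization values are rounded to 10⁻⁹ before ranking so that
  piecewise-constant noiseless scenes do not have their ties broken by
  floating-point dust.

## Known limitations

- Retardances are reported on the principal branch [0°, 180°]; stacks whose
  total retardance exceeds 180° would alias, so the simulator forbids them
  per layer and the presets stay well inside.
- Azimuth of a retarder with R → 180° is extracted from an antisymmetric
  part that vanishes as sin R; pixels that close to the branch point are
  reported NaN rather than guessed.
- The differential route fails (by design, flagged per pixel) whenever an
  eigenvalue reaches the negative real axis — the known failure mode of
  log-based decomposition for strongly scattering or reflection-geometry
  data; the polar decomposition has no such restriction.
- `alpha0` is only guaranteed ≈0 for m11-normalized input; the pipeline
  normalizes both before and after filtering to keep this exact.
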