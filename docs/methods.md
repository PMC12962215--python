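# Methods

This note records the models, conventions and numerical choices behind
`phyllotaxis3d`, in the spirit of a package-level methods appendix: what is
simulated, what the defaults mean, and what passing tests do and do not
demonstrate.

## Trajectory designs

Spokes are full diameters of the k-space ball, sampled from +k_max·**d** to
−k_max·**d**. The azimuth of spoke n (1-based) is φₙ = n·φ_GA mod 2π with
φ_GA = π(3−√5); the polar angle follows a linear schedule: θₙ = (π/2)(n/N)
for the original design, the two-branch pole-to-pole schedule reaching π at
n = N (N even), and the four-segment full-circle schedule reaching 2π at
n = N (N divisible by 4). Angles beyond π are converted to directions by
literal trigonometric evaluation, which realizes the pole-crossing path.
The acquisition order interleaves the index space as n(j,k) = k + (j−1)K,
with interleave k played out contiguously. The first spoke of each
interleave is flagged as the superior-inferior (self-gating) spoke;
`si_spoke_mode="replace_with_z"` optionally overwrites it with an exact +z
spoke, the scanner convention, while the default leaves the formula value
(the two conventions differ only in that near-pole spoke).

Conventions worth stating once: spoke indices in all public interfaces are
1-based to match the design formulas; a start direction with z = 0 is
assigned to the upper hemisphere; the polar schedules are evaluated
literally so θ_N touches the stated endpoint (π/2, π, 2π respectively).

A consequence of the *linear* polar schedules is that spoke directions are
not uniformly distributed on the sphere: their density is proportional to
1/sin θ, i.e. the poles are oversampled. This matters for density
compensation (below).

## Imperfection model

Two effects, chosen as the minimal parameterization that reproduces the
orientation-dependent k-space-center phase pattern and the
single-hemisphere smearing artifact:

* **Direction-odd zeroth-order phase.** Each spoke's samples are multiplied
  by exp(i **c**·**d**) with **c** in radians per unit direction component.
  Odd symmetry — ψ(−**d**) = −ψ(**d**) — is the defining property: it is
  what opposing-spoke acquisition cancels and what single-hemisphere
  acquisition cannot.
* **Gradient delays.** Per-axis delays τ (plus an isotropic global delay),
  in readout-sample units, displace the *effective* sample positions by
  Δk_a = (τ_a + τ_g)·d_a·Δk per axis. An isotropic delay reduces to a pure
  along-readout shift of τ samples for every spoke; anisotropic delays also
  move samples across the nominal line.

The simulator evaluates the phantom's closed-form spectrum at the
*effective* positions and hands the reconstruction the *nominal* ones; the
mismatch is the artifact mechanism. Noise is i.i.d. circular complex
Gaussian, with sigma specified relative to the phantom's k-space-center
magnitude and seeded for exact reproducibility. Transient (history-
dependent) eddy-current behavior is deliberately out of scope: the model
is memoryless per spoke.

## Phantoms

Phantoms are unions of uniform balls with closed-form 3D Fourier
transforms, so single-coil k-space is sampled grid-free with no inverse
crime at the gridding stage. The canonical homogeneous phantom
(`salt_water_ball`) stacks 1-voxel shells so its radial profile
approximates a super-Gaussian exp(−(r/10)⁶): a ball with a ~3-voxel soft
edge. The soft edge is a deliberate desk-scale study condition: at the
benchmark spoke counts (hundreds to thousands of spokes, far below the
~π·matrix² angular Nyquist of a sharp edge) the streak floor of a
hard-edged ball would bury the phase-inconsistency artifacts under
coverage artifacts that exist for *any* trajectory. A real salt-water ball
edge is also not a mathematical discontinuity at acquisition resolution,
only narrower. The tissue phantom (`vial_phantom`, and the two-plane
variant used in the mapping tests) arranges soft vials so that different
tissues share z-columns, making smearing-induced cross-talk visible in the
estimated relaxation times.

Multi-coil data are produced by forward-gridding the sensitivity-weighted
rasterized phantom; coil sensitivities are synthetic smooth Gaussian
fields on a ring, with no claim of modeling a physical array.

## Reconstruction

Readouts in the benchmark experiments use 2× oversampling
(samples_per_spoke = 2·matrix + 1). With only ~matrix samples per spoke the
radial sample spacing supports a spherical field of view of diameter
`matrix`, and the corners of the cubic volume receive aliased copies of
the object; 2× readout oversampling is standard radial-MRI practice and
removes this entirely.

Density compensation is the Voronoi-of-shells convention: along each spoke
w ∝ |k|², with the exact-center sample assigned the analytic limit
(Δk/2)²/3 (the mean of r² over the central half-bin), multiplied by each
line's solid-angle share sin θ_line to account for the 1/sin θ direction
density of the linear polar schedules. `reconstruct` then refines these
weights by a deterministic iterative spread-and-resample scheme (10
iterations of dividing each weight by the kernel-convolved weight density
at its own location), which adapts them to arbitrary spoke subsets —
hemisphere splits and retrospective undersampling in particular, where the
closed-form law is no longer the Voronoi volume. `dcf="analytic"` skips the
refinement.

Gridding is conventional Kaiser-Bessel convolution onto a 1.5× oversampled
grid with Beatty's kernel shape parameter and quadrature-evaluated
continuous-FT deapodization; the adjoint is defined as
f(x) = Σᵢ wᵢ sᵢ exp(+2πi kᵢ·x) on the centered voxel grid and is verified
against an exact (naive) adjoint DFT. The kernel width defaults to 5 grid
cells: at oversampling 1.5 a width-4 kernel leaves ~1.1×10⁻³ relative
aliasing error, marginal against the 10⁻³ oracle-equivalence target, while
width 5 gives ~3×10⁻⁴ at negligible cost. Coil combination estimates
sensitivities from low-resolution images formed from the centered 4³-sample
block of each coil's Cartesian k-space (interpreting the calibration region
as k-space samples; the image-voxel reading is the flagged alternative),
normalizes them to unit sum-of-squares, and projects. The SI spokes are
excluded before reconstruction by default.

## Corrections

**Opposing-spoke constant phase.** For every spoke the nearest opposing
spoke is found by exhaustive search over the other start hemisphere
(ties broken by the lower phyllotaxis index; a faster index would have to
match this definition exactly). Each spoke and coil is then multiplied by
the unit-magnitude complex phase of its partner's k-space-center sample.
Sign convention: with numpy's counter-clockwise angle convention the
correction multiplies by exp(+i·∠S_opp); since the partner's center phase
carries the *negative* of the spoke's own direction-odd error, this cancels
the inconsistency (the equivalent clockwise-angle formulation writes the
same operation with a minus sign in the exponent). Per-spoke magnitudes are
unchanged exactly; spokes whose partner phase is undefined (zero-magnitude
center) are left uncorrected and reported.

**Gradient-delay correction.** Spokes are inverse-Fourier-transformed along
the readout; the partner's projection is reversed, because opposing spokes
traverse the same line in opposite directions; per-coil phase differences
are combined by a magnitude-weighted complex sum (a plain angle sum is
available); the unwrapped difference is fitted linearly against the
projection coordinate where the combined projection magnitude exceeds 10%
of its maximum (the fit-region threshold is otherwise unspecified in the
underlying procedure and fixed here); and half the fitted slope-plus-
intercept is removed from each spoke, so both members of a pair move
symmetrically (`apply="full"` instead applies the full difference to the
upper-hemisphere member). The slope maps to a per-spoke readout shift as
τ = a·M/(4π) samples; the intercept carries the zeroth-order phase, which
is why intercept-only correction already removes most of the artifact. The
implementation requires an odd sample count so the reversed projection
lands on the same coordinate grid.

## bSSFP signal model and inversion

With E₁ = exp(−TR/T1), E₂ = exp(−TR/T2), flip angle α and
Θ = 2π·Δf·TR − ΔΦ (ΔΦ the per-TR RF phase increment; the sign convention
is fixed by the Bloch steady state below):

S(Θ) = i·M·(1 − E₂ e^{−iΘ})/(1 − b cos Θ) · e^{−TE/T2} · e^{i2πΔf·TE},

with D = 1 − E₁cos α − E₂²(E₁ − cos α), b = E₂(1−E₁)(1+cos α)/D and
M = PD·(1−E₁) sin α / D. The expression is verified to 10⁻⁶ against an
independent 3×3 matrix Bloch steady-state solver (RF rotation about x,
relaxation + precession per TR in the RF-phase-hopped frame, receiver
demodulated at the exciting pulse's phase); the global factor i and the
e^{−iΘ} numerator are consequences of measuring Mx + iMy with a
right-handed rotation convention.

`estimate_tissue` inverts the model by variable projection: for trial
(θ₀, a, b) the complex amplitude is solved linearly, and the three shape
parameters are refined by bounded least squares from a deterministic
multi-start grid (12 θ₀ values × 3 (a,b) pairs, tolerances 10⁻¹⁴, at most
200 function evaluations per start; the multi-start grid replaces an
algebraic conic-fit initialization, which is brittle for short 12-sample
profiles). T2 = −TR/ln a; E₁ follows in closed form from (a, b, α);
Δf = θ₀/(2πTR) (wrapped, so Δf is identifiable only within ±1/(2TR)); PD
from the amplitude after removing the TE decay. Estimates are invariant to
global complex scaling of the profile — which is also why a per-ROI
corruption that is constant across the phase-cycled series does *not*
bias T1/T2: only effects that differ between increments, chiefly
compartment cross-talk from smearing, propagate into mapping errors.
Nonphysical outcomes (E₁ outside (0,1), T1 < T2) are flagged, not clipped;
degenerate profiles (all-zero, collinear) return a failure flag with a
reason instead of numbers.

## Evaluation metrics

`artifact_metric` reports the image-energy ratio outside/inside the
phantom support, with the support dilated by 2 voxels so boundary Gibbs
ringing does not count as artifact; the share of outside energy within a
3-voxel-radius cylinder around the polar axis (the artifact's preferred
direction); and interior phase/magnitude statistics on the phantom's solid
core (≥50% of peak amplitude, eroded by 2 voxels). `jump_statistics`
separates great-circle steps between consecutively acquired start points
into within-interleave and interleave-boundary transitions — the original
design's boundary jumps are ≈π/2 (equator to pole), the pole-to-pole
design's ≈π, and the continuous design's are small by construction.
Retrospective undersampling keeps every R-th spoke in acquisition order
(stride; preserves the golden-angle azimuthal spread) or a prefix.

## Benchmark problem sizes

The packaged benchmarks run at matrix 48 with 97-sample readouts:
N = 2000 spokes (K = 10 interleaves of 200, the per-interleave structure of
the fully sampled protocols) for the self-compensation and correction
experiments, the full 89×200 = 17800-spoke protocol for the undersampling
experiment, and 12- or 18-step phase-cycle ladders for mapping. These sizes
were chosen so the full pipeline remains a desk-scale computation; the
fully sampled protocol bookkeeping (17800 spokes; 320400 and 213600
readouts over the 18- and 12-cycle series; 547×18 = 9846 for the cardiac
protocol) is asserted exactly.

One deliberate measurement choice: in the undersampling experiment the
designs are compared on the *corruption-attributable* artifact energy
(corrupted minus imperfection-free baseline at identical sampling). At a
matched retained-spoke count the pole-to-pole design covers about half as
many distinct k-space lines as the original — two nearly-antipodal spokes
sample one line — so its coverage-streak floor is ~4× higher, an effect
orthogonal to phase compensation; the baseline subtraction isolates the
phase-error component whose persistence is the claim under test.

## What the synthetic results do and do not show

The generator reproduces: orientation-dependent k-space-center phase
(odd in the spoke direction), sample shifts from gradient delays,
multi-coil weighting, complex Gaussian noise, bSSFP contrast across RF
phase increments, and the resulting design-dependent artifacts and mapping
errors. It does not model: eddy-current transients with memory across
spokes, B1⁺ inhomogeneity, intra-voxel dephasing, fat, motion, or
scanner-specific gradient responses. Consequently, passing tests
demonstrate the *mechanism* (odd phase errors cancel between opposing
spokes) and the correctness of the algorithms, not quantitative agreement
with any particular scanner's artifact amplitude. Mapping-error contrasts
between designs are bounded by the square root of the artifact-energy
contrast, because per-series-constant corruption cancels in the ellipse
inversion; dramatic real-world mapping failures likely involve
increment-dependent effects outside this model.

## Known limitations

* The adjoint reconstruction is linear; no iterative/compressed-sensing
  reconstruction is provided or needed for these demonstrations.
* `find_opposing` is O(N²); fine for ≤10⁵ spokes, and by definition the
  reference any accelerated index must match.
* The delay fit assumes the object's projections have adequate support
  (10% magnitude mask); pathological phantoms with disjoint tiny support
  can leave spokes uncorrected (reported, not silent).
* Off-resonance from the ellipse inversion is wrapped to ±1/(2TR) Hz.
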