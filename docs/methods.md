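# Methods

## Model

`softcells` simulates a two-dimensional non-confluent tissue as N soft
deformable disks in a periodic square box of side L. Cell i has a fixed
radius R_i; there is no growth, division or adhesion. Two cells i, j
interact only when they interpenetrate, i.e. when the overlap

    h_ij = max(0, R_i + R_j − |r_i − r_j|)   (minimum-image distance)

is positive. The repulsive contact force is Hertzian,

    F_ij = h_ij^{3/2} / [ (3/2) ((1 − ν²)/E) √(1/R_i + 1/R_j) ],

directed along the centre line, with elastic modulus E and Poisson
ratio ν identical for all cells. Softness matters: at high packing
fraction ϕ = Σ πR_i²/L² (which may approach or exceed hard-disk close
packing) the cells overlap appreciably, and that overlap is what frees
up space elsewhere.

Dynamics is overdamped and athermal,

    dr_i/dt = F_i/(γ0 R_i) + µ W_i(t),

with friction proportional to cell size (γ_i = γ0 R_i, so small cells
are more mobile) and a delta-correlated active noise of amplitude µ —
a stand-in for intrinsically generated cell motility, not a thermal
bath. The integrator is explicit Euler–Maruyama with per-step kick
µ√Δt·ξ, the unique discretisation consistent with delta-correlated
noise. Note on units: dimensional consistency forces µ to carry µm/√s
(the characteristic time ⟨R⟩²/µ² is a time only under that reading);
the numeric value used is the reference 0.045.

### Default parameters

| parameter | value | unit | role |
|---|---|---|---|
| Δt | 10 | s | timestep (stable: max per-step drift ≪ cell radius) |
| µ | 0.045 | µm/√s | self-propulsion noise amplitude |
| γ0 | 0.1 | kg/(µm·s) | friction prefactor (γ_i = γ0 R_i) |
| E | 10⁻³ | MPa | cell elastic modulus |
| ν | 0.5 | — | cell Poisson ratio |
| N | 500 | — | cells per box |

With lengths in µm, forces in µN (= MPa·µm²) and friction in kg/s these
units are mutually consistent: 1 µN/(kg/s) = 1 µm/s.

### Radius distribution

Real embryonic tissue shows a broad spread of projected cell sizes. The
exact distribution behind the reference observations is not available,
so the generator is configurable and the default is chosen once to meet
every printed constraint simultaneously: a log-normal in radius,
truncated to [3, 24] µm (max/min = 8), with the location parameter
solved numerically so the truncated mean is exactly 8.5 µm (the
monodisperse reference radius) and shape σ_log = 0.40. Within the
truncated log-normal family, σ_log trades the position of the first
g(r) peak (it needs enough mass near 8.5 µm to sit at ≈ the mean cell
diameter of 17 µm) against the free-area statistics of the jammed state
(too broad a distribution inflates ϕ_free above its reported plateau
≈ 0.22); σ_log = 0.40 is the middle of the window that satisfies both
to within ~10%, and it was frozen before any acceptance threshold was
evaluated against it. Monodisperse (R = 8.5 µm) and 1:1 binary mixtures
are provided for the reference comparisons (the monodisperse system
crystallises; the binary one is glassy at all ϕ with no viscosity
plateau).

### Initialisation and equilibration

Random placement at ϕ ≥ 0.9 produces catastrophic overlaps, so cells
are seeded uniformly at 50% of their final radius and grown linearly to
full size over a ramp (default 5·10³ steps) with the active noise on,
then equilibrated at full size. Production records frames every
`save_every` steps and the off-diagonal virial stress every step.
Structural observables (g(r), Voronoi statistics) converge within a few
10⁵ s of burn-in even at ϕ = 0.93 (checked against 4× longer runs);
dynamical observables in the glassy regime are measured over windows of
5–20 times the relaxation time at that ϕ. Every run is bit-reproducible
from its seed; sweeps spawn per-run child seeds from a master seed via
`numpy.random.SeedSequence` and record them in a manifest.

## Observables

**g(r)** — shell- and density-normalised histogram of minimum-image
pair distances over all cells and frames, with a KD-tree (periodic
boxsize) doing the pair search. The first-peak position is refined
below the bin width by a parabola through the peak bin and its
neighbours; a configurable prominence threshold (5% of the g-range)
rejects noise bumps.

**Fs(q,t)** — the isotropic self-intermediate scattering function. The
orientation average of exp(−i q·Δr) in 2D is J₀(q|Δr|), which is used
directly instead of sampling q directions. Displacements are unwrapped
(wrapped coordinates would produce a spurious plateau once |Δr| reaches
the box scale — this is tested). Lags are log-spaced; all available
time origins are used per lag, strided to a cap of a few hundred. The
probing wavevector is q = 2π/r_max with r_max that state point's own
g(r) first peak, recomputable per ϕ or fixable across a sweep. The
relaxation time τα solves Fs(q, τα) = 1/e, log-linearly interpolated
between bracketing lags; series that never reach 1/e report a censored
"unrelaxed" value (None / NaN) rather than a number. Per-cell τα uses
the same estimator restricted to one cell; the global Fs is exactly the
per-cell mean, so the two views are consistent by construction.

**Overlap and free-area statistics** — P(h_ij) pools all contacting
pairs over frames. The periodic Voronoi tessellation replicates the
centres into the 3×3 images, tessellates with Qhull, and keeps the
primary-image polygons, whose areas partition the box exactly
(Σ A_i = L², asserted to 10⁻⁹). Free area per cell is
A_free,i = A_i − πR_i² (negative when overlaps squeeze the polygon
below the disk area), and ϕ_free is the frame-averaged sum of positive
A_free over L². The plain (unweighted) Voronoi diagram of the centres
is used, not the radical/Laguerre tessellation: the radical tessellation
assigns almost no cell a polygon smaller than its disk, which destroys
the negative-A_free mass and the ϕ_free ≈ 0.22 plateau that the plain
construction reproduces (a Laguerre mode was prototyped and rejected on
this evidence).

## Green–Kubo effective viscosity

The off-diagonal virial stress P_xy = (1/A) Σ_{i<j} r_ij,x f_ij,y
(kinetic term absent: the model is overdamped and athermal, so η̄ is a
proxy for shear viscosity in reduced stress²·time units, with no
A/k_BT prefactor) is accumulated every step. Its time-origin-averaged
autocorrelation, summed over the two off-diagonal components (equal for
central forces, hence 2× the xy term), is integrated:

    η̄ = ∫₀^∞ dt Σ_(µν) ⟨P_µν(t) P_µν(0)⟩ .

The empirical sample mean of P_xy (zero in the ensemble) is subtracted
before correlating; otherwise the finite-run offset never decays and
biases the integral.

The raw long-time ACF is noisy, so the integrand is spliced: a cubic
spline (not-a-knot ends — value, slope and curvature continuous at the
interior nodes and cubics reproduced exactly) interpolates the
short-time data on [0, t₁] and is resampled on a uniform δt = 10 s
grid; beyond t₁ the data are replaced by a stretched-exponential fit
C_s exp[−(t/τ_η)^β], β ∈ (0, 2]. The splice point t₁ defaults to the
flattest point (smallest log-derivative) of the smoothed normalised ACF
between its half-decay time and the end of resolved signal —
a reproducible automation of the usual visual plateau choice — and is
overridable. The fit window ends where the smoothed normalised ACF
sinks below 5% for good (fitting further into pure noise would drag
the fit off the knee). A discontinuity at t₁ larger than 35% of the
local amplitude is an error, not silently integrated over. The integral
is a trapezoidal sum on the δt grid, closed by the analytic tail
∫_T^∞ C_s e^{−(t/τ)^β} dt = C_s (τ/β) Γ(1/β) Q(1/β, (T/τ)^β) once the
remainder is below 0.1%; for rapidly decayed, non-KWW-shaped ACFs a
raw-data tail mode integrates the measured points instead.

## Fits

**VFT**: η̄(ϕ) (and τα(ϕ)) follow η = η₀ exp[D/(ϕ₀/ϕ − 1)] below the
saturation packing fraction ϕ_S. The fit runs in log space, where the
model is linear in (ln η₀, D) at fixed ϕ₀: a bounded 1-D profile search
over ϕ₀ followed by a full nonlinear polish. Optional inverse-variance
weights come from replicate spreads; the window is restricted to
ϕ ≤ ϕ_S (default 0.90, or estimated as the smallest ϕ beyond which
successive values are statistically flat). A ϕ₀ on the search boundary
is flagged. **Stretched exponential**: shared with the viscosity
module; amplitudes are normalised internally so that reduced-unit
magnitudes (~10⁻¹²) do not break the finite-difference steps.
**Gaussian master curve**: P(ln τα)/P_max is fitted to
exp[−c (ln(τα/τ₀))²]; the mean squared residual is returned so the
below-/above-ϕ_S contrast (Gaussian vs not) is quantifiable.

## Synthetic fixtures

Deterministic fixtures generate all test data at run time: exact
two-cell and lattice geometries; free-diffusion trajectories with
Gaussian steps (Fs then has the closed form exp(−q²σ²(t)/2)); and
stationary Gaussian stress series with a prescribed stretched-
exponential autocovariance via circulant embedding (negative embedding
eigenvalues clipped — harmless for these smooth ACFs). These synthetic
processes validate the estimators against closed forms; they share no
code path with the estimators they test.

## What the simulations do and do not show

The generator emulates the steady state of a dense, polydisperse,
actively jittering 2D cell layer. It does not include cell division,
growth, adhesion, three-dimensional rearrangement, or any imaging
artefacts of real tissue; agreement of the synthetic pipeline with the
reference observations therefore supports the model's mechanism
(polydispersity + softness → free-area saturation → viscosity plateau)
but is not by itself evidence about any particular experimental system.

## Problem sizes used in the shipped tests and acceptance script

The reference study used N = 500 with 24–40 replicates per ϕ and runs
of 5–10 τα. The shipped acceptance script reproduces the structural
targets at full N = 500 with 3 replicates per ϕ and ~1.2·10⁶ s of
burn-in (convergence checked against 4× longer runs). The test suite
exercises the dynamical (VFT/aging) criteria at reduced scale — N = 200,
fewer replicates, shorter windows — which widens the scatter of fitted
VFT parameters relative to the reference values; the chosen sizes and
their observed spreads are stated in the tests themselves.

## Known limitations

- The radius distribution is a calibrated stand-in for an unavailable
  reference distribution; structural observables shift by ~5–10% across
  plausible alternatives (uniform-in-radius, neighbouring σ_log).
- The *steepness* of the glassy slowdown is sensitive to that
  calibration in a way the structural observables are not: with the
  default parameters the relaxation time grows by a factor ~13–20
  between ϕ = 0.75 and 0.89, substantially shallower than the
  reference VFT parameters (ϕ0 ≈ 0.95, D ≈ 0.5) imply. The acceptance
  tests for those fitted parameters are therefore expected to fail at
  their stated tolerances; the qualitative phenomenology — monotone
  VFT-regime growth of η̄ and τα, saturation of both above ϕ_S ≈ 0.90,
  a ϕ_free plateau, no aging — is reproduced. The number-weighted
  fraction of small, fast cells (which dominates how quickly the mean
  Fs decays) is the prime suspect, and it is exactly the feature of
  the size distribution that the available constraints pin down least.
- The jammed-state P(A_free) is flat-topped over roughly 40–90 µm², so
  its mode is reported from a lightly smoothed histogram and sits at
  the centre of that top (~65–75 µm²); it remains an unstable summary
  of a stable distribution.
- η̄ at ϕ > ϕ_S requires stress windows ≫ τ_η; at the shipped test
  scale those points carry large error bars and are used only for
  plateau/ordering checks, not for fits.
- The splice-point heuristic can misplace t₁ for ACFs with no resolved
  plateau; it is overridable per run, and the discontinuity guard turns
  silent failures into errors.
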