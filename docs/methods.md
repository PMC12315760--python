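# Methods

## The problem

Capillary-scale vascular properties — blood volume fraction (BVf), mean
vessel radius (R), blood oxygen saturation (SO2) — modulate the MR signal of
a voxel through the microscopic field inhomogeneities that magnetized blood
creates, but they are far below imaging resolution. Vascular fingerprinting
estimates them by simulating the signal of explicit sub-voxel vascular
geometries over a range of parameters (a *dictionary*) and inverting the
acquired signal against it, either by nearest-entry matching (DBM) or by a
learned Bayesian inverse regression (DBL).

The acquisition modelled here is GESFIDSE — a single spin-echo experiment
sampled with gradient echoes on both sides of the refocusing pulse —
acquired once before and once after injection of an iron-oxide contrast
agent (USPIO). The two acquisitions are concatenated into one fingerprint
per voxel. Default timing: TR 4000 ms, 32 echoes, ΔTE 3.3 ms, spin echo at
60 ms; echoes at i·ΔTE, refocusing pulse at 30 ms, so the spin echo falls
between echoes 18 (59.4 ms) and 19 (62.7 ms). The exact echo placement
relative to the 180° pulse is a package convention (config-exposed).

## Forward model

**Geometry.** A voxel is a binary occupancy volume on a cell-centred grid
(micrometre spacing; axis order x, y, z; z is the B0 axis by default).
Three families: 2D disks of a fixed radius (the original 2D representation),
3D straight cylinders with isotropic orientations and variable radii, and
stochastic tortuous branching networks standing in for microscopy-derived
voxels. Structures are placed uniformly at random with periodic wrap
(minimum-image rasterization, matching the periodic FFT field solver) and
may overlap; occupancy is the union. Structures are added until the realized
BVf is within max(0.05 pp, 2 % relative) of the target; because whole disks
or cylinders are coarse volume increments, the final structure is placed by
bisecting its lateral offset from an existing one (its marginal volume
varies continuously with overlap), and network growth stops sub-step-wise
inside the band. Unreachable targets raise with the achievable range — the
geometric constraint that low-BVf/large-R combinations cannot always be
accommodated is inherent to cylinder packing.

**Characterization.** BVf is exact voxel counting. R is half the mean
minimum Feret diameter of per-slice (xy) 2D connected components: a tilted
vessel shows an elliptical cross-section whose short axis is the true
diameter, which is what the minimum caliper width measures. Components under
5 cells are treated as rasterization noise (with a documented fallback when
nothing passes); detections are aggregated as a plain mean over components
and slices (not length-weighted), and at most ~24 evenly spaced slices are
measured since per-slice detections are exchangeable. Rasterized cylinders
with R ≥ 3 grid spacings are recovered within one spacing.

**Susceptibility and field.** Intravascular cells carry
Δχ = Δχ_deoxy · Hct · (1 − SO2/100) + Δχ_CA, extravascular cells 0.
Defaults: Δχ_deoxy = 3.318 ppm (SI, fully deoxygenated, per unit
haematocrit), Hct = 0.42, Δχ_CA = 0.5 ppm post-injection (chosen on the
order of the mid-range deoxygenation contrast; the in-vivo dose does not fix
a susceptibility, so this is config-exposed, and absolute SO2 estimates
depend on it). An optional distributed-oxygenation mode assigns per-vessel
SO2 values; with all vessels equal it reproduces the uniform mode bit for
bit. The field offset is computed with the Fourier dipole kernel
(1/3 − k_z²/|k|²) at B0 = 4.7 T, periodic boundaries, k = 0 term set to
zero (the uniform offset is absorbed into the rotating frame; magnitude
signals are unaffected). No Lorentz correction beyond the kernel's 1/3
term. 2D voxels use the in-plane kernel (1/2 − k_b²/|k|²) with B0 in-plane,
i.e. disks model cross-sections of cylinders perpendicular to the plane.
The solver reproduces the closed-form exterior field of a perpendicular
infinite cylinder within 5 % (relative to the local dipole envelope, after
removing the constant offset of the zero-mean convention) at ρ ≥ 2r, and a
parallel cylinder's exterior residual is at machine precision.

**Signal.** Transverse magnetization starts uniform on the grid; each step
multiplies by exp(i·Δω·dt), applies transverse relaxation, and convolves
the complex magnetization with a Gaussian diffusion kernel of standard
deviation √(2·ADC·dt) per axis (periodic wrap; ADC = 1000 µm²/s); an ideal
instantaneous 180° pulse conjugates the phase at SE/2; the signal is the
magnitude of the spatial mean at each echo time. Because the voxel carries
a single T2, the relaxation factor is a uniform scalar that commutes with
every other operator; it is applied analytically as exp(−t/T2) on the
recorded echoes, which is exactly equivalent to per-step multiplication.
Intravascular spins contribute with the same T2 by default (an
intravascular-nulling option exists). No thermal noise is added by the
simulator; noise is the phantom/reconstruction layer's concern.

Numerical choices that matter:

- *Step size.* The per-step phase is bounded: max|Δω|·dt < π/4 is enforced
  as a precondition (violations raise, naming the required step). The
  default explicit step is 0.1 ms; with ``dt_sim_ms=None`` the largest step
  with max|Δω|·dt ≤ 0.9·π/4 is chosen and each inter-event interval is
  subdivided evenly, so echoes and the refocusing pulse are hit exactly.
  The auto step agrees with a 0.1 ms reference to ~0.1 % on dictionary-type
  voxels while being ~10× faster.
- *Diffusion kernel.* The per-step blur is discretized with an **exact
  discrete second moment**: an m-fold self-convolution of the
  moment-matched stencil [v/2, 1 − v, v/2], v = σ²_cells/m ≤ 1/3. Since
  variances add exactly under convolution, the accumulated diffusion width
  is √(2·ADC·t) independent of step size. (A sampled or bin-integrated
  Gaussian is biased at sub-cell σ and the bias accumulates over thousands
  of steps — with bin integration the fine-step limit over-diffuses by
  1/12 cell² per step.) Kernels wider than an axis fold periodically.
- 2D voxels restrict dephasing and diffusion to the plane.
- Everything is deterministic: identical inputs give identical signals.

## Dictionaries

One (SO2, T2) pair per voxel geometry, sampled jointly from a scrambled 2D
Sobol sequence over [35, 90] % × [45, 110] ms (the scrambled series is
drawn to the next power of two and truncated, keeping it deterministic in
the seed; joint 2D scrambling is the package's choice where the alternative
would be two independent 1D series). BVf and R are imposed by the geometry
and recorded *as measured on the rasterized mask* — that is what the
fingerprints actually encode. Pre- and post-contrast states share one
unit-susceptibility field solve per geometry (the field is linear in the
uniform intravascular Δχ); each entry is two signal simulations and one
jointly L2-normalized concatenated fingerprint (raw norms kept for
diagnostics). Dictionaries persist losslessly to a single HDF5 container
with full provenance metadata.

### Desk-scale study conditions

Full-scale applications of vascular fingerprinting use dictionaries of
~28,000 microscopy-derived voxels of 248 × 248 × 744 µm³ at 2 µm
resolution — roughly 10 s of compute per voxel on a large multi-core
server. This package's defaults are sized for a single CPU:

- dictionary size 2,000 entries (3D families), simulation grid 48 × 48 × 72
  cells at 3.875 µm isotropic (a 186 × 186 × 279 µm³ box); 2D disks use
  64 × 64 cells (248 × 248 µm²);
- synthetic vascular conditions: target BVf log-uniform on [1, 12] %,
  radius log-uniform on [3, 10] µm (right-skewed, physiologically centred
  near 3 % and 5 µm), with the radius capped by the largest cylinder that
  fits the target BVf in the box;
- a full 2,000-entry dictionary builds in minutes; grid and sizes are
  config-exposed.

The reduced box matters scientifically: fingerprints of voxels with *the
same* (BVf, R, SO2, T2) but different random geometries differ
(realization noise), and this variance grows as the box shrinks (fewer
vessels per voxel). At the default box it is comparable to the fingerprint
spacing of a 2,000-entry dictionary, which bounds what any estimator can
recover — see "What the tests show" below.

## Reconstruction

**DBM** scores a normalized fingerprint against every entry by dot product
and returns the argmax entry's parameters (ties: lowest row index).
Estimates live on the dictionary grid by construction.

**DBL** fits a Gaussian locally-linear mapping (GLLiM) to the dictionary:
a K-component joint Gaussian mixture in which t = (BVf, R, SO2, T2) follows
N(c_k, Γ_k) and x | t follows N(A_k t + b_k, Σ_k) with diagonal Σ_k,
estimated by EM in the parameter→signal direction (L = 4 regressors against
D = 64 outputs keeps the parameter count small). The inverse conditional
p(t | x) is another Gaussian mixture in closed form; prediction reports its
posterior mean (not the mode — the posterior expectation is the standard
GLLiM point estimate) and standard deviation. Defaults:
K = 50, EM tolerance 10⁻⁶ relative log-likelihood, max 200 iterations,
seeded k-means++ initialization, per-dimension standardization, covariance
regularization 10⁻⁶, variance floors; starved components are re-seeded and
then dropped if they collapse again. K was probed on an independent
validation split (K ∈ {50 … 150}); differences were within split noise, so
the default stays at 50. Everything is config-exposed and seeded.

Estimates are clipped to physical ranges afterwards: BVf and SO2 to
[0, 100] %, R to [0, 250] µm, T2 to ≥ 0 ms (no upper clip); clipping is
idempotent and flags which bounds fired. Map reconstruction applies either
estimator voxelwise under an optional mask; masked-out voxels hold NaN
(never 0, which is a legal value). Quality sidecars (match score /
posterior sd) accompany the maps.

## Phantoms and ROI statistics

Phantoms emulate the tumour-study ROI design: a label image (default: a
square "tumor" inset in "contra" tissue) with per-region (BVf, R, SO2, T2);
every voxel gets its own cylinder geometry and goes through the full
forward chain. Gaussian noise is added to the raw magnitude samples before
normalization (values kept non-negative, as magnitudes are), with SNR
defined on the mean first pre-contrast echo. Region parameters outside the
dictionary ranges warn (DBL extrapolation) rather than fail.

ROI statistics follow the per-animal design: voxel values are averaged
inside each ROI per unit, and the per-unit means are the samples of a
two-sided two-sample t-test at α = 0.05 — Student by default, Welch as an
option (the source protocol does not specify the variant). Pooled-voxel
testing is deliberately not the default because it inflates significance.

## What the synthetic data do and do not show

The generators emulate geometric statistics (volume fraction, calibre,
orientation dispersion, tortuosity, branching), not real vascular topology:
no closed capillary loops, no arteriole/venule hierarchy, no flow, no
species-specific anatomy, no myelin or air-interface susceptibility
sources, and the acquisition model has ideal pulses, no slice profile, no
stimulated echoes and no motion. Passing tests therefore demonstrate
internal consistency of the simulation–reconstruction chain and its
physics, not in-vivo accuracy.

Two quantitative consequences of the desk-scale conditions are documented
by the test suite itself:

- **Noisy exact-row matching is information-limited.** Neighbouring
  fingerprints in a 2,000-entry dictionary are separated by ~10⁻² in
  L2 distance after normalization, while SNR-50 noise perturbs a
  fingerprint by a comparable amount; exact-row recovery under noise
  plateaus near 60 %, and mismatches land on parameter-similar entries.
  This is a property of dictionary density and noise, not of the matcher
  (noiseless self-match is exactly 100 %).
- **Held-out recovery is realization-limited.** DBL recovers held-out
  off-grid parameters with RMSE ≈ 0.6–0.9 pp (BVf), ≈ 0.9 µm (R),
  ≈ 5–6 pp (SO2), ≈ 3–4 ms (T2) at the default box, uniformly better than
  DBM's quantization error — the interpolation advantage of learning over
  matching. BVf and SO2 errors track the geometry-realization noise of the
  small box and shrink with box volume.

## Known limitations

- Minimum-image rasterization of "infinite" cylinders keeps only the
  nearest periodic image of each axis; obliquely wrapped continuations
  beyond the first image are dropped (an infinite line on a torus would
  otherwise fill it densely).
- Per-slice components that touch the periodic seam are measured as split
  components, slightly biasing the Feret statistic for near-seam vessels.
- The 2D kernel convention (B0 in-plane, cylinders normal to the plane) is
  one of several in use; it is recorded in the field-map metadata.
- GLLiM posterior sd is a within-model uncertainty; it does not include
  realization noise or model misspecification.
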