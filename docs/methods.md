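# Methods

This note documents the models implemented in `ipdtplan`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Quantitative SFDI concentration mapping

Structured sinusoidal illumination at spatial frequency f (the
acquisition set is 0, 0.2 and 0.5 mm^-1; 0.5 mm^-1 is the analysis
default because it has the shallowest, sharpest depth sensitivity) is
projected in three frames with 120 deg phase offsets.  The modulation
amplitude is demodulated as

    MAC(r) = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2),

which returns exactly the sinusoid amplitude A for ideal frames
`I_k = DC + A cos(phi + 2 pi k/3)` regardless of DC and phase; the
amplitude-recovery property fixes the prefactor uniquely and is enforced
by a least-squares-sinusoid oracle test.

Concentration follows the diffusion-theory correction

    [PS](r) = k_PS * mu_a,x * Fm(r) / D(r),
    D(r) = 1 - (1 - (MACs/MACref) Rx_ref) * (MACs/MACref) * Rm_ref,

with `k_PS` (to ug/mL) and the excitation absorption `mu_a,x` (1/mm)
supplied as calibration inputs, and the reference phantom quantities
`MACref`, `Rx_ref`, `Rm_ref` supplied per pixel or as scalars.  The
grouping of the denominator admits more than one reading when typeset;
the implementation exposes `quantification_denominator` as an
inspectable intermediate so alternate groupings can be A/B-tested.  The
fluorescence input `Fm` may be a raw frame or a demodulated fluorescence
MAC; the raw frame is the default.  Pixels where D falls below an
epsilon are flagged invalid (never silently zeroed); negative results
are clamped to zero and counted.  The multi-frequency inversion of
optical properties from reflectance is out of scope: `mu_a,x` enters as
calibration.

The detection limit of a dilution series is the smallest concentration
whose mean recovered signal exceeds the blank mean plus three blank
standard deviations.

## Heterogeneity statistics

Tumor [PS] histograms are typically bimodal (poorly perfused core,
well-perfused rim).  The module provides:

* histogram-counts Otsu thresholding (the cut between bins maximizing
  the between-class variance `w0 w1 (mu0-mu1)^2`, ties toward the lower
  edge) — computed from the histogram, not raw pixels, with 256 bins
  over the data range by default;
* a two-component Gaussian mixture via EM (scikit-learn backend,
  k-means++ initialization, 5 restarts, tolerance 1e-6 — strongly
  overlapping modes converge slowly, so the tolerance is deliberately
  tight), components ordered by mean; a least-squares fit of the
  two-Gaussian density to the normalized histogram is provided as an
  alternate route;
* a degeneracy flag raised when the fitted means collapse within one
  pooled SD or when BIC prefers a single component — "no second mode";
* summary statistics: per-mode CV = SD/mean, the 10th-to-90th
  percentile range of the pooled sample (linear-interpolation
  percentiles), the fold range max/min of per-slice mode-2 means, and
  the dimensionless separation (mean2-mean1)/pooled-SD.  Reported CVs
  round half-up to two decimals.

## GLCM texture

Maps are quantized to a constant number of gray levels (default 32)
over a study-wide dynamic range.  Co-occurrence matrices are built at
unit pixel distance for the four principal angles, symmetrized and
normalized; three Haralick features are reported:

    contrast    = sum (i-j)^2 p(i,j)
    energy      = sum p(i,j)^2
    homogeneity = sum p(i,j) / (1 + |i-j|)

Homogeneity uses the inverse-difference kernel; the
inverse-difference-moment variant `1/(1+(i-j)^2)` is selectable because
both circulate under the same name.  The sliding window moves with step
1 and features are computed only where the window fits entirely (no
padding), averaged over the four angles.  A "1-pixel" window carries no
pixel pairs, so the smallest supported window is 3x3; the default
window set is {3, 5, 15, 20}.  The sliding kernel is compiled (numba)
and cross-checked against per-window brute-force pair enumeration.
Mapping window areas to sampling volumes requires an effective optical
depth, which is a configurable parameter rather than an asserted value.

## Synthetic data

`gen_bimodal_tumor_map` draws a disk tumor (core disk + rim annulus,
rim fraction 0.35 of the radius by default) at 0.06 mm pixel pitch.
Default modes: core mean 3.03, SD 1.25; rim mean 7.97, SD 3.37 ug/mL —
the statistical structure of a strongly bimodal tumor; the background
is a narrow normal spanning 0-0.9 ug/mL.  Concentrations are
zero-truncated (the mixture model fits untruncated normals; truncation
is a physical-nonnegativity choice and is negligible at the default
modes).  `gen_sfdi_frames` inverts the quantification formula to a
fluorescence frame and synthesizes the three-phase reflectance triplet,
noise applied last; with zero noise the full analysis chain recovers
the ground truth to 1e-6 relative.

What the generator does *not* emulate: speckle, the optical system PSF,
depth-dependent partial-volume effects, or spatially correlated
biological texture beyond the core/rim split.  Tests passing on these
maps therefore validate the estimators' correctness and calibration,
not their robustness to optical artifacts of real images.

## Meshes and heterogeneity scenarios

Tumors are unions of interconnected random spheres around a central
core, meshed by Delaunay triangulation of a jittered lattice whose
density targets the preset tetra volume (presets: low 5.39 mm^3 average,
medium 6.99/3.43 mm^3, high 0.08 mm^3).  Boundary lattice layers sit
exactly on the bounding box so the meshed volume equals the analytic
volume.  The layered-head fixture nests scalp/skull, CSF, gray matter
and white matter shells inside an absorbing bounding box, with a
spherical tumor at the center.

The rim is the outer shell of the tumor within a thickness of 20% of
the equivalent radius (a default; the rim/core boundary is not a
measured quantity).  [PS] heterogeneity scenarios (cell multipliers =
local/mean concentration, bounded to [1/3, 3]):

1. multiplier 1 everywhere;
2. core at exactly half the rim (two-region closed form; whole-tumor
   volume-weighted mean exactly 1);
3. core as scenario 2 plus a heterogeneous rim realized by four seeded
   random-field recipes — patchy, gradient, hot-spot, cold-spot —
   rescaled to preserve the core:rim mean ratio 0.5 and whole-tumor
   mean 1.  The recipes keep amplitudes mild and cold structure
   localized: the rim remains the drug-rich compartment throughout, so
   the homogeneous scenario is the most power-demanding plan.  These
   recipes are synthetic stand-ins for perfusion-driven rim structure,
   not reconstructions of any measured pattern.

`fine_grained_ps_field` models heterogeneity whose correlation length
(default 0.1 mm) lies below both 1/mu_eff and the cell size: each
cell's multiplier is the average of the many independent sub-volumes it
contains, so per-cell multipliers concentrate near 1.  This encodes the
physical statement that a dose model resolves heterogeneity only down
to its element size.

## Monte Carlo light transport

Photon packets are launched from cylindrical diffusers (uniform line of
isotropic emitters; angular profile is not otherwise constrained) or
points, traversing the tetrahedral mesh by exact ray-face stepping with
precomputed outward face normals.  Free paths are exponential at
mu_t = mu_a + mu_s; at each interaction the packet deposits
`w mu_a/mu_t` into the enclosing cell (fluence = deposited /(mu_a *
volume * packets)), survives with `w (1 - mu_a/mu_t)`, and is rouletted
below weight 1e-4 (survival 0.1, weight x10).  Refractive-index
mismatches apply unpolarized Fresnel reflection/refraction; the
bounding region absorbs perfectly.  The weight ledger
deposited + escaped + roulette-killed - roulette-boost = launched closes
to float precision and is asserted in tests.

Two scattering representations: `transport` (default) applies the
similarity relation — isotropic scattering at mu_s', preserving mu_a
and mu_s' and hence the diffusive fluence — because anisotropic walks
at the tabulated scattering levels (mu_s up to 254/mm in white matter)
cost one to two orders of magnitude more interactions for the same
diffuse field; `hg` runs the full Henyey-Greenstein walk with
mu_s = mu_s'/(1-g).  The closed-form diffusion solution
`phi(r) = exp(-mu_eff r)/(4 pi D r)` depends only on mu_a and mu_s' and
is the validation oracle for both modes (agreement within 3 relative
standard errors; the two modes also cross-check each other).

Optical properties at 635 nm (1/mm): tumor 0.18/10/0.8/1.39, gray
matter 0.01/8.8/0.89/1.36, white matter 0.08/40.7/0.84/1.467,
scalp+skull 0.55/10.8/0.8/1.56, CSF 0.0038/0.005/0.87/1.3891
(mu_a/mu_s'/g/n).  The near-transparent CSF produces light piping,
verified as a directional property.  The optional coupling of [PS] to
absorption, `mu_a -> mu_a (1 + beta (m - 1))` in tumor cells, defaults
to beta = 0: optics independent of the photosensitizer map, with
heterogeneity entering only through the dose threshold.

## Threshold-dose planning

A tissue element dies iff `phi_i m_i >= T(tissue)`, with per-tissue
thresholds T as configuration inputs (the threshold table behind this
dose model is not published with the optical properties; the package
default sets a uniform T = 20 in fluence-dose units, which fixes only
the power scale and none of the reported fractions or comparisons).

`optimize_power` factors the power vector as scale x direction on the
simplex.  For a fixed direction, the minimal scale achieving the
target coverage is computed exactly as the coverage-weighted quantile
of per-cell ratios T/dose — the limit a scale bisection would converge
to, without iteration — so the achieved destruction equals the target
(98%) up to one cell-volume quantum; the head fixture's tumor cells
(~0.12 mm^3) keep that quantum below 0.1%.  The direction minimizing
the organ-at-risk objective (volume-weighted hinge overdose
`sum V max(0, dose - T)` over OAR cells, unit weights by default,
bounding region excluded) is found by deterministic candidate screening
(simplex vertices, centroid, a seeded Dirichlet sample, and a dense
sweep for two sources) followed by pattern search on the simplex.  The
coverage constraint set is not convex, so the search is a documented
heuristic anchored by a brute-force grid oracle on toy meshes.

`anneal_positions` wraps the power optimizer in simulated annealing
over diffuser centers and (1 mm discretized) lengths: one source moves
per proposal, its unit field is recomputed at a reduced packet budget,
acceptance follows Metropolis with geometric cooling (factor 0.95), and
the best-seen plan is rebuilt at the full budget.  Plans are compared
by per-OAR V100 differences and per-source Euclidean displacement under
minimal-total-distance assignment.

## Problem sizes and what the experiments show

The planning experiments run on a desk-scale head fixture: head radius
35 mm with a 5 mm spherical tumor refined to ~0.12 mm^3 cells, one
central diffuser (4 mm; at this tumor size the clinical placement rule
of 8-10 mm edge margin and 10 mm spacing degenerates to the deepest
feasible position), and 10^6 packets for the headline run with 2x10^5
per seed for the ten-seed stability study.  At the tabulated tumor
attenuation (mu_eff = 2.34/mm) fluence spans ~4 orders of magnitude
across this tumor, which is the largest dynamic range a desk-scale
packet budget resolves robustly; the same contracts (98% +/- 0.1%
coverage pinning, seed CV, scenario sensitivity) are scale-free
properties of the optimizer and transfer to larger models with larger
budgets.  The scenario study holds optics fixed (beta = 0), so one
Monte Carlo field serves all scenarios and differences between plans
are attributable purely to the heterogeneity structure.

Known limitations: no oxygen/photobleaching kinetics (the dose model is
the fluence x [PS] threshold comparison); no tomographic depth
resolution in the imaging chain; mesh generation is lattice-Delaunay
rather than boundary-conforming, so curved tissue interfaces are
staircase-approximated at the cell scale; the annealer's budget is
deliberately small and it makes no claim of global optimality.
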