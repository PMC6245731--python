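# Methods

`cruspark` couples two engines around a shared picture of the cardiac dyad:
a grid-based quantification of RyR (ryanodine receptor) clusters and Ca²⁺
release units (CRUs) from single-molecule localization data, and a stochastic
finite-volume reaction–diffusion simulator of the Ca²⁺ sparks those units
produce. A synthetic-data layer generates every input with known ground
truth, so each stage is testable closed-loop without any external data.

## Cluster / CRU quantification

**Reconstruction.** Localization events (x, y, frame, precision) are
deposited on a 10 nm pixel grid with bilinear sub-pixel splitting (each event
carries unit mass) and convolved with a 2D Gaussian of FWHM 20 nm — the
nominal image resolution. Chains of events recurring at one site (within a
50 nm colocalization radius) over ≥ 10 consecutive frames are removed first;
they are the signature of autofluorescent particles, not single-fluorophore
blinking.

**Thresholding.** RyR-positive pixels are found with an exact Otsu threshold
(between-class variance maximized over cuts between consecutive distinct
sample values, no histogram binning) computed on the nonzero intensities
after excluding the brightest 0.3% of them. The exclusion keeps
constantly-active sites from skewing the threshold; excluded pixels remain
suprathreshold in the mask.

**Grid fit and morphometry.** The binary mask is fitted to a 30 nm lattice —
the footprint of one RyR tetramer; a cell is occupied when more than half of
its area (≥ 5 of 9 subpixels) is above threshold. Clusters are 8-connected
components of occupied cells (a contiguous stretch of junctional SR can
bridge a diagonal; 4-connectivity is available as a switch). CRUs group
clusters by single linkage under a strict edge-to-edge criterion
(< 150 nm by default, < 100 nm as the stricter alternative), where
edge-to-edge distance is measured between the 30 nm cell squares themselves,
not their centers. CRU solidity is the occupied fraction of the convex hull
of the CRU's cells after dropping clusters with fewer than 5 RyRs; undefined
(NaN) when nothing survives the exclusion. Inter-cluster distance is the
mean nearest-neighbour centroid distance; density is RyRs per µm of scanned
cell length.

**Known bias.** At 21 nm localization precision the suprathreshold halo of a
very small cluster (2×2 cells, ~60 nm) exceeds its true footprint, so 4-RyR
clusters are systematically over-counted by one to two cells. For clusters of
≥ 9 RyRs — the scale actually reported for ventricular myocytes (~14
RyRs/cluster) — the closed loop recovers cluster count exactly and mean
RyRs/cluster within ±1 across seeds. Counts for sub-100 nm clusters should be
read as upper bounds.

## Dyad geometry

The simulation domain is a box of 12 nm cubic voxels. From top to bottom: a
48 nm non-conductive t-tubule slab; a single 12 nm cleft layer; the
junctional SR (jSR) plate (2 voxels thick by default; exposed as
`jsr_thick`); bulk cytosol below. Each RyR occupies a 36 × 36 nm footprint
(3 × 3 voxel columns) at 36 nm pitch on the jSR surface; the jSR is the union
of RyR footprints padded laterally by `padding` RyR widths (36 nm each).
Disconnected padded patches of one CRU can be bridged into a single jSR sheet
(always done for dSTORM-derived maps, where sub-clusters of a CRU share SR).

The network SR (nSR) is modeled as a narrow neck — 108 nm long, 72 nm wide,
at the jSR z-levels — leading to a reservoir block that grows in whole 36 nm
tiles until the total SR voxel count hits an exact target (default 3.5% of
the domain). Fixing that target across geometries keeps the initial SR Ca²⁺
content identical when comparing fragmentation levels. The neck's diffusive
resistance sets the jSR refill rate independently of domain size; the
reservoir can be clamped at the initial SR concentration, which emulates the
effectively infinite network SR of a whole cell (the clamp is off for
conservation checks, which run with closed boundaries).

Quantification-lattice maps (30 nm cells) convert to the simulation lattice
by mapping one cell to one 36 nm RyR site, preserving the occupancy pattern;
all pairwise distances scale by 36/30.

## Spark simulator

**Fields and reactions.** Free Ca²⁺ diffuses in cytosol+cleft
(D = 0.22 µm²/ms) and SR (0.06 µm²/ms). Four cytosolic buffers — ATP
(455 µM, k_on 0.225 µM⁻¹ms⁻¹, k_off 45 ms⁻¹, D 0.14), calmodulin (24,
0.1, 0.038, D 0.025), troponin (70, 0.039, 0.02, stationary), Fluo-4 (25,
0.08, 0.09, D 0.042) — and calsequestrin in the SR (14 mM binding sites,
k_on 0.1, k_off 65 ms⁻¹, stationary) follow mass-action kinetics
R = k_on·c·(B_tot − b) − k_off·b. These magnitudes are the common-pool values
of the cardiac dyad modeling literature; none is fitted to data in this
package. Resting state: c₀ = 0.1 µM, s₀ = 1000 µM, buffers at binding
equilibrium.

**Numerics.** Explicit finite-volume diffusion with symmetric face fluxes
(exactly amount-conserving), forward-Euler reactions, SERCA flux
J = (a₁c² − a₂s²)/(a₃c² + a₄s² + a₅) applied as matched sink/source pairs on
the nSR/cytosol faces (coefficients chosen to balance the pump at rest;
SERCA is negligible on the spark timescale), and an *analytic* sub-solve for
the stiff RyR release pair — the SR-side and cleft-side voxel relax toward
their common mean with rate 2K (K = per-face conductance over voxel volume),
which is unconditionally stable for any step. Operator order per step:
diffusion → buffering → SERCA → release → gating. The global step is 0.1 µs
at 12 nm, set by the CFL bound 2DΣh⁻² ≤ 1, and checked at configuration
time.

**Gating.** Each RyR is a two-state (closed/open) Markov channel driven by
the mean free Ca²⁺ over its cleft-side voxels:
k⁺(c) = clamp(φ⁺c², k⁺min, k⁺max) and k⁻(c) = clamp(φ⁻c^(−1/2), k⁻min,
k⁻max), with k⁺ ∈ [10⁻⁴, 3] ms⁻¹ and k⁻ ∈ [0.3, 1.5] ms⁻¹. φ⁺ is calibrated
(shipped routine) so the opening rate reaches the midpoint of its clamped
range at exactly 80 µM — the half-maximal-activation constraint the gating
model is anchored to. φ⁻ = 5 makes openings longer at high cleft Ca²⁺
(induction-decay-style termination as the jSR depletes). Transitions flip
with probability 1 − e^(−k·dt) per step from one seeded stream; a randomly
chosen trigger RyR is forced open at t = 0 and gates freely afterwards. Runs
stop at the final RyR closure (the default), at a time cap, or immediately
upon detection/propagation when only that binary outcome is sampled.

**Fluorescence readout.** F is Ca²⁺-bound Fluo-4 weighted by a 3D Gaussian
PSF (FWHM 250 × 250 × 500 nm) sampled along a line through the cleft plane —
a linescan through the dyad. The PSF extends beyond the simulated box into
quiescent cytosol; that volume contributes its constant resting fluorescence
to F and F₀ (computed analytically per axis), so ΔF/F₀ = max over line
positions of (F − F₀)/F₀ is insensitive to the box size. Events with peak
ΔF/F₀ ≥ 0.4 count as detected sparks — the experimentally determined
detection limit.

**Desk-scale mode.** Production sweeps run on a laterally coarsened mesh
(36 × 36 × 12 nm voxels; `lateral_factor=3`) in a tight box around the CRU
(margins ~0.2 µm, z = 384 nm), with dt = 0.25 µs from the same CFL rule, an
open (Dirichlet-at-rest) boundary condition on the box faces standing in for
the surrounding cytosol, and the nSR clamp on. The 12 nm cleft/jSR vertical
structure, RyR footprints and pitch are preserved exactly by the coarsening;
a deterministic single-channel release on the 9-RyR geometry gives peak
ΔF/F₀ within ~6% of the full 12 nm mesh (asserted at 10% in the test suite).
Fidelity estimates use 20–50 runs per geometry and propagation sweeps 20 runs
per gap; these sizes give binomial CIs adequate for the ordering and
threshold statements made, and are the package's default study sizes.

**Emergent behavior** (computed by the test suite, not asserted as numbers):
single-channel and few-channel openings stay well below the 0.4 detection
limit ("quarky" release); fidelity rises steeply between 9 and 25 RyRs;
release triggered in one 9-RyR cluster propagates across contiguous jSR to a
second cluster at separations up to ~150 nm and rarely beyond; dispersed
multi-cluster CRUs at matched RyR count show lower fidelity and slower rise
(longer time to peak) than compact single-cluster CRUs.

## Linescan and microsome analysis

Baseline F₀ is the per-position temporal mean over a declared quiescent
window; the noise floor is the SD of ΔF/F₀ there. Sparks are local maxima of
lightly smoothed ΔF/F₀ above 0.4, merged within a 2 µm / 30 ms exclusion
radius; amplitude is read at the unsmoothed peak. Onset for TTP is the last
time before two consecutive samples exceed baseline + 2×noise SD; FWHM and
FDHM interpolate the half-amplitude crossings of the spatial and temporal
profiles through the peak (crossings that run off the recording flag the
measurement partial). Spark mass = amplitude × FWHM × FDHM; frequency is
normalized per 100 µm of cell and per second; spark-mediated leak = mean
mass × frequency. Sparks with TTP > 13 ms are classified "slow".

Transients: global F/F₀ is the spatial mean; local transients average
non-overlapping 2 µm bands anchored at the line start; the dyssynchrony
index is the SD of per-band TTF50 values (bands that never reach half-max
are excluded and counted).

Microsome traces calibrate via [Ca²⁺] = K_d·(R − R_min)/(R_max − R)·(S_f2/S_b2);
samples at or beyond R_max are flagged and excluded from fits. Uptake and
leak are OLS slopes over the central 20–80% of the post-ATP and
post-thapsigargin segments (avoiding mixing transients); releasable content
is the post-CMC plateau minus the leak fit extrapolated to the CMC time;
normalized leak = leak rate / releasable content.

## Synthetic data: what it does and does not emulate

Layout generation places compact blobs on the 30 nm lattice with controlled
edge-to-edge gaps (compact "Sham-like" vs fragmented "HF-like"
configurations at matched RyR totals) and can tile rows at a z-line-like
pitch for realistic field density. Blink tables draw Poisson(50) events per
RyR with 21 nm Gaussian scatter, uniform background events, and
artifact sites emitting 10–30 consecutive-frame runs at one position;
there is no camera-frame simulation, emitter photophysics, or drift.
Linescans inject separable spark kernels — Gaussian in space,
(1 − e^(−t/τ_rise))·e^(−t/τ_decay) in time, normalized to unit peak so the
requested amplitude is exact — plus cell-wide transients with per-position
onset offsets, and Gaussian noise. Microsome traces are piecewise-linear
[Ca²⁺] mapped through the inverse calibration (exact round trip at zero
noise).

Passing closed-loop tests therefore shows the pipeline recovers what these
forward models encode — localization scatter, Poisson sampling, background,
detector thresholds — not robustness to drift, anisotropic PSFs, motion, or
labeling stoichiometry beyond the one-cloud-per-RyR assumption (an epitope
dropout probability exists but defaults to 0).

## Numerical and design choices

- Exact Otsu (cumulative moments over sorted values) rather than a binned
  histogram: removes binning as a tie-break concern; degenerate (constant)
  images raise.
- Ties in blob growth and all stochastic choices run through
  `numpy.random.Generator` seeded per call; identical seeds reproduce
  outputs bit-for-bit.
- The release sub-solve conserves x + y exactly; with equal voxel volumes on
  both membrane sides this equals amount conservation (volumes are equal by
  construction here; the symmetric form is documented rather than general).
- The fused numba loop applies per-face SERCA updates sequentially and is
  compiled with fastmath; it matches the vectorized reference operators to
  ~10⁻⁷ relative, asserted in the consistency test.
- Degenerate inputs: empty blink tables filter to empty; reconstruction of
  an empty table and thresholding of a constant image raise; empty grids
  give empty cluster sets and NaN distance summaries; CRU solidity is NaN
  when all member clusters have < 5 RyRs.

## Limitations

- The desk-scale box and open-boundary approximation compress spark FDHM
  relative to a whole-cell setting; kinetics comparisons are made
  within-model, between geometries, never against absolute experimental
  durations.
- Simulated times to peak (~1–3 ms) are shorter than experimental spark rise
  times; the package's claims about kinetics are ordinal (multi-cluster
  slower than single-cluster).
- The gating model has no inter-RyR allosteric coupling or explicit luminal
  sensor; termination is induction decay (depletion-driven loss of
  regeneration) plus stochastic attrition.
- Quantification of clusters smaller than ~3 lattice cells is biased upward
  at 21 nm localization precision (see above).
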