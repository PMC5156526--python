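# Methods

This note records the models implemented in `mitodyn`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real data.

## Two-state kinetic framework

All SPT stages assume a TF population switching between a chromatin-bound
state (diffusion coefficient D_bound) and a free state (D_free), with
exponential state durations: unbinding at rate k_off and binding at a
pseudo-first-order rate k_on* (binding sites in excess). The stationary
bound fraction is F = k_on*/(k_on* + k_off). Photobleaching removes
molecules at rate k_photobleach regardless of state (constant illumination).

Named presets pin the stationary bound fractions at 0.309 (interphase) and
0.183 (mitosis) and scale the mitotic specific off-rate by 1/0.54, mirroring
the reported interphase/mitosis contrast for Sox2. The absolute interphase
D_free (2 µm²/s), D_bound (0.01 µm²/s) and switching rates are plausible
defaults for a nuclear TF, not measured values; they are configuration, not
hard-coded truth.

## Synthetic trajectories (fast tracking)

State paths are simulated in continuous time (alternating exponential
waiting times). Within each frame interval the per-axis displacement is
Gaussian with variance 2·(D_free·t_free + D_bound·t_bound) integrated over
the state path — exact for the lateral coordinates at any switching rate.
The axial coordinate performs the same walk, reflecting at ±4 µm
(`cell_half_depth`; the axial cell extent is not a measured quantity — a
bounded domain keeps the out-of-focus pool finite and lets defocused
molecules return). Reflection is folded at frame resolution. A localization
is emitted only while |z| ≤ 0.35 µm (half the ~0.7 µm detection slice), with
N(0, σ²) localization error per axis, σ = 35 nm. Detections separated by at
most one missed frame (the tracking "blinking" setting) share a trajectory.

Slow-tracking data are generated directly as dwell samples rather than
movies: at 500 ms exposures only bound molecules are detected, and the
analysis consumes dwell times, not images. Observed dwells are
min(unbinding, bleaching) floored to whole frames (minimum one frame), with
a censoring flag.

## Residence-time fitting

The survival curve S(j·Δt) = #(dwell ≥ j·Δt)/n is fitted by *unweighted*
least squares with the two-exponential model, the time axis shifted so the
first grid point is t = 0. (Whether the original analyses weighted survival
points or used a raw-dwell likelihood is not documented; unweighted survival
LS is the canonical reading, and a maximum-likelihood variant would change
the weighting, not the model.) The fit is parameterized as
(F, k_slow, Δk ≥ 0) with k_fast = k_slow + Δk, so "specific = slower
component" is enforced structurally rather than by initialization luck.
Initialization takes k_slow from a log-linear fit to the final third of the
curve and k_fast from the initial third after subtracting the slow
component; six deterministic multiplicative restarts guard against local
minima. Dwells shorter than two frames are retained by default
(`min_dwell_frames=1`).

The bleach correction k_off,s = k_slow,emp − k_photobleach requires
k_slow,emp > k_photobleach; otherwise bleaching dominates and the residence
time is unidentifiable (rejected, not extrapolated). Without correction,
1/k_slow,emp underestimates τ_s by exactly k_s/(k_s + k_pb) — the recovery
tests verify both the corrected estimate and this bias factor.

Known limitation: at 0.5 s frames a non-specific rate of ~2 s⁻¹ decays
within 1–2 frames, so k_ns is only loosely constrained; the specific (slow)
rate, which carries the biology, is the robust quantity.

## Jump-length model and defocus correction

Displacements at lags k·Δt (k = 1…7, Δt = 4.5 ms) are pooled per lag; a pair
is used only if all intermediate frames were detected (pairs spanning blink
gaps are skipped). Histograms use 10 nm bins on r ∈ [0, 1.2] µm,
density-normalized per lag.

The model density per lag is

    P(r,Δτ) = F·p(r; D_b) + Z_corr(Δτ)·(1−F)·p(r; D_f),
    p(r; D) = r/(2(DΔτ+σ²)) · exp(−r²/(4(DΔτ+σ²))),

the standard 2D Rayleigh jump density with static localization error. (The
prefactor and exponent signs follow uniquely from requiring a density with
this variance structure that integrates to one.) Because Z_corr scales only
the free term, the model is unnormalized (total mass F + Z_corr·(1−F));
fitting compares per-lag *normalized* model densities with per-lag
normalized empirical densities so both sides are proper densities and the
least-squares comparison is scale-consistent. Lags are not weighted by jump
counts.

Z_corr(Δτ) is the survival probability of a Brownian z-path in a slab with
absorbing walls, started uniformly: an alternating erfc image series
integrated over the slab by 64-point Gauss–Legendre quadrature, truncated
when the next term falls below 1e-10 (cap 100 terms), clamped to [0, 1].
Absorbing walls overestimate the loss (molecules can exit and re-enter
between observations), so the slab uses a corrected effective thickness
Δz_eff = 0.700 + 0.15716·√D_free + 0.20811 µm. The printed calibration is
typographically ambiguous (√D vs D); the a + b√D + c reading is implemented,
and the constants should not be treated as an exact calibration of any
specific microscope. A brute-force Monte Carlo absorption simulation with
Brownian-bridge wall-crossing correction serves as an independent oracle;
series+quadrature agree with it to well under 1%.

Fitting minimizes the summed squared density difference jointly across lags
with `scipy.optimize.least_squares`, diffusion coefficients in log space,
bounds F ∈ [0,1], D_free ∈ [0.15, 20] µm²/s (upper bound = the tracker's
maximal expected diffusion constant), D_bound ∈ [5e-4, 0.1] µm²/s; five
Latin-hypercube restarts plus one physically motivated start, fixed
sub-seeds, best converged restart wins. σ is fixed at 0.035 µm by default or
fitted within [0.02, 0.06] µm. Recovery tests at 48 000 jumps (24 cells ×
2000 jumps) recover F within ±0.03 of 0.309 and 0.183; a small positive bias
(~1–2 points) remains, consistent with residual mismatch between the
corrected-Δz calibration and the simulated axial geometry.

## FRAP

Normalization: I(t) = (spot − background)/(whole_cell − background), scaled
so the pre-bleach mean is 1; dividing by the whole-cell trace removes
acquisition bleaching. The bleach frame must show a drop > 3 SD of the
pre-bleach noise. The exact normalization recipe in the source literature is
by citation only; this double normalization is the field standard.

t90 is the first time the curve reaches floor + 0.9·(plateau − floor),
linearly interpolated between frames, where the plateau is the mean of the
final 10% of post-bleach frames (≥5) and the floor is the first post-bleach
point. "90% recovery" is deliberately measured from the bleach floor to the
*recovered* plateau — against 90% of the pre-bleach level, partial-recovery
curves would never qualify. Crossing detection runs on a 3-frame moving
average (floor anchored at the raw bleach point); this keeps the noiseless
error below one frame across k = 0.05–2.5 s⁻¹ and the median error with 2%
noise below one frame. The estimate is invariant under affine intensity
transforms. No model fitting is involved; a single-exponential fit is
provided for diagnostics only.

## Enrichment imaging

Cell mask: 3-class multi-Otsu on the summed channels, taking the *lowest*
threshold, holes filled, largest component kept. (A plain 2-class Otsu on a
three-class scene — background, cytoplasm, bright chromosomes — provably
splits chromosomes-vs-rest rather than cell-vs-background, so multi-Otsu is
used; a manual ROI can override.) Chromosome mask: Otsu on the H2B channel
within the cell, holes filled, components < 20 px removed; an H2B channel
whose above/below-threshold means differ by less than 50% is rejected as
having no chromosome signal. Background defaults to the median intensity
outside the cell mask (constant override available). The thresholding method
and background handling are not documented in the source literature; these
choices are recorded here.

E = log2[(mean TF on chromosomes − bg)/(mean TF over cell − bg)], the
whole-cell mean *including* chromosome pixels (this matters: excluding them
would inflate E). Time-lapse movies are re-masked per frame (chromosomes
move; no registration) and report the normalized chromosome intensity
interpolated at 60 s post addition; >10% mask failures reject the movie.

The renderer draws three-level ellipse scenes with additive camera
background and Poisson noise at a photon budget. Estimator bias is ≤ 0.1
log2 units at a budget of 10³ photons across ratios 0.5–4, and vanishes as
the budget grows.

## Fixation-artifact simulation

Geometry: a chromosome disc (R = 4 µm) concentric in a cell disc (R = 8 µm),
2D. Mobile free particles diffuse with D_free = 2 µm²/s, reflecting at the
cell boundary, bind with hazard k_on* = 2 s⁻¹ while inside the chromosome
disc; bound particles are immobile and unbind with hazard k_off
(0.5 s⁻¹ default). The initial state is the exact stationary distribution
(free uniform, bound on top inside the disc with local ratio k_on*/k_off).

The fixative front is C(r,t) = C0·erfc((R_cell − r)/√(4·D_eff·t)); every
mobile particle crosslinks with hazard k_x·C (k_x = 0.2 s⁻¹ per unit dose)
and is then frozen at its position and state forever — bound particles
crosslink at the same hazard as free ones (whether chromatin-bound TFs
crosslink at a different rate is unknown; equal hazards is the neutral
choice). `uniform_instant` mode freezes everything at t = 0.

D_eff = 0.2 µm²/s is an *effective front* diffusivity, far below the aqueous
diffusivity of free formaldehyde. This is intentional: incoming fixative is
consumed by crosslinking ("crosslinks to the nearest protein"), so the
reactive front advances much more slowly than free diffusion. A fast,
unconsumed front (tens of µm²/s) equilibrates across the cell within ~1 s,
makes the crosslinking hazard spatially uniform, and — since uniform-hazard
freezing captures the mobile ensemble at its live steady state — produces
almost no artifact and a non-monotone dose response. At D_eff = 0.2 µm²/s
the front crosses the 4 µm cytoplasmic depth in ~20 s and reaches the cell
centre in ~80 s, matching the tens-of-seconds collapse seen in
fixative-addition movies, and the dose response is strictly monotone.

The time step must satisfy dt ≤ 0.1/max(k_off, k_on*, k_x·C0) (enforced);
per-step hazards use exact exponential probabilities 1 − exp(−rate·dt).
The reported enrichment is the same statistic the imaging stage computes
(mean particle density in the disc over cell-average density), and particle
snapshots can be rendered to image pairs and pushed through the imaging
quantification as a round trip. Discrete stepping leaves a ~2% downward
offset in the no-fixation equilibrium enrichment (boundary-straddling
particles bind for partial steps); it is stable and far below the artifact
effect sizes.

Only directional predictions are testable — the source data quantify neither
k_x, the front speed, nor dose-response values — so the model is validated
on sign and ordering: dose monotonicity, k_off resistance, and exact
enrichment preservation under uniform instantaneous fixation.

## Localization linking

The greedy nearest-neighbour linker (distance ≤ max_jump per frame step,
gap closing up to the blinking tolerance, ties by distance then track id) is
plumbing for simulated localizations at low density (≲0.1 particles/µm²),
where it reconstructs ground-truth tracks exactly. It is not a
multi-hypothesis tracker and is not validated on dense real data.

## Problem sizes and determinism

Recovery tests and the acceptance script use 5000 dwell events, 48 000
jumps (24 cells × 2000), 10⁵–4·10⁵ Monte-Carlo z-paths, 128² images, and
2000-particle fixation runs with 20 replicates per condition — sizes at
which every tested tolerance is comfortably resolved by the corresponding
sampling error. All generators and fits are deterministic given a seed;
identical seeds reproduce outputs byte-for-byte.

## What the synthetic tests do not show

The generators share their statistical assumptions with the fitters, so
parameter recovery demonstrates correctness of the implementation, not
robustness to real-data pathologies: anisotropic or non-Gaussian
localization error, motion blur, detection-efficiency tapering at the slice
edges, state-dependent bleaching, chromatin motion, uneven illumination, or
segmentation on crowded fields of view. The corrected-Δz constants are taken
as printed and their calibration conditions are not reproduced here; the
small residual bias they leave on simulated data (see above) may differ on a
real microscope.
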