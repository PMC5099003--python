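# Methods

## Scope and model

`cuffshear` computes six wall-shear-stress (WSS) metrics of atherogenic flow
on triangulated lumen surfaces, segregates a cuff-instrumented vessel into
four axial regions, and compares paired instrumented/control vessels across
a cohort. Real inputs would be WSS vector fields exported from CFD on
reconstructed vessel geometry; the package instead generates synthetic
fields whose structure reproduces the cuff model's flow regimes, so that
every downstream stage (metrics, calibration, region statistics) is
exercised under controlled, seeded conditions.

## Synthetic flow generator

**Geometry.** Vessels are straight structured tubes (default 121 rings × 32
circumferential nodes, 10 mm long) aligned with +z. The instrumented lumen
has radius 311 µm (622 µm diameter) with a piecewise-linear constriction:
a 0.3 mm entry ramp to the cuff inlet radius (250 µm), a linear taper to
the cuff outlet radius (125 µm) over the cuff span (5.0–6.2 mm), and a
0.3 mm exit ramp back to the vessel radius. The control is a uniform 297 µm
(594 µm diameter) tube. The axial coordinate is the projection onto a
straight axis; curved-centerline extraction and bifurcations are out of
scope, so real meshes are assumed straight or pre-straightened.

**Inflow.** A two-harmonic waveform
U(t) = U·(1 + 0.4·sin(2πt/T) + 0.15·sin(4πt/T + π/4)), rescaled so its
sample mean is exactly U, strictly positive (no bulk reversal at the inlet).
Default means: 112.8 mm/s instrumented, 153.4 mm/s control, at 8 Hz
(T = 0.125 s), 300 steps per cycle with every 10th step retained
(30 exported instants, 0.0042 s apart). The measured in-vivo waveform shape
is not tabulated anywhere usable, so no attempt is made to match it beyond
pulsatility amplitude.

**Quasi-steady Poiseuille closure.** The flow rate Q(t) = U(t)·πR_inlet²
is conserved along the tube, and the instantaneous wall shear magnitude is
the steady fully developed value |τ|(s, t) = 4µQ(t)/(πR(s)³) with
µ = 3.5 mPa·s (Newtonian blood, justified by mean wall shear rates
8U/D > 1000 s⁻¹ at these velocities and diameters; Re ≈ 40, Womersley
number ≈ 2–3). The shear vector points along the axial direction projected
into the local tangent plane — WSS is tangent to the wall, so on the cuff
cone the direction tilts with the taper while the magnitude keeps the
Poiseuille value, preserving the |τ|·R³ mass-conservation invariant
exactly. This closure reproduces amplitude-level behaviour (cuff shear
≈ (R_vessel/R_cuff)³ × upstream shear), not entrance effects, separation
points or true vortex dynamics.

**Downstream vortex surrogate.** In the recirculation zone
(cuff exit → +2.5 mm by default), with envelope
w(s) = sin²(π·(s − s_exit)/L_zone), the axial component is multiplied by
1 − A_rev·w·(1 + sin(2πmt/T + θ)) and a circumferential component
A_circ·w·|τ_axial|·cos(2πmt/T + 2θ) is added (defaults A_rev = 1,
A_circ = 0.5, m = 2). With A_rev > 0.5 the axial shear reverses at the
envelope peak, giving OSI > 0; the circumferential term gives tSS > 0; the
(s, θ, t) dependence gives SAD > 0. The parameters are an analytic
surrogate chosen to produce the qualitative downstream regime (reversal +
multidirectionality confined to the zone), not a solved recirculation.

**Spatial heterogeneity.** Each node's whole shear history is scaled by
exp(g), g ~ N(−σ²/2, σ) with σ = 0.2 by default, making control TAWSS
log-normal by construction — the distributional form the threshold
calibration assumes — while leaving directions (hence OSI/tSS/SAD)
untouched. σ = 0.2 gives a control coefficient of variation of ≈ 20%,
a realistic node-level spread for a healthy straight segment.

**Cohorts.** Per-mouse seeds spawn deterministically from the master seed.
Mice receive mild ±10% uniform jitter on the mean inlet velocities, on the
heterogeneity spread and on the disturbance amplitudes. The last of these
is a deliberate design choice: velocity and heterogeneity scalings are
direction-preserving, so without amplitude jitter the directional metrics
would be numerically identical across animals and the between-mouse t-tests
degenerate; jittering the vortex strength restores the between-animal
variance any real cohort has.

## Metrics

All time integrals use the equal-weight rectangle rule on the uniform
30-point grid (for periodic signals on a uniform grid this coincides with
the trapezoid rule). Conventions for degenerate inputs: a node with zero
WSS throughout gets OSI = 0 and tSS = 0 (counted in the log); a vanishing
time-mean vector makes RRT an infinite sentinel that the display
normalization caps at 1. SAD is computed per instant over edge-connected
neighbours, then averaged over the cycle; node–instant pairs with a zero
vector contribute zero angle. SAD is the one metric whose published
formulation is only verbal, so the per-instant-then-average order is an
interpretation, stated here as the contract.

**Threshold calibration.** low/high = exp(m ∓ 0.67·s) with m, s the mean
and sample SD (n − 1) of ln(TAWSS_control). The multiplier is used
literally as 0.67, the printed two-decimal standard-normal 75th percentile
(not 0.6745). Thresholds are calibrated per mouse from its own
contralateral control by default; a pooled-cohort mode is available. LSI
and HSI are clamped to zero outside their windows, so LSI·HSI = 0
everywhere and TAWSS between the thresholds is "normal" — absence of one
index does not imply presence of the other.

**Display normalization.** OSI, SAD, LSI, HSI divide by their theoretical
maxima (0.5, π, 1, 1). TAWSS, tSS and RRT have no finite theoretical
maximum and divide by the observed maximum over all vessels of the cohort;
this choice is flagged in the run manifest since it makes those three
columns cohort-relative.

## Region statistics

Region means are unweighted node averages (structured tubes have
near-uniform node density; the area-weighted mean differs by < 1% there).
Per-mouse region means below 0.005 are floored at 0.005 — "near zero" is
read as "below the floor", applied on the display-normalized scale — and
all values are divided by the cohort mean of the control values for that
(region, metric), so scaled controls average exactly 1 and instrumented
values read as fold factors. Instrumented-vs-control tests are one-tailed
two-sample equal-variance t-tests (H₁: instrumented > control), unpaired by
default; the vessels are contralateral pairs, so a paired mode is provided
in the config for users who prefer it. No multiple-testing correction is
applied — each metric is compared only against its own control, and this
is documented rather than silently changed. Zero-variance degenerate cases
use the convention t = 0, p = 0.5 for equal means. One-way ANOVA is
provided for velocity/diameter-style group comparisons.

## Numerical choices and tolerances

- STL vertex merge tolerance 1e-6 mm (STL is a triangle soup; merging is
  required before adjacency); file normals are ignored and recomputed
  area-weighted from geometry. Zero-area triangles are dropped and counted.
- Region boundary ties go to the more distal region, so the cuff interval
  is closed; the upstream plaque region is [s_cuff − 1.6 mm, s_cuff). The
  1.6 mm extent comes from histological plaque length (shrinkage-corrected)
  and is a config parameter, measured as straight-line axial distance.
- Control regions are anchored to the distal vessel end: boundaries sit at
  the same distance from the outlet as in the instrumented vessel.
- Metrics at the 30-instant export stride agree with a 300-instant
  computation to within 2% provided the field stays short of the full
  angle-reversal limit; at full reversal the neighbour-angle integrand is
  discontinuous in time (0 → π jumps) and SAD's stride error grows to a
  few percent, an intrinsic property of sampling a discontinuous integrand
  rather than of the implementation.
- The whole pipeline is a pure function of (config, master seed); repeated
  runs are byte-identical, which the test suite checks on file output.

## What the synthetic data does and does not show

Passing tests demonstrate that the metric definitions, calibration,
segmentation and statistics behave correctly on fields with the cuff
model's qualitative structure (low/high/oscillatory regimes in the right
regions, log-normal control TAWSS). They do not validate magnitudes
against in-vivo CFD: the synthetic closure has no entrance or separation
effects, no curved geometry or bifurcations, rigid walls, and a parametric
rather than solved vortex, so in-vivo quantities (velocities, Fig.-style
bar heights, specific fold factors) are outside what this package claims
to reproduce. Problem sizes in the default configuration — 121×32-node
meshes, 30 exported instants, 7 mice — keep a full cohort analysis under
ten seconds on one CPU.
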