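# Methods

This note documents the models, numerical choices, and limitations behind
`pwv4d`. Everything quantitative stated here is computed by the test suite
or the pipeline itself.

## Phantom model

The phantom is a **prescribed-flow traveling-wave model**, not a
fluid-structure simulation. Its purpose is to test an estimator, so the
quantity the estimator targets — the wave transit delay — is encoded
exactly:

    Q(s, t) = D(s) · Q_in(t − s / PWV_true),        D(s) = exp(−s / L_d)

where `s` is arclength (mm) from the inlet, `Q_in` the inflow waveform,
and `D(s)` an optional exponential damping. The lumen is a linearly
tapered tube (default radii 18 → 10 mm over 250 mm, i.e. diameters
36 → 20 mm) whose radius breathes with the local flow:

    R(s, t) = R0(s) · sqrt(1 + α · (Q − Qmin) / (Qmax − Qmin))

so the **peak relative area change equals α exactly** (0.06 for the
compliant configuration, 0.002 for the nearly rigid one). Axial velocity
follows a parabolic (default) or plug profile; a plug option is retained
because pump-driven in vitro profiles are blunt. Mass is not exactly
conserved when α > 0 or damping is active — this is deliberate and
documented; conservation tests are restricted to the rigid, undamped case,
where net flow per cycle matches the stroke volume to < 2 % at any plane.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| stroke volume / RR | 71.2 mL / 1000 ms | programmed pump conditions |
| peak-flow cap | 300 mL/s | pump hardware limit; the waveform is uniformly down-scaled to the cap if exceeded, and the realized stroke volume reported |
| systole | cosine-squared, onset 50 ms, 500 ms wide | broad, pump-limited pulse whose 71.2 mL cycle integral stays under the 300 mL/s cap without truncation (peak ≈ 272 mL/s) |
| diastolic lobe | 15 % of systolic peak at 0.66·RR | the secondary flow-rate peak seen in pump-driven aortic waveforms |
| compliance α | 0.06 compliant / 0.002 rigid | the compliant wall's measured systolic area change exceeds 5 %, so the true change must exceed 5 % strictly (frame averaging can only attenuate the measured peak); the rigid wall stays below 1 % |
| damping length L_d | 648 mm | exp(−250/648) = 0.68: reproduces a 68 % descending-aorta flow split over the tube length, and keeps distal centerline velocity just under Venc |
| grid / Venc / frames | 2.5 mm iso, 120 cm/s, 20/40/62.5 ms | 4D-flow protocol values; Venc sits just above peak systolic velocity |
| noise | 3 cm/s per component, Gaussian | moderate phase-contrast velocity noise (2.5 % of Venc); additive per component, no Rician magnitude noise — velocity is the analysis target |
| axis offset | (0.37, 0.61) mm | a generic transverse axis position; a grid-aligned axis correlates boundary-voxelization errors around the lumen ring and biases areas by several percent |

**Temporal resolution** is emulated by boxcar averaging: the tube is
simulated at 1 ms substeps and each stored frame is the mean over its
frame interval, stamped at the frame center. This reproduces the smoothing
direction of segmented k-space acquisition but not its exact temporal
point-spread (view ordering and sharing are scanner-specific and out of
scope). An important consequence, verified analytically and numerically:
any plane-independent temporal smoothing leaves TTF *differences* — hence
the fitted PWV — unchanged to first order; what remains at coarse sampling
is cubic-spline reconstruction error, which is periodic in the foot's
phase relative to the frame grid. At the default conditions this produces
the expected behavior (estimates at 62.5 ms fall ~2–3 % below 20 ms, with
the 40 ms point in between), but the *magnitude* of the bias in real
segmented acquisitions is not reproduced by frame averaging alone.

**Magnitude images** encode the partial-volume lumen fraction (3×3×3
supersampling; the boxcar over substeps is computed exactly by counting
substep radii via a sorted search). A static gel block fills the remainder
of the volume at lower intensity; it is disjoint from the lumen at every
frame and serves the offset correction. Besides the 4-D flow magnitude, a
separate high-resolution (1 mm) structural volume emulates the steady-flow
anatomical scan: segmentation operates on it, because a binary mask at the
2.5 mm flow resolution carries several-percent cross-sectional area
quantization. Velocities beyond Venc are clipped and counted (real
phase-contrast data would wrap; clipping keeps the generator monotone and
flags the condition loudly).

Everything is seeded: identical spec and seed give bit-identical volumes.

## Offset correction

Each velocity component's time-mean over the static region is fitted by
ordinary least squares to `a + b·x + c·y + d·z` in physical mm
coordinates, and the plane subtracted from every frame everywhere. The fit
is strictly first order, on the time average by default (offsets are
modeled as time-stationary; a per-frame variant exists behind a flag).
Degenerate static regions (rank-deficient design, e.g. a single voxel
plane) are an error; fewer than 50 voxels warns. The correction is
idempotent and affine in position by construction; injected offsets are
recovered to 1e−6 noiselessly.

## Geometry

*Segmentation* is seeded 3-D region growing: voxels at or above
`threshold_fraction` (default 0.5) times the seed-neighborhood median are
candidates; the 26-connected component containing the seed is closed with
a 1-voxel ball and reduced to its largest component. The threshold is
relative, so segmentation is invariant to global intensity scaling. The
default seed is the centroid of the brightest voxels — the first-in-memory
maximum can sit on the lumen boundary, where the neighborhood median (and
with it the threshold) is depressed.

*Centerline*: 3-D thinning skeleton; the longest endpoint-to-endpoint
geodesic through the 26-connected skeleton graph (Dijkstra with physical
edge lengths) resolves branching; the path is smoothed by a 5-point moving
average and resampled to 1 mm arclength steps. Two practical corrections:
(1) thinning erodes a few voxels at each skeleton tip, so both ends are
prolonged along their tangents until the interpolated mask drops below the
0.5 iso-level — without this the arclength underestimates tube length by
5–15 %; (2) thinning can annihilate tubes whose cross-section has an
even-width plateau (no unique medial voxel); a one-sided single-voxel
dilation breaks the tie at the cost of < 1 voxel of bias. The path
direction out of the skeleton is arbitrary; `orient_centerline_by_flow`
fixes the proximal→distal orientation by the sign of the time-mean
through-plane velocity probed at interior centerline points, after which
landmarks (`LSA`, `outlet`, defaults at 10 % and 90 % of arclength) are
assigned.

*Planes*: centers at equidistant arclengths (default 5 mm); normals are
centered-difference tangents evaluated over the plane-spacing scale —
half-voxel skeleton wobble would tilt a 1 mm centered difference by up to
~10°, inflating areas by 1/cos of the tilt. *Cross-sections* sample the
binary mask on the oriented in-plane grid (default step: half the mask
voxel) by trilinear interpolation, threshold at the 0.5 iso-level, and
keep the connected region containing the plane center. On analytic
cylinders this reproduces transverse and 30°-oblique section areas to
within 2–3 %.

## Flow metrics

Flow rate is the discrete surface integral of the normal velocity over the
in-plane lumen pixels (cm/s · mm² · 10⁻² → mL/s); net flow is the
periodic trapezoidal integral over the cycle (equal to mean(Q)·RR on a
uniform grid). Mean/max speed are taken over the lumen contour; the max
discards pixels whose interpolated lumen fraction falls below 0.5, a guard
against spurious near-boundary values (configurable off). The area-change
series re-derives the in-plane contour from each magnitude frame with the
same region rule and reports change relative to frame 0; frames whose
contour vanishes are flagged, not fatal. Flow splits are percentages of
the inlet net flow with the residual reported.

## PWV estimation

TTF: cubic spline (not-a-knot, the default of a generic cubic
interpolation) to a 1 ms dense grid; global peak; the final pre-peak
upstroke located as the stretch from the last sample at or below 20 % of
peak to the next sample at or above 80 %; an OLS line through *all* dense
samples inside the 20–80 % band (more stable under noise than the two
crossing points alone); TTF is its x-intercept. Degenerate waveforms
(non-positive peak, thresholds not crossed, band shorter than two samples)
raise, and the series assembler records them as excluded planes.

LSE: OLS of TTF on arclength with iterative gross-outlier exclusion. A
point is excluded when its deviation from the line fitted to the
*remaining* points exceeds 100× that fit's RMSE; this delete-one form is
necessary because for any single fit max|residual| ≤ sqrt(n)·RMSE, so no
point can ever exceed a 100×RMSE threshold measured against a fit that
includes it. Validity gate: PWV is withheld when the slope is non-positive
or R² < 0.3 (configurable) — the situation produced by nearly rigid
vessels whose transit time across the analysis segment is below the TTF
resolution, where no credible linear TTF-distance relation exists.

RANSAC: 2-point minimal samples, 1000 iterations, inlier threshold
1.4826 × median absolute deviation of the initial OLS residuals (a robust
sigma), final refit on the largest consensus set; seeded. The
implementation wraps scikit-learn's `RANSACRegressor`; tests cross-check
it against an exhaustive search over all point pairs. With ≤ 20 % planted
gross outliers RANSAC beats LSE in ≥ 95 % of seeded repetitions.

Units: TTF in ms against distance in mm makes PWV = 1/slope in m/s with no
conversion factors.

`moens_korteweg` evaluates the closed form; the default fluid density used
with it in examples is 1100 kg/m³ (a 40/60 glycerol-water mixture).

## Wall material

Nominal stress is the thin-wall relation σ = P·r/h (mmHg converted at
133.322 Pa/mmHg; the unit must be stated). The tangent modulus E_t at an
operating stress locates the operating strain by monotone interpolation
and differentiates a local quadratic fit over a ±0.02 strain window —
noise-robust compared to a two-point difference, and stable to within 2 %
under window halving on smooth curves.

## Problem sizes used in the tests

The default phantom is a 250 mm tube at 2.5 mm voxels (≈ 29×29×100 grid)
with 50/25/16 frames per cycle and a 1 mm structural volume for
segmentation; analysis uses ~40 planes at 5 mm spacing. One full chain
runs in a few seconds, so the end-to-end suite covers wave speeds of
4/6/8 m/s, three temporal resolutions, and compliant/rigid configurations
in under a minute.

## What the phantom does and does not show

Passing the end-to-end tests demonstrates that the geometric and temporal
machinery — segmentation, centerline, oriented resampling, flow
integration, spline TTF, regression — recovers a known wave speed under
controlled conditions, with realistic discretization, partial-volume, and
noise effects. It does **not** demonstrate robustness to features the
generator omits: secondary/helical flow and wave reflections at branches,
dispersion of the wavefront, k-space-specific temporal blurring, phase
wrapping, B0/Maxwell/gradient-nonlinearity residuals, or anatomically
curved multi-branch geometry (a single optional circular-arc bend is the
only curvature). Measured-PWV comparisons on acquired datasets remain the
benchmark for those effects.
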