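# placodyn — methods note

## The measurement problem

Apically constricting placodes are curved: a single confocal slice cuts
obliquely through the tissue, so per-cell quantities must be measured in a
thin shell that follows the apical surface.  On top of that geometry, the
biology of interest is *oscillatory*: medial myosin II pulses every few
minutes and couples, with a lag, to transient constrictions of the apical
area.  The package therefore separates (i) recovering a quasi-2D view of the
apical surface, (ii) building per-cell time series, and (iii) oscillation
statistics on those series.

## Synthetic placode model

The generator produces the raw data the pipeline is specified against, with
full ground truth.

**Geometry.**  Cells are the Voronoi diagram of a hexagonal lattice jittered
by a fraction (default 0.35) of the lattice pitch, clipped to a rectangular
domain by mirroring sites across the four edges, so the polygons tile the
domain exactly and cell areas always sum to the domain area.  Cells whose
site falls inside a configurable ellipse are *placodal*; the rest stand in
for surrounding epidermis.  The invagination pit sits off-center inside the
placode (cf. the dorsal-posterior corner where constriction initiates in the
salivary-gland placode).

**Oscillations.**  Each placodal cell i oscillates with period
Tᵢ ~ N(150 s, 15 s²) (matching the observed ~120–180 s range of medial
myosin cycles) and a uniform random initial phase.  The waveform is a raised
cosine rc(φ) = (1 − cos 2πφ)/2 — smooth, single-peaked; the pulse shape is
not otherwise constrained by observation.  Medial myosin is
mᵢ(t) = m₀ + aᵢ·rc(φᵢ(t)) with baseline m₀ = 20 grayscale units (gs) and
amplitude aᵢ = 10 gs scaled down linearly with radial distance from the pit
(`radial_gradient` = 0.5: 50% loss at the placode edge), emulating the
observed decline of myosin activity away from the pit.

**Constriction.**  The apical area executes, per cycle, a constriction pulse
of depth ΔAᵢ = g·(aᵢ/2)·Tᵢ/60 (g = `constriction_gain`, 0.25 µm² per
gs·min; aᵢ/2 is the cycle-mean myosin excess), whose waveform is the myosin
waveform delayed by `lag_cycles` (default 0.125, i.e. one-eighth of a
cycle), plus a ratchet: `ratchet_fraction` (default 0.3) of each pulse is
retained as a linear constriction trend:

    Aᵢ(t) = Aᵢ(0) − ΔAᵢ·rc(φᵢ(t) − lag) − ratchet·ΔAᵢ·t/Tᵢ.

Writing the area waveform directly (rather than integrating a rate
proportional to lagged myosin) keeps the myosin → inverse-radius phase
difference equal to the configured lag *exactly*, which is what makes the
generator usable as a phase-recovery oracle; integrating the rate would add
a quarter-cycle of its own.  Parameters that would drive any area
non-positive within the simulated duration are rejected up front.

**Polygon realization.**  Target areas are realized on the tiling by a
conforming vertex relaxation: every vertex moves to the average of the
positions requested by its incident cells (each cell asking for an isotropic
rescaling about its centroid toward its target area), with domain-boundary
vertices pinned to the rectangle.  Shared vertices move consistently, so the
tiling never tears; because the targets are not exactly feasible on a fixed
domain, the iteration (40 sweeps/frame) converges to a compromise that
retains ~97% of the oscillation amplitude with no measurable phase shift.
The ground-truth table records the *analytic* areas (exactly lag-faithful);
the polygons are the rendered realization.

**Rendering.**  The scene is painted into a (t, z, channel, y, x) stack at
0.25 µm/pixel laterally and 1 µm z-steps, 20 s frame interval.  The apical
surface is a Gaussian dome (4 µm over an 80 µm field) by default; signal at
height h is split between the two nearest slices with linear weights, as
optical sectioning does.  The membrane channel is the cell-boundary skeleton;
the myosin channel paints each cell's true medial value inside the polygon
eroded by 0.5 µm plus a constant junctional band (12 gs) and an epidermal
level (8 gs) outside the placode.  A fraction (0.2) of each cell's
*pulsatile* medial pool is concentrated into a Gaussian blob orbiting the
medial centroid (emulating myosin flows) — normalized so the medial mask
mean equals the truth value exactly, and scaled by the instantaneous myosin
excess so non-pulsing cells image as uniform sheets.  A Gaussian PSF
(σ = 0.3 µm lateral / 0.6 µm axial), uniform background (3 gs), scaled
Poisson photon noise and Gaussian read noise complete the model.

**Noise calibration.**  The activity thresholds (0.5 for myosin, 0.005 for
radius) are fixed numbers in arbitrary signal units, so the imaging model
must be calibrated relative to them: the defaults (100 photons per grayscale
unit, read σ = 0.25 gs) put the noise-floor activity of a non-oscillating
cell trace near 0.3 — below threshold — while the default oscillation
produces activities near 4.  Under this calibration a zero-amplitude movie
yields ~0.1% spuriously fluctuating instances through the full imaging
pipeline (exactly 0% on the generated traces themselves), and a movie with
amplitude scaled to 10% stays below 10%.

**What the generator does not emulate.**  No mechanics (no force balance or
vertex-model energetics — geometry follows prescribed areas), no cell
intercalation or division (the modeled tissue is postmitotic), no junctional
myosin dynamics, no photobleaching or drift, no supracellular actomyosin
cable.  Passing the recovery tests therefore demonstrates that the
measurement chain is unbiased for data of this statistical structure, not
that it is robust to every artifact of real microscopy.

## Pipeline components and defaults

| parameter | default | rationale |
|---|---|---|
| projection thickness | 1.0 µm (config: 1.0 or 1.5) | thin apical shell below the blanket |
| blanket smoothness bound | 1 µm height / µm lateral | placodes are gently curved |
| watershed normalization block | 15 µm | larger than one cell, smaller than the field |
| seed minimum separation | 2 µm | below the smallest expected apex diameter |
| junctional band width | 1.0 µm | clears the PSF-blurred junctional signal |
| detrend boxcar | 360 s | longer than the longest expected cycle |
| extremum prominence | 0.2 × detrended σ | rejects sub-noise wiggles |
| activity thresholds | 0.5 (myosin), 0.005 (radius) | fixed classification values |
| QC | area 2–150 µm², rel. speed ≤ 5 µm/min, \|d ln A/dt\| ≤ 3 min⁻¹, ≥ 6 frames, drop edge cells | rule types are standard; values chosen for 20 s sampling |
| phase bins | 16 | ~45+ instances per bin on the reference scene |
| radial bin width | 5 µm | matches the granularity of radial-band reporting |

**Blanket fit.**  The column score is the Gaussian-smoothed membrane
intensity.  The exact 2D maximum-score surface under a hard Lipschitz bound
is an expensive MRF problem; instead the score is block-averaged laterally
(2 µm blocks), the per-column argmax is regularized by a 3×3 median and a
Gaussian (σ = 1 block), bilinearly upsampled, and finally projected onto the
Lipschitz cone by iterated lower-envelope clipping (h ← min(h, erosion(h) +
bound·pixel)).  A zero bound degenerates to the single globally best slice.
Each frame is fitted independently; the mean frame-to-frame surface
displacement is reported as a diagnostic.

**Projection.**  Max intensity over z ∈ [h, h + thickness], endpoints
rounded to the nearer slice and inclusive — at 1 µm z-steps a 1 µm layer
spans exactly two slices.  Slabs reaching past the stack are clamped with a
logged warning.

**Adaptive watershed.**  The membrane image is locally normalized
((I − µ)/(σ + ε) over the block; ε scales with the image range, making
labels exactly invariant to positive rescaling), smoothed, and flooded from
the regional minima that survive an h-minima transform; seeds closer than
the minimum separation are merged keeping the deeper one (a seed is
represented by its deepest pixel, which keeps non-convex plateau regions
well-behaved).  Basin boundaries are labeled 0.

**Linking and QC.**  Greedy maximal-overlap matching; a link requires the
overlap to cover ≥ 0.5 of the smaller region; ties break by larger overlap,
then smaller label id.  QC only flags instances (geometry untouched);
relative speed uses central-difference centroid velocities minus the mean
velocity of label-adjacent neighbors.  Manual outline correction is replaced
by an importable pixel/label edit table.

**Traces and cycles.**  Medial/junctional means subtract the per-frame mean
over the epidermal (non-placode) mask and floor at 0; an emptied medial
region is *missing*, not zero.  Detrending is an exactly-decomposing
centered boxcar, truncated at trace ends (only the first/last 3 min are
affected).  Myosin cycles run trough→trough on the detrended trace, radius
cycles peak→peak; phase advances linearly in time within a cycle, 0 at the
opening extremum; the sample shared by two cycles belongs to the earlier
one.  The fraction of fluctuating instances is reported with two
denominators: all instances of analyzable tracks (inclusive, the headline
number) and only instances between a trace's first and last detected
extremum (strict).

**Phase lead.**  Cycle instances are pooled into phase bins with 1.96·SEM
CIs.  The lead of myosin over the inverse radius is estimated from the first
circular harmonic of the bin means (continuous in phase, robust to bin-width
quantization); the coarser bin-argmax difference is also computed and
exposed (`lead_cycles_argmax`).  Lead is reported in [−0.5, 0.5) cycles,
positive = myosin ahead.

**Radius convention.**  "Cell radius" is the equivalent-circle radius
√(A/π) by default; a mean centroid-to-vertex radius is available behind the
same switch.  The inverse radius (not the radius) enters the lag analysis.

**Tissue area rate.**  Radial profiles of contraction use the pooled
per-cell d(ln A)/dt from centered 60 s least-squares windows; no
tissue-tensor strain-rate decomposition (shape vs intercalation) is
attempted — the modeled tissue does not intercalate.

**Statistics.**  KS is two-sided with the asymptotic p; the G test uses
G = 2 Σ O ln(O/E), df = (r−1)(c−1), rejecting zero margins; the t test pools
variances by default ("Student"), with Welch as an option.  Two degenerate
equal-constant samples give t = 0, p = 1; separated constants give p = 0.
No multiple-testing correction is applied; p-values are reported
individually.

## Problem sizes

The reference scene is an 80×80 µm field of 250 cells (~150 placodal),
15 min at 20 s sampling (46 frames), 320×320×10 voxels — about 790 pooled
myosin cycles per run.  Integration tests additionally use a 100-cell,
50×50 µm, 11-min scene.  The acceptance script runs the reference scene
once end to end plus single-frame fidelity checks (~1 minute total on one
CPU).

## Known limitations

* The blanket fit is a regularized heuristic, not the exact constrained
  optimum; on surfaces steeper than the smoothness bound it will lag the
  true surface.
* Segmentation has no split/merge correction beyond the edit table; heavily
  over-/under-segmented frames degrade linking silently (QC then drops the
  affected tracks).
* The fluctuating/non-fluctuating classification inherits the arbitrariness
  of fixed activity thresholds; they are meaningful only under a stated
  intensity calibration.
* Areas measured from watershed basins exclude the 1-px boundary line and so
  underestimate polygon areas by a roughly constant factor; detrended and
  relative quantities are unaffected.
* Phase-lead estimation assumes a common lag across cells; cell-to-cell lag
  heterogeneity is averaged, not modeled.
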