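# Methods

This note documents the models, estimators and numerical choices behind
`cupmap`, in the spirit of a methods appendix: what is computed, under what
assumptions, with which defaults, and where the known limits are.

## Synthetic scenes

The image-analysis pipeline is developed and validated against synthetic
cells whose ground truth is analytic.

**Geometry.** The cell is a sphere of radius R (default 5 μm). A cup of
opening half-angle α is created by reflecting the spherical cap around the
cup axis through the plane of its rim circle. The reflection is an isometry
of the cap, which has two consequences: the ground-truth domain (the
reflected cap) has *exact* closed forms — area 2πR²(1−cos α), rim perimeter
2πR sin α, geodesic depth Rα — and a mesh built by applying the reflection
to icosphere vertices keeps the intrinsic sampling quality of the sphere.
Mean curvature is exactly −1/R on the cup's inner face and +1/R outside,
with a sharp convex crease at the rim. A narrow Gaussian ring (height
0.25 μm, σ 0.10 μm, crest 0.3 μm outside the rim) provides the raised lip;
it decays to ~1% of its height at the rim circle so the cap's closed forms
are not perturbed. Opening angles are limited to α < π/4, where the dented
shape is star-convex, so the binary cell mask can be rasterised exactly
from a radius function.

**Dynamics.** Cup area grows linearly at an expansion rate (default
0.3 μm² s⁻¹) until a stall fraction of the lifetime (default 0.6), then
holds — the life history the analysis is designed to recover. The tabular
generator (`make_domain_timeseries`) additionally tapers the perimeter to
zero over the final 20 s to emulate lip closure; cohort expansion rates are
Gaussian (mean 0.3, SD 0.34 μm² s⁻¹ by default, matching measured spread),
lifetimes uniform in 30–130 s.

**Photometry.** The PIP3 channel paints the cup's inner face with a linear
base-to-lip gradient (default ratio 3:1) on top of a membrane-wide
background (default 30 counts, needed for fold normalization to be
meaningful), with a half-Gaussian spill-over past the rim (default
0.3 μm). The actin channel is a uniform shell with Gaussian lip enrichment.
Volumes are rendered by evaluating a Gaussian shell of width `blur_sigma`
around densely sampled surface points on an anisotropic voxel grid
(0.104, 0.104, 0.163 μm), then applying Poisson noise. `blur_sigma`
defaults to 0.30 μm, about twice the coarsest voxel pitch: a thinner shell
is not Nyquist-sampled by the z-grid and trilinear interpolation then clips
its peak by ~10%, which would corrupt any projection-fidelity measurement
regardless of the projector. The generator emulates shapes, life histories
and counting noise; it does not emulate the true lattice light-sheet PSF,
deconvolution artefacts, cytoplasmic autofluorescence or multi-cell
crowding, so passing tests demonstrate correctness of the measurement
chain, not robustness to every property of real data.

## Surface measurements

**Curvature** uses the cotangent Laplacian with Meyer mixed-Voronoi vertex
areas, signed by the outward normal (convex cell body positive). On
icospheres of ≥2562 vertices the worst-case error against 1/R is below 5%.

**Geodesics** are shortest paths on the edge graph (Dijkstra) with
Euclidean weights — an upper bound on true surface distance (≤8% on
icosphere great circles), chosen because every consumer (band partitions,
depth, Voronoi splitting) only needs a consistent metric. Where a distance
to a region boundary is needed, the mean of distances to the inner and
outer boundary vertex rings is used: the true cut lies between them, and
averaging removes the half-edge quantisation bias.

**Region geometry.** Area sums faces weighted by their fraction of inside
vertices (unbiased for random cuts); perimeter is the boundary loop length
after one pass of a [1/4, 1/2, 1/4] smoothing kernel, which cancels the
alternating zigzag of edge-graph boundaries (raw edge sums overestimate a
geodesic circle by up to ~13%); depth is the maximum centred boundary
distance over the region. At icosphere level 4 these agree with spherical
cap closed forms to within 5% once the cap radius exceeds roughly nine
edge lengths; smaller regions are boundary-quantisation limited, which is
why validation draws cap angles from [0.7, 1.2] rad.

**Projection.** Line scans run from 0.2 μm inside to 1.0 μm outside the
surface (1.5 μm for actin) along the outward vertex normal, sampled at half
the smallest voxel edge with trilinear interpolation, taking the maximum.
Scans truncate at the first sample closer to another surface vertex (the
scan's own two-ring excluded) than to its own vertex; outward truncation is
floored at 2 voxels so curved patches keep a scan, the inward leg truncates
without a floor so thin sheets never leak signal across their midplane.
The actin projection first retracts the surface by mean-curvature flow
applied only where H > 0 (explicit steps capped at 0.05 μm, stopping when
any vertex has moved a configurable budget, 5 μm by default), then scans
from the retracted vertices; this reaches the cortex lying below sharply
convex lips that plain scans cannot reach because of truncation.

**Segmentation.** Per marker, the Otsu threshold is computed on the exact
value histogram (maximising between-class variance over all cuts, which
makes segmentation exactly equivariant under affine intensity maps) over
the marker's geodesic Voronoi cell capped at 5 μm; the cup is the
connected supra-threshold concave component about the marker; the lip is
the 0.2 μm geodesic band outside the cup boundary with the highest mean
curvature (ties to the nearer band); the domain is the supra-threshold
part of the region enclosed by the lip (enclosure is tested against the
one-ring-dilated band so single-vertex gaps cannot leak), cleaned with
dilate ×2, fill, erode ×2. Sub-threshold markers get the minimal false
domain (marker vertex plus face-sharing neighbours); false↔true
transitions define formation/elimination; structures shared by two markers
are split along equal geodesic distance with ties to the lower track id.
On a coarse mesh the lip band can fail to enclose a region; the
segmentation then falls back to the smoothed cup with a warning.

**Profiles and life histories** follow the measurement conventions
described in the README: 10 inside bands of 0.1 × depth, 0.2 μm outside
bands, fold normalization by the median-over-lifetime mean of the 5 μm
band, per-domain averaging before cohort aggregation, linear interpolation
on a 2.5 s grid before closure for space-time maps, and double
normalization (20 time points on [0, 1]; division by the cohort-level 75th
percentile, chosen over per-track percentiles so relative domain sizes
survive averaging). Tracks graded split or erroneous in a window are
excluded from that window. The domain depth metric is geodesic, consistent
with the banding.

## The contour model

The cell cross-section is a closed polyline (initially a circle of radius
5 μm with 1000 segments and a 0.02 μm PIP3 patch) moving with overdamped
dynamics dx/dt = F/drag, drag = 1.

* **Tension**: each segment is a linear spring about its rest length
  (k_T × strain along the tangents). Rest lengths are the initial chord
  lengths, so the start state is an exact discrete equilibrium.
* **Bending**: E = (k_B/2) Σ θ_i²/ā_i, the squared turning angle per unit
  arclength — a discrete curvature-squared energy with an analytic
  gradient (verified against finite differences).
* **Area**: a pressure-like force −k_A (A/A₀ − 1) applied along the area
  gradient keeps the enclosed (cytoplasmic) area within ~2% of its initial
  value.
* **Polymerization**: k_P times a normalised Gaussian (σ = 0.25 μm) of
  arclength distance to each domain endpoint, along the outward normal,
  weighted by the local vertex length so the total applied force per
  boundary is k_P.
* **Retrograde load** (optional): the reaction to the polymerization force,
  scaled by a coupling in [0, 1], distributed over the domain arc along the
  membrane toward the domain midpoint; the total applied magnitude equals
  coupling × the summed polymerization force exactly.

The domain arc is tracked by the material (rest-arclength) coordinates of
its two endpoints. While expanding, the physical arc length obeys
dd/dt = v_P/d (v_P = 0.1 μm² s⁻¹), both endpoints advancing symmetrically;
after the stall time the endpoints are frozen in material coordinates, so
the domain's material extent is conserved to machine precision even though
its physical length changes as the membrane stretches. Remeshing resamples
the polyline to uniform physical spacing along a periodic cubic spline
(linear resampling cuts corners and drifts the readouts), assigning each
new segment the material content of its span, so elastic state and the
endpoints are preserved; per-event readout drift is below 0.1% once the
domain is larger than ~1.5 μm.

**Integration** is first-order IMEX: forces are evaluated explicitly and
filtered through (1 + dt λ_k)⁻¹ in Fourier space, with λ_k an upper bound
on the tension (graph Laplacian, k_T/rest) and bending (biharmonic,
1.5 k_B/ℓ³) stiffness. This is unconditionally stable for the stiff terms,
leaving dt (default cap 2 ms; vertex displacement additionally capped at
0.01 μm) set by accuracy. A numba kernel computes the forces; the vectorised
numpy implementation is retained as the cross-checked reference.

**Outcomes.** Self-contact is detected between vertices within twice the
target segment length in space but more than 1 μm apart in arclength.
Contact with both points within 2 μm (arclength) of a domain endpoint is a
lip closure; the sealed vesicle is the contour arc containing the domain
midpoint, closed by the contact chord and revolved about the cup symmetry
axis (frustum formulas; a revolved semicircle reproduces sphere area and
volume to 0.5% at 1000 segments). Contact further away is a wall/waist
contact, reported as a tube that is a candidate for base closure. Without
contact, depth/width ≥ 2 is a tube and anything else an open cup.

**Parameter window.** The model's force coefficients are defined by this
package's discretization (per-boundary total force k_P, spring-constant
k_T), so their numerical values are not comparable to other formulations
of the same physics; the outcome regimes, not coefficient values, are the
reproducible content. k_B = 0.05 and k_A = 50 are held constant
everywhere. With v_P = 0.1 μm² s⁻¹ and drag 1, protrusion velocities are
O(0.1 μm/s) when k_P is O(1), and the three outcome classes appear for k_T
roughly in [0.01, 0.2] and k_P in [1, 8]: low polymerization or stiff
membranes leave shallow or bowl-shaped open cups; strong polymerization
elongates the crown into a tube whose walls meet (the base-closure
candidate); and on the boundary between those two regimes the stalled rim
curls over the mouth and seals — a lip closure. A known limitation of this
formulation: the lip-closure outcome occupies only a thin band of the
(k_T, k_P) plane rather than an extended region, and the vesicles it seals
are narrow pouches of small revolved volume. With an extensible elastic
contour, a stalled cup either everts (the domain membrane balloons through
the mouth, since the rim force also loads the cup floor) or tubulates
before the mouth seals; calibration over two bending discretizations and
two orders of magnitude in each coefficient did not widen the band. As a
result, trends *within* the lip-closure region (how vesicle volume and
closure time vary with distance to the regime boundary) are not
measurable here, and the corresponding acceptance checks fail; the class
structure itself, its monotone arrangement along k_P, and the deepening
effect of retrograde coupling are reproduced. Near the regime boundary the
deterministic trajectories are sensitive to discretization detail, so the
boundary itself shifts with resolution. The validation phase scan runs at
400 segments with a 5 ms step cap and a 600 s horizon, reduced from the
1000-segment reference configuration to keep a 5×5 grid within minutes of
compute.

## Base closure

A delaminated cylindrical membrane section (length l, width w, end rings
pinned at radius w/2) moves with normal velocity proportional to mean
curvature of its surface of revolution; in graph form
dr/dt = ½(r''/(1+r'²) − 1/r), discretised on 257 axial nodes with the
quasilinear diffusion implicit (tridiagonal solves, lagged coefficients)
and the −1/(2r) focusing term explicit with dt shrinking near the pinch.
Surface area is checked to be non-increasing along every run. Pinch-off is
declared at min r < 0.01 w; convergence at max |dr/dt| < 10⁻⁵. The
catenoid r = c cosh((z−l/2)/c) is stationary for this flow, and the
existence bound for a catenoid spanning the rings — the largest l/w = u/cosh u
over u, ≈ 0.6627 — separates tubes that relax (below) from tubes that
pinch (above). The package computes the threshold both ways: bisection
over dynamic runs (tolerance 0.01) and the analytic bound; they agree
within 0.005. Scale invariance (pinch time ∝ l² at fixed l/w) is verified
numerically. The hand-off from the contour model takes the delaminated
length as 0.8 × tube depth by default; modelling progressive delamination
(tension-driven growth of the detached zone) is out of scope.

## Known limitations

* Geodesics and region boundaries are graph-metric quantities; regions
  smaller than ~5 edge lengths are unreliable, and all band statistics are
  biased at the one-edge scale.
* The synthetic optics are an isotropic Gaussian, not a lattice
  light-sheet PSF; segmentation robustness to deconvolution artefacts is
  untested.
* The contour model is 2D with an axisymmetric interpretation; multi-lobed
  cups and the signalling dynamics that sustain PIP3 domains are not
  modelled, and coefficient values are discretization-specific.
* Lip/base closure *detection* from image geometry alone is not attempted;
  closure labels come from events or synthetic truth.
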