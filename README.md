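# cupmap

Surface-based mapping of PIP3 domains in macropinocytic cups, and a
biophysical "stalled wave" model of how those cups close.

Macropinocytosis is the actin-driven engulfment of extracellular fluid into
micron-scale vesicles. In *Dictyostelium*, a cup-shaped membrane protrusion
is templated by a contiguous plasma-membrane domain of elevated PIP3: actin
polymerization at the domain rim expands the cup, and the cup seals — at its
lip or at its base — shortly after the domain stops expanding. `cupmap`
provides two pipelines around this biology:

1. **Image analysis.** Two-channel 3D time-lapse volumes (PIP3 + actin
   reporters) with a binary cell segmentation are turned into triangulated
   surfaces; fluorescence is projected onto the surface along truncated
   normal line scans; PIP3 domains are segmented around markers by local
   Otsu thresholding gated by mean curvature (cup = supra-threshold concave
   component, lip = the most convex geodesic band outside it, domain =
   supra-threshold vertices within the lip contour); domains are tracked,
   graded, and profiled in geodesic distance bands with fold normalization,
   event-aligned space-time maps, and double-normalized life histories.
   Because suitable raw light-sheet data are not redistributable, a
   synthetic-scene generator with closed-form ground truth (spherical cells
   whose cups are reflected spherical caps) drives development and testing.

2. **Biophysics.** An overdamped 2D contour model of the cell cross-section
   with tension, bending, area-conservation and rim-localized actin
   polymerization forces, in which a PIP3 domain arc first expands
   (dd/dt = v_P/d) and then stalls. Depending on the tension and
   polymerization coefficients (k_T, k_P) the stalled cup seals at the lip,
   elongates into a tube, or stays open. A separate axisymmetric model
   evolves a delaminated membrane tube under tension proportional to mean
   curvature: tubes with length-to-width ratio above the catenoid-existence
   bound pinch off (basal closure), those below relax to a stable catenoid.

## Worked example

Critical aspect ratio for basal closure, by two independent routes:

```sh
$ cupmap critical
dynamic bisection: 0.6672
catenoid bound:    0.6627
```

The catenoid bound solves w/2 = c·cosh(l/(2c)) for the largest l/w with a
real solution; the dynamic value bisects between curvature-flow runs that
pinch and runs that converge. Both give ~0.66: a delaminated tube less than
two-thirds as long as it is wide can find a minimal surface and never
closes.

One contour-model run on the lip-closure boundary:

```sh
$ cupmap model --k-t 0.01 --k-p 8.0
outcome: lip_closure  closure_t: 540.3  vesicle: 0.0 um^3  aspect: 45.22
```

The domain expands for 20 s, stalls, the rim protrudes, and the lips seal
at t ≈ 540 s. In this formulation lip closures sit on the narrow boundary
between the open-cup and tube regimes and seal thin pouches (hence the
tiny revolved volume); see `docs/methods.md` for why, and for what the
model does and does not reproduce of the published regime structure.

The full synthetic image pipeline (volumes → surfaces → projection →
segmentation → geometry and profiles):

```sh
$ cupmap demo --seed 1 --out artifacts/
```

writes per-frame TIFF volumes and PLY surfaces plus `geometry.csv` (per
domain and frame: area, perimeter, depth in μm), `profiles.csv`
(fold-normalized intensity per geodesic band) and
`geometry_normalized.csv` (the double-normalized cohort life history).

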