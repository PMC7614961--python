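"""Geodesic-band fluorescence profiles and domain geometry series.

Measurements are made relative to the domain boundary.  Bands inside the
domain are spaced at 0.1 x domain depth (a normalised depth fraction, so
domains of different sizes are comparable); bands outside are spaced at
0.2 μm.  Per-domain profiles are fold-normalised by the median-over-lifetime
mean fluorescence of the band 5 μm outside the domain, then aggregated
across domains.  Event-aligned space-time maps interpolate profiles on a
2.5 s grid before closure.  Geometry series report area, perimeter and depth
with the domain lifetime double-normalised (time to [0, 1], values to the
cohort 75th percentile) for cohort averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mesh as mm
from .mesh import SurfaceMesh, VertexRegion

N_INSIDE_BANDS = 10
OUTSIDE_STEP = 0.2          # μm
BACKGROUND_DISTANCE = 5.0   # μm outside the domain


@dataclass
class BandLabeling:
    """Per-vertex band assignment around one domain.

    ``band`` is +k (k = 0..9) for inside band k (0 = at the boundary,
    9 = deepest tenth), -(k+1) for outside band k (0.2 μm spacing), and a
    large sentinel for unassigned vertices.
    """

    mesh: SurfaceMesh
    domain: VertexRegion
    band: np.ndarray
    depth: float

    UNASSIGNED = -10 ** 6

    def inside_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.band == k)

    def outside_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.band == -(k + 1))

    @property
    def n_outside(self) -> int:
        neg = self.band[(self.band < 0) & (self.band != self.UNASSIGNED)]
        return int(-neg.min()) if len(neg) else 0


@dataclass
class BandProfile:
    inside_centers: np.ndarray      # depth fraction in (0, 1)
    inside_mean: np.ndarray
    outside_centers: np.ndarray     # μm outside the boundary
    outside_mean: np.ndarray
    background: float = np.nan

    def series(self) -> np.ndarray:
        """Concatenated profile, outside (far to near) then inside."""
        return np.r_[self.outside_mean[::-1], self.inside_mean]


def band_partition(mesh: SurfaceMesh, domain: VertexRegion,
                   depth: float | None = None,
                   max_outside: float = BACKGROUND_DISTANCE,
                   claimed: np.ndarray | None = None) -> BandLabeling:
    """Partition the surface into geodesic distance bands around a domain.

    Inside bands are 0.1 x depth wide (10 bands); outside bands are 0.2 μm
    wide out to ``max_outside`` (inclusive of the band covering it).  With
    multiple domains on one cell, pass ``claimed`` (a boolean per-vertex
    mask of vertices nearest to *this* domain's boundary) to restrict the
    outside bands.

    Distance to the boundary is the mean of the distances to the inner and
    outer boundary vertex rings (the true cut lies between them), matching
    the depth measurement, so band edges are not biased by the half-edge
    quantisation of the vertex region.
    """
    d = 0.5 * (mm.geodesic_distance(mesh, mm.boundary_vertices(domain))
               + mm.geodesic_distance(mesh,
                                      mm.outside_boundary_vertices(domain)))
    if depth is None:
        depth = mm.region_depth(domain)
    band = np.full(mesh.n_vertices, BandLabeling.UNASSIGNED, dtype=np.int64)
    inside = domain.mask()
    if depth <= 0 or not np.isfinite(depth):
        warnings.warn("domain depth is zero; using a single inside band")
        band[inside] = 0
    else:
        k = np.minimum((d[inside] / (0.1 * depth)).astype(int),
                       N_INSIDE_BANDS - 1)
        band[inside] = k
    out = ~inside
    if claimed is not None:
        out &= claimed
    n_out = int(np.ceil(max_outside / OUTSIDE_STEP))
    ko = (d[out] / OUTSIDE_STEP).astype(int)
    vals = np.where(ko < n_out, -(ko + 1), BandLabeling.UNASSIGNED)
    band[out] = vals
    return BandLabeling(mesh, domain, band, float(depth))


def claim_masks(mesh: SurfaceMesh, domains) -> list:
    """Per-domain masks of outside vertices nearest that domain's boundary."""
    dists = np.stack([mm.geodesic_distance(mesh, mm.boundary_vertices(d))
                      for d in domains])
    owner = np.argmin(dists, axis=0)
    return [owner == i for i in range(len(domains))]


def band_profile(bands: BandLabeling, intensity,
                 mask: np.ndarray | None = None) -> BandProfile:
    """Arithmetic mean intensity per band; empty bands yield NaN."""
    x = np.asarray(intensity, dtype=float)
    ok = np.ones(len(x), dtype=bool) if mask is None else np.asarray(mask)
    ins_mean = np.full(N_INSIDE_BANDS, np.nan)
    for k in range(N_INSIDE_BANDS):
        sel = bands.inside_indices(k)
        sel = sel[ok[sel]]
        if len(sel):
            ins_mean[k] = x[sel].mean()
    n_out = bands.n_outside
    out_mean = np.full(n_out, np.nan)
    for k in range(n_out):
        sel = bands.outside_indices(k)
        sel = sel[ok[sel]]
        if len(sel):
            out_mean[k] = x[sel].mean()
    return BandProfile(
        inside_centers=(np.arange(N_INSIDE_BANDS) + 0.5) / N_INSIDE_BANDS,
        inside_mean=ins_mean,
        outside_centers=(np.arange(n_out) + 0.5) * OUTSIDE_STEP,
        outside_mean=out_mean)


def normalize_profile(profiles: list[BandProfile],
                      background_distance: float = BACKGROUND_DISTANCE):
    """Fold-normalise a domain's per-frame profiles by its background.

    The background is the median over frames of the mean fluorescence in the
    outside band containing ``background_distance``; every band mean is
    divided by it.  Raises if the background is not positive (over-subtracted
    input).  Returns ``(normalised profiles, background)``.
    """
    if not profiles:
        raise ValueError("no profiles to normalise")
    k = min(int(background_distance / OUTSIDE_STEP),
            len(profiles[0].outside_mean) - 1)
    bg_frames = [p.outside_mean[min(k, len(p.outside_mean) - 1)]
                 for p in profiles]
    bg_frames = [b for b in bg_frames if np.isfinite(b)]
    if not bg_frames:
        raise ValueError("background band empty in every frame")
    bg = float(np.median(bg_frames))
    if bg <= 0:
        raise ValueError("non-positive background; fluorescence was "
                         "over-subtracted upstream")
    out = []
    for p in profiles:
        out.append(BandProfile(p.inside_centers, p.inside_mean / bg,
                               p.outside_centers, p.outside_mean / bg,
                               background=bg))
    return out, bg


def aggregate_profiles(domain_profiles: list[BandProfile]):
    """Cohort mean and standard error across per-domain mean profiles.

    Returns a DataFrame with columns (position, kind, mean, se, n); ``se`` is
    NaN for n < 2.
    """
    if not domain_profiles:
        raise ValueError("no domains to aggregate")
    rows = []
    p0 = domain_profiles[0]
    for kind, centers, get in (
            ("inside", p0.inside_centers, lambda p: p.inside_mean),
            ("outside", p0.outside_centers, lambda p: p.outside_mean)):
        stack = np.stack([get(p) for p in domain_profiles])
        for j, c in enumerate(centers):
            col = stack[:, j]
            col = col[np.isfinite(col)]
            n = len(col)
            rows.append({
                "position": c, "kind": kind,
                "mean": col.mean() if n else np.nan,
                "se": col.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n})
    return pd.DataFrame(rows)


# -- geometry -----------------------------------------------------------------------


def domain_geometry(mesh: SurfaceMesh, domain: VertexRegion):
    """(area, perimeter, depth) of a domain in μm units.

    Area sums faces with boundary faces weighted by their inside-vertex
    fraction; perimeter is the boundary-loop length with the edge-graph
    zigzag smoothed out; depth is the maximum geodesic distance of any
    domain vertex to the boundary.
    """
    area = mm.region_area(domain)
    perimeter = mm.smoothed_boundary_length(domain)
    depth = mm.region_depth(domain)
    return area, perimeter, depth


def expansion_rate(times, areas, window: float = 30.0) -> float:
    """Least-squares slope (μm²/s) of area vs time over the first ``window``
    seconds after formation (time origin = first sample).  NaN if fewer than
    three samples fall in the window."""
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    sel = t <= t[0] + window + 1e-9
    if sel.sum() < 3:
        return float("nan")
    return float(np.polyfit(t[sel], a[sel], 1)[0])


def double_normalize(df: pd.DataFrame, variables=("area", "perimeter", "depth"),
                     n_points: int = 20):
    """Double normalisation of domain tracks for cohort averaging.

    Each track's time axis is rescaled so formation (its first frame) is 0
    and closure (its last frame) is 1, and each variable is interpolated at
    ``n_points`` evenly spaced points; variables are then divided by their
    cohort-level 75th percentile (computed across all time points of all
    tracks).  Tracks with fewer than two frames are excluded.  Returns
    ``(per-track DataFrame, cohort summary DataFrame)``.
    """
    grid = np.linspace(0.0, 1.0, n_points)
    per_track = []
    for track, g in df.groupby("track"):
        g = g.sort_values("t")
        if len(g) < 2 or g["t"].iloc[-1] <= g["t"].iloc[0]:
            warnings.warn(f"track {track} shorter than 2 frames; excluded")
            continue
        s = (g["t"] - g["t"].iloc[0]) / (g["t"].iloc[-1] - g["t"].iloc[0])
        row = {"track": track, "s": grid}
        for var in variables:
            row[var] = np.interp(grid, s, g[var])
        per_track.append(pd.DataFrame(row))
    if not per_track:
        raise ValueError("no usable tracks")
    out = pd.concat(per_track, ignore_index=True)
    for var in variables:
        q75 = np.nanpercentile(out[var], 75)
        out[var] = out[var] / q75
    summary = out.groupby("s").agg(
        **{f"{v}_mean": (v, "mean") for v in variables},
        **{f"{v}_se": (v, lambda c: c.std(ddof=1) / np.sqrt(len(c)))
           for v in variables},
        n=("track", "count")).reset_index()
    return out, summary


# -- space-time maps ----------------------------------------------------------------


@dataclass
class SpaceTimeMap:
    times: np.ndarray               # s relative to closure (<= 0)
    positions: np.ndarray           # μm; negative = outside, positive = inside
    grid: np.ndarray                # (n_positions, n_times) mean intensity
    n_tracks: int
    mean_depth: float


def spacetime_map(track_profiles: dict, closure_times: dict,
                  window: float = 60.0, dt: float = 2.5,
                  depths: dict | None = None) -> SpaceTimeMap:
    """Event-aligned mean profile map over the ``window`` before closure.

    ``track_profiles`` maps track id to a list of ``(t, BandProfile)``
    (normalised) and ``closure_times`` maps track id to its closure
    reference time (halfway between the event frame and the previous one).
    Tracks must cover the full window before closure; others are dropped.
    Each band's value is linearly interpolated on the dt grid per track,
    then averaged across tracks.  The inside axis is scaled by the average
    domain depth so inside positions are in μm like the outside ones.
    """
    grid_t = np.arange(-window, 0.0 + 1e-9, dt)
    usable = []
    for track, prof in track_profiles.items():
        if track not in closure_times or len(prof) < 2:
            continue
        t0 = closure_times[track]
        rel = np.asarray([t - t0 for t, _ in prof])
        if rel.min() > grid_t[0] or rel.max() < grid_t[-1]:
            continue
        series = np.stack([p.series() for _, p in prof])   # (frames, bands)
        interp = np.stack([np.interp(grid_t, rel, series[:, b])
                           for b in range(series.shape[1])])
        usable.append((track, interp))
    if not usable:
        warnings.warn("no tracks cover the requested closure window")
        return SpaceTimeMap(grid_t, np.empty(0), np.empty((0, len(grid_t))),
                            0, np.nan)
    stack = np.stack([g for _, g in usable])
    grid = np.nanmean(stack, axis=0)
    p0 = next(iter(track_profiles.values()))[0][1]
    if depths:
        mean_depth = float(np.mean([depths[t] for t, _ in usable]))
    else:
        mean_depth = float("nan")
    d = mean_depth if np.isfinite(mean_depth) else 1.0
    positions = np.r_[-p0.outside_centers[::-1], p0.inside_centers * d]
    return SpaceTimeMap(grid_t, positions, grid, len(usable), mean_depth)
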