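"""PIP3-domain segmentation on the cell surface.

Domains are delineated around annotated markers from the projected PIP3
channel and the surface mean curvature:

* a local Otsu threshold is computed from the vertices geodesically nearest
  to the marker (its geodesic Voronoi cell among all markers, capped at a
  radius so that small domains are not swamped by the whole-cell histogram);
* the *cup* is the connected supra-threshold, concave (H < 0) component
  about the marker;
* the *lip* is the geodesic distance band outside the cup boundary with the
  highest mean curvature (the convex rim);
* the *domain* is everything inside the lip contour above threshold,
  cleaned up by dilate x2, fill, erode x2.

Markers whose vertex is below threshold get a minimal "false domain" (the
marker vertex plus its face-sharing neighbours); transitions between false
and true domains define formation and elimination events.  Structures shared
by two markers are split along the line of equal geodesic distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import mesh as mm
from .mesh import SurfaceMesh, VertexRegion

EVENTS = ("formation", "elimination", "lip_closure", "base_closure",
          "failed_closure", "split", "segmentation_error", "none")


@dataclass
class Marker:
    frame: int
    position: np.ndarray            # (3,) μm
    track: int = -1
    label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class DomainSegmentation:
    marker: Marker
    vertex: int                     # marker snapped to nearest mesh vertex
    threshold: float
    cup: VertexRegion
    lip: VertexRegion | None
    domain: VertexRegion
    is_false_domain: bool = False
    is_split: bool = False
    degenerate_histogram: bool = False


def otsu_threshold(values) -> float:
    """Exact Otsu threshold on the value histogram.

    Maximises the between-class variance over cuts between consecutive
    distinct values; the threshold returned is the midpoint of the best cut
    (ties resolved toward the lowest cut, so reruns are deterministic).
    Exactly equivariant under affine intensity maps with positive scale.
    """
    v = np.sort(np.asarray(values, dtype=float))
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("degenerate single-valued histogram")
    n = len(v)
    # class 0 = values <= cut, evaluated at each distinct-value boundary
    idx = np.searchsorted(v, uniq[:-1], side="right")
    csum = np.cumsum(v)
    w0 = idx / n
    w1 = 1.0 - w0
    mu0 = csum[idx - 1] / idx
    mu1 = (csum[-1] - csum[idx - 1]) / (n - idx)
    var = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(var))     # argmax takes the first (lowest) maximiser
    return float(0.5 * (uniq[k] + uniq[k + 1]))


def snap_to_vertex(mesh: SurfaceMesh, position) -> int:
    return int(cKDTree(mesh.vertices).query(np.asarray(position))[1])


def marker_voronoi(mesh: SurfaceMesh, marker_vertices) -> np.ndarray:
    """Geodesic Voronoi assignment of every vertex to its nearest marker.

    Returns per-vertex index into ``marker_vertices`` (ties go to the lower
    marker index, scipy's multi-source Dijkstra being deterministic given the
    source order).
    """
    d = np.stack([mm.geodesic_distance(mesh, [v]) for v in marker_vertices])
    return np.argmin(d, axis=0), d


def local_otsu_threshold(mesh: SurfaceMesh, pip3, vertex: int,
                         neighborhood: VertexRegion):
    """Otsu threshold from the marker's geodesic neighbourhood histogram.

    Returns ``(threshold, degenerate)``; a single-valued histogram is
    degenerate and the threshold equals that value (false-domain path).
    """
    vals = np.asarray(pip3)[neighborhood.indices]
    uniq = np.unique(vals)
    if len(uniq) < 2:
        return float(uniq[0]), True
    return otsu_threshold(vals), False


def false_domain(mesh: SurfaceMesh, vertex: int) -> VertexRegion:
    """Marker vertex plus all vertices sharing a face with it."""
    shares = np.unique(mesh.faces[(mesh.faces == vertex).any(axis=1)])
    return VertexRegion(mesh, shares)


def segment_cup(mesh: SurfaceMesh, pip3, curvature, vertex: int,
                threshold: float):
    """Connected supra-threshold concave component about the marker.

    Returns ``(region, is_false)``: if the marker vertex itself fails the
    criteria the false-domain fallback is returned.
    """
    ok = (np.asarray(pip3) > threshold) & (np.asarray(curvature) < 0)
    if not ok[vertex]:
        return false_domain(mesh, vertex), True
    comp = mm.connected_component_about(
        VertexRegion(mesh, np.flatnonzero(ok)), vertex)
    if len(comp) == 0:
        return false_domain(mesh, vertex), True
    return comp, False


def find_lip(mesh: SurfaceMesh, cup: VertexRegion, curvature,
             band_width: float = 0.2, max_search: float = 3.0) -> VertexRegion:
    """Distance band outside the cup with the highest mean curvature.

    Vertices outside the cup are grouped into geodesic bands of width
    ``band_width`` μm from the cup boundary, out to ``max_search`` μm; the
    band with the highest average H is the lip (ties go to the nearer band).
    """
    if len(cup) == 0:
        raise ValueError("cup is empty")
    outside = ~cup.mask()
    if not outside.any():
        raise ValueError("cup covers the whole mesh; no outside for a lip")
    d = mm.geodesic_distance(mesh, mm.boundary_vertices(cup))
    h = np.asarray(curvature)
    nb = max(int(np.ceil(max_search / band_width)), 1)
    best, best_h = None, -np.inf
    for k in range(nb):
        sel = outside & (d > k * band_width) & (d <= (k + 1) * band_width)
        if not sel.any():
            continue
        hk = h[sel].mean()
        if hk > best_h:        # strict: ties keep the nearer band
            best, best_h = sel, hk
    if best is None:
        raise ValueError("no vertices found outside the cup within range")
    return VertexRegion(mesh, np.flatnonzero(best))


def inside_lip(mesh: SurfaceMesh, lip: VertexRegion, seed: int) -> VertexRegion:
    """Vertices enclosed by the lip band: the component of mesh minus lip
    containing the seed (the marker/cup side).

    The band is dilated by one ring before the enclosure test so that
    single-vertex-thin stretches of the band cannot leak connectivity
    through diagonal adjacencies; the extra ring is handed back to the
    inside afterwards.
    """
    barrier = mm.dilate(lip)
    rest = barrier.complement()
    comp = mm.connected_component_about(rest, seed)
    if len(comp) == 0 or len(comp) == len(rest):
        raise ValueError("lip band does not enclose a region (not a closed "
                         "contour around the marker)")
    grown = mm.dilate(comp)
    inside = np.setdiff1d(grown.indices, lip.indices)
    return VertexRegion(mesh, inside)


def segment_domain(mesh: SurfaceMesh, pip3, lip: VertexRegion, seed: int,
                   threshold: float) -> VertexRegion:
    """Supra-threshold vertices within the lip contour, then smoothed.

    Spill-over fluorescence beyond the lip is excluded even when above
    threshold, because membership is gated by the lip contour first.
    """
    inner = inside_lip(mesh, lip, seed)
    above = np.asarray(pip3) > threshold
    raw = VertexRegion(mesh, inner.indices[above[inner.indices]])
    if len(raw) == 0:
        return false_domain(mesh, seed)
    return mm.smooth_region(raw)


def split_by_markers(seg_a: DomainSegmentation, seg_b: DomainSegmentation,
                     mesh: SurfaceMesh):
    """Split intersecting structures along equal geodesic distance.

    If any of the two markers' cup/domain/lip regions intersect, every vertex
    of the shared structures is reassigned to its geodesically nearer marker
    (ties to the lower track id) and both segmentations are flagged split.
    Non-intersecting structures are returned unchanged.
    """
    pairs = [(seg_a.cup, seg_b.cup), (seg_a.domain, seg_b.domain)]
    if seg_a.lip is not None and seg_b.lip is not None:
        pairs.append((seg_a.lip, seg_b.lip))
    if not any(np.intersect1d(x.indices, y.indices).size for x, y in pairs):
        return seg_a, seg_b, False
    da = mm.geodesic_distance(mesh, [seg_a.vertex])
    db = mm.geodesic_distance(mesh, [seg_b.vertex])
    first = (seg_a.marker.track, seg_b.marker.track, 0) <= \
            (seg_b.marker.track, seg_a.marker.track, 1)
    a_wins = (da < db) | ((da == db) & first)
    for x, y in pairs:
        union = np.union1d(x.indices, y.indices)
        x.indices = union[a_wins[union]]
        y.indices = union[~a_wins[union]]
    seg_a.is_split = seg_b.is_split = True
    return seg_a, seg_b, True


def segment_frame(mesh: SurfaceMesh, pip3, curvature, markers,
                  voronoi_radius: float = 5.0, band_width: float = 0.2):
    """Segment every marker on one frame; returns list of DomainSegmentation.

    The Otsu histogram for each marker uses its geodesic Voronoi cell among
    all markers, intersected with a ``voronoi_radius`` μm geodesic cap.
    Pairwise intersecting structures are split along equal geodesic distance.
    """
    pip3 = np.asarray(pip3, dtype=float)
    verts = [snap_to_vertex(mesh, m.position) for m in markers]
    assign, dmat = marker_voronoi(mesh, verts)
    segs = []
    for i, (marker, v) in enumerate(zip(markers, verts)):
        cell = np.flatnonzero((assign == i) & (dmat[i] <= voronoi_radius))
        if len(cell) == 0:
            cell = np.asarray([v])
        thr, degen = local_otsu_threshold(mesh, pip3, v,
                                          VertexRegion(mesh, cell))
        if degen:
            segs.append(DomainSegmentation(
                marker, v, thr, false_domain(mesh, v), None,
                false_domain(mesh, v), is_false_domain=True,
                degenerate_histogram=True))
            continue
        cup, is_false = segment_cup(mesh, pip3, curvature, v, thr)
        if is_false:
            segs.append(DomainSegmentation(marker, v, thr, cup, None, cup,
                                           is_false_domain=True))
            continue
        try:
            lip = find_lip(mesh, cup, curvature, band_width=band_width)
            domain = segment_domain(mesh, pip3, lip, v, thr)
        except ValueError as e:
            # degenerate lip band (e.g. gaps on a coarse mesh): fall back
            # to the smoothed cup so the frame stays usable downstream
            warnings.warn(f"marker {marker.track} frame {marker.frame}: "
                          f"{e}; using the cup as the domain")
            lip = None
            domain = mm.smooth_region(cup)
        segs.append(DomainSegmentation(marker, v, thr, cup, lip, domain))
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[i].is_false_domain or segs[j].is_false_domain:
                continue
            split_by_markers(segs[i], segs[j], mesh)
    return segs


# -- marker tracking ----------------------------------------------------------------


def track_markers(markers: pd.DataFrame, merge_labels: bool = True
                  ) -> pd.DataFrame:
    """Group markers into tracks by mutual nearest neighbours across frames.

    Each marker is paired with its nearest marker in the following frame and
    vice versa; markers are linked only when both directions agree (a marker
    equidistant to two partners pairs with the lower row index, and a
    symmetric tie that breaks mutuality yields no link).  Chains of links
    form tracks.  If ``merge_labels``, tracks with identical non-empty
    ``label`` and no overlapping frames are merged (the regrouping hook for
    closure-time jumps).  Returns a copy with a ``track`` column.
    """
    df = markers.copy().reset_index(drop=True)
    if "label" not in df:
        df["label"] = ""
    frames = sorted(df["frame"].unique())
    parent = {i: i for i in df.index}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(j)] = find(i)

    for fa, fb in zip(frames[:-1], frames[1:]):
        ia = df.index[df["frame"] == fa].to_numpy()
        ib = df.index[df["frame"] == fb].to_numpy()
        if len(ia) == 0 or len(ib) == 0:
            continue
        pa = df.loc[ia, ["x", "y", "z"]].to_numpy()
        pb = df.loc[ib, ["x", "y", "z"]].to_numpy()
        fwd = cKDTree(pb).query(pa)[1]      # nearest next-frame marker
        bwd = cKDTree(pa).query(pb)[1]      # nearest previous-frame marker
        for a_pos, b_pos in enumerate(fwd):
            if bwd[b_pos] == a_pos:
                union(ia[a_pos], ib[b_pos])
    df["track"] = [find(i) for i in df.index]

    if merge_labels:
        by_track = df.groupby("track")
        info = {t: (set(g["frame"]), set(g["label"]) - {""})
                for t, g in by_track}
        tracks = sorted(info)
        for i, t in enumerate(tracks):
            for u in tracks[i + 1:]:
                ft, lt = info[t]
                fu, lu = info[u]
                if lt and lt == lu and not (ft & fu):
                    df.loc[df["track"] == u, "track"] = t
                    info[t] = (ft | fu, lt)
                    info[u] = (set(), set())
    # relabel tracks densely in order of first appearance
    order = {t: i for i, t in enumerate(
        df.sort_values(["frame"]).drop_duplicates("track")["track"])}
    df["track"] = df["track"].map(order)
    return df


# -- grading ------------------------------------------------------------------------


def auto_grade(track_segs, manual_present=None) -> pd.DataFrame:
    """Event labels for one track of per-frame segmentations.

    A false-to-true domain transition is a *formation*, true-to-false an
    *elimination*.  Where a manual presence call disagrees with the automatic
    one the frame is graded *segmentation_error* (and excluded downstream);
    split frames are graded *split*.
    """
    rows = []
    prev_true = None
    for k, seg in enumerate(track_segs):
        is_true = not seg.is_false_domain
        event = "none"
        if prev_true is not None:
            if is_true and not prev_true:
                event = "formation"
            elif prev_true and not is_true:
                event = "elimination"
        if seg.is_split and event == "none":
            event = "split"
        if manual_present is not None and \
                bool(manual_present[k]) != is_true:
            event = "segmentation_error"
        rows.append({"index": k, "frame": seg.marker.frame,
                     "track": seg.marker.track, "present": is_true,
                     "event": event})
        prev_true = is_true
    return pd.DataFrame(rows)
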