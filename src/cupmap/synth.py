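"""Synthetic cells, volumes and domain life histories.

The generator emulates the statistical structure that the surface-mapping
pipeline assumes: a closed cell bearing 1-3 cup-shaped invaginations, a
PIP3-like channel bright on the cup's inner face with a base-to-lip gradient
and spill-over past the lip, an actin-like channel forming a shell with lip
enrichment, Gaussian (PSF-like) blur, and Poisson noise.

Geometry is deliberately analytic: the cell is a sphere of radius R and each
cup is the spherical cap of opening angle alpha reflected through the plane
of its rim circle.  The reflected cap is congruent to the original cap, so
the ground-truth domain has *exact* closed forms

    area      = 2 pi R^2 (1 - cos alpha)
    perimeter = 2 pi R sin alpha
    depth     = R alpha            (geodesic, apex to rim)

which serve as independent oracles for every downstream measurement.  A
narrow raised ring just outside the rim provides the convex lip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

DEFAULT_VOXEL_SIZE = (0.104, 0.104, 0.163)  # (x, y, z) μm, deskewed geometry


@dataclass
class CupSpec:
    """One cup-shaped invagination on the cell sphere.

    ``opening_angle`` is the half-angle of the cap *at stall* (the fully
    expanded size).  The cup indentation is the mirror image of the cap in
    its rim plane, so the indentation depth is fixed by geometry
    (``2 R (1 - cos alpha)`` radially at the apex); an explicit ``depth`` is
    accepted for bookkeeping but the reflection depth is what is rendered.
    """

    axis: tuple = (0.0, 0.0, 1.0)
    opening_angle: float = 0.7          # rad, at stall
    depth: float | None = None          # derived; see docstring
    pip3_gradient: float = 3.0          # base-to-lip intensity ratio >= 1
    lip_spillover: float = 0.3          # μm of PIP3 bleed past the rim
    lifetime_s: float = 80.0
    stall_fraction: float = 0.6         # fraction of lifetime spent expanding
    expansion_rate: float = 0.3         # μm² s⁻¹ of domain area growth
    rim_height: float = 0.25            # μm outward bump of the lip ring
    rim_width: float = 0.10             # μm Gaussian sigma of the ring
    rim_offset: float = 0.3             # μm arc from rim circle to ring crest
    # (the ring decays to ~1% of its height at the rim circle itself, so the
    # reflected cap stays congruent and its closed-form area exact)

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("cup axis must be nonzero")
        self.axis = tuple(a / n)
        if not 0 < self.opening_angle < np.pi / 4:
            # the reflected cap is overhang-free (star-convex) iff cos(2a) > 0
            raise ValueError("opening_angle must lie in (0, pi/4) rad")
        if self.pip3_gradient < 1:
            raise ValueError("pip3_gradient must be >= 1")
        if not 0 < self.stall_fraction <= 1:
            raise ValueError("stall_fraction must be in (0, 1]")

    def stall_time(self) -> float:
        return self.stall_fraction * self.lifetime_s

    def angle_at(self, t: float, cell_radius: float,
                 min_angle: float = 0.12) -> float:
        """Cap half-angle at time t: area grows linearly until stall."""
        a_stall = cap_area(cell_radius, self.opening_angle)
        a = a_stall - self.expansion_rate * max(self.stall_time() - t, 0.0)
        a = np.clip(a, cap_area(cell_radius, min_angle), a_stall)
        return float(np.arccos(1.0 - a / (2.0 * np.pi * cell_radius ** 2)))


def cap_area(radius: float, angle: float) -> float:
    """Area of a spherical cap of half-angle ``angle`` on a sphere."""
    return 2.0 * np.pi * radius ** 2 * (1.0 - np.cos(angle))


def cap_perimeter(radius: float, angle: float) -> float:
    return 2.0 * np.pi * radius * np.sin(angle)


def cap_depth(radius: float, angle: float) -> float:
    """Geodesic depth (apex to rim along the surface) of the cap."""
    return radius * angle


@dataclass
class SyntheticScene:
    """Full description of one synthetic cell; the seed fixes all randomness."""

    voxel_size: tuple = DEFAULT_VOXEL_SIZE      # (x, y, z) μm per voxel
    cell_center: tuple | None = None            # μm; default = volume centre
    cell_radius: float = 5.0                    # μm
    cups: list = field(default_factory=list)
    noise_model: str = "none"                   # "none" or "poisson"
    noise_scale: float = 1.0                    # photons per intensity unit
    blur_sigma: float = 0.30                    # μm, PSF-like shell width
    # (>= ~2x the coarsest voxel pitch so the shell is Nyquist-sampled)
    seed: int = 0
    margin: float = 1.6                         # μm of empty border
    mesh_subdivisions: int = 5
    pip3_lip_intensity: float = 150.0
    pip3_background: float = 30.0               # membrane-wide PIP3 level
    actin_intensity: float = 150.0
    actin_lip_factor: float = 2.0
    actin_rim_width: float = 0.3                # μm sigma of lip enrichment

    def __post_init__(self):
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")
        self.cups = [c if isinstance(c, CupSpec) else CupSpec(**c)
                     for c in self.cups]
        _check_cup_overlap(self.cups)

    # -- geometry helpers ---------------------------------------------------------

    def volume_shape(self):
        """(nz, ny, nx) voxel counts covering the cell plus margin."""
        extent = 2 * (self.cell_radius + max(
            [0.0] + [c.rim_height for c in self.cups]) + self.margin)
        dx, dy, dz = self.voxel_size
        return (int(np.ceil(extent / dz)), int(np.ceil(extent / dy)),
                int(np.ceil(extent / dx)))

    def center(self):
        if self.cell_center is not None:
            return np.asarray(self.cell_center, dtype=float)
        nz, ny, nx = self.volume_shape()
        dx, dy, dz = self.voxel_size
        return np.array([nx * dx, ny * dy, nz * dz]) / 2.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cups"] = [dataclasses.asdict(c) for c in self.cups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScene":
        return cls(**d)


def _check_cup_overlap(cups, solid_angle_budget: float = 0.35) -> None:
    """Reject cup layouts whose cones (cap + rim zone) overlap."""
    total = 0.0
    for i, c in enumerate(cups):
        pad_i = c.opening_angle + (c.rim_offset + 3 * c.rim_width) / 1.0
        total += (1.0 - np.cos(c.opening_angle)) / 2.0
        for j in range(i):
            o = cups[j]
            ang = np.arccos(np.clip(np.dot(c.axis, o.axis), -1, 1))
            pad_j = o.opening_angle + (o.rim_offset + 3 * o.rim_width)
            if ang < pad_i + pad_j:
                raise ValueError(
                    f"cups {j} and {i} overlap: axis separation {ang:.2f} rad "
                    f"< required {pad_i + pad_j:.2f} rad")
    if total > solid_angle_budget:
        raise ValueError(f"cups exceed solid-angle budget "
                         f"({total:.2f} > {solid_angle_budget})")


# -- radial shape function ----------------------------------------------------------


def _reflected_cap_table(radius: float, angle: float, n: int = 512):
    """Tabulate the reflected cap as a radial function rho(direction angle).

    A cap point at polar angle t maps under reflection in the rim plane to
    cylindrical coordinates (R sin t, 2 R cos(alpha) - R cos t); its direction
    angle phi(t) is monotone in t for alpha < ~62 deg, so rho(phi) is a
    single-valued star-convex profile.
    """
    t = np.linspace(0.0, angle, n)
    s = radius * np.sin(t)
    z = 2.0 * radius * np.cos(angle) - radius * np.cos(t)
    phi = np.arctan2(s, z)
    rho = np.hypot(s, z)
    if np.any(np.diff(phi) <= 0):
        raise ValueError("reflected cap is not star-convex at this angle")
    return phi, rho, t


def scene_radius_function(scene: SyntheticScene, directions: np.ndarray,
                          t: float) -> np.ndarray:
    """Star-convex radius r(u) of the cell surface along unit directions.

    Used for the inside/outside test when rasterising the binary cell mask;
    valid because opening angles are restricted to < pi/4 (no overhangs).
    """
    R = scene.cell_radius
    r = np.full(len(directions), R)
    for cup in scene.cups:
        alpha = cup.angle_at(t, R)
        theta = np.arccos(np.clip(directions @ np.asarray(cup.axis), -1, 1))
        phi_tab, rho_tab, _ = _reflected_cap_table(R, alpha)
        inside = theta <= phi_tab[-1]
        r[inside] = np.interp(theta[inside], phi_tab, rho_tab)
        crest = alpha + cup.rim_offset / R
        arc = (theta - crest) * R
        ring = ~inside & (np.abs(arc) < 4 * cup.rim_width)
        r[ring] += cup.rim_height * np.exp(-arc[ring] ** 2 /
                                           (2 * cup.rim_width ** 2))
    return r


def scene_surface_points(scene: SyntheticScene, directions: np.ndarray,
                         t: float):
    """Map unit directions to surface points via the cap-reflection isometry.

    Directions inside a cup cone are mapped by reflecting the sphere point
    through the cup's rim plane — an isometry of the cap, so the sampling
    density and intrinsic geometry of the cup equal those of the sphere.
    Returns ``(points, label, cap_param)`` where points are relative to the
    cell centre, label is the 1-based owning cup (0 = sphere) and cap_param
    is the polar-angle fraction theta/alpha inside cups (NaN outside).
    """
    R = scene.cell_radius
    pts = R * np.asarray(directions, dtype=float).copy()
    label = np.zeros(len(directions), dtype=np.int64)
    cap_param = np.full(len(directions), np.nan)
    for k, cup in enumerate(scene.cups, start=1):
        axis = np.asarray(cup.axis)
        alpha = cup.angle_at(t, R)
        ct = directions @ axis
        inside = ct >= np.cos(alpha)
        pts[inside] -= (2.0 * R * (ct[inside] - np.cos(alpha)))[:, None] * axis
        label[inside] = k
        theta = np.arccos(np.clip(ct, -1, 1))
        cap_param[inside] = theta[inside] / alpha
        crest = alpha + cup.rim_offset / R
        arc = (theta - crest) * R
        ring = ~inside & (np.abs(arc) < 4 * cup.rim_width)
        bump = cup.rim_height * np.exp(-arc[ring] ** 2 /
                                       (2 * cup.rim_width ** 2))
        pts[ring] += bump[:, None] * directions[ring]
    return pts, label, cap_param


def _paint_channels(scene: SyntheticScene, directions, label, cap_param,
                    t: float):
    """Ground-truth PIP3 and actin surface intensities per direction."""
    R = scene.cell_radius
    pip3 = np.full(len(directions), scene.pip3_background)
    actin = np.full(len(directions), scene.actin_intensity)
    for k, cup in enumerate(scene.cups, start=1):
        alpha = cup.angle_at(t, R)
        mine = label == k
        g = cup.pip3_gradient
        # inside: linear base-to-lip gradient in the cap parameter, on top
        # of the membrane-wide background
        pip3[mine] = scene.pip3_background + scene.pip3_lip_intensity * \
            (1 + (g - 1) * (1 - cap_param[mine]))
        theta = np.arccos(np.clip(directions @ np.asarray(cup.axis), -1, 1))
        # spill-over: half-Gaussian decay past the rim
        out = ~mine & (theta > alpha)
        s = (theta[out] - alpha) * R
        sigma = max(cup.lip_spillover / 2.0, 1e-6)
        bleed = scene.pip3_lip_intensity * np.exp(-s ** 2 / (2 * sigma ** 2))
        pip3[out] = np.maximum(
            pip3[out],
            scene.pip3_background + np.where(s < 4 * sigma, bleed, 0.0))
        # actin lip enrichment centred on the rim crest
        crest = alpha + cup.rim_offset / R
        arc = (theta - crest) * R
        actin += scene.actin_intensity * (scene.actin_lip_factor - 1) * \
            np.exp(-arc ** 2 / (2 * scene.actin_rim_width ** 2))
    return pip3, actin


# -- frame assembly -----------------------------------------------------------------


def scene_mesh(scene: SyntheticScene, t: float = None,
               subdivisions: int = None) -> SurfaceMesh:
    """Ground-truth surface mesh at time t with truth channels attached."""
    import trimesh
    if t is None:
        t = max([c.stall_time() for c in scene.cups], default=0.0)
    sub = scene.mesh_subdivisions if subdivisions is None else subdivisions
    unit = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
    dirs = np.asarray(unit.vertices)
    pts, label, cap_param = scene_surface_points(scene, dirs, t)
    pip3, actin = _paint_channels(scene, dirs, label, cap_param, t)
    mesh = SurfaceMesh(scene.center() + pts, np.asarray(unit.faces))
    mesh.scalars["label"] = label.astype(float)
    mesh.scalars["pip3_truth"] = pip3
    mesh.scalars["actin_truth"] = actin
    return mesh


def _voxel_centers_world(shape, voxel_size):
    dx, dy, dz = voxel_size
    nz, ny, nx = shape
    z, y, x = np.meshgrid((np.arange(nz) + 0.5) * dz, (np.arange(ny) + 0.5) * dy,
                          (np.arange(nx) + 0.5) * dx, indexing="ij")
    return x, y, z


def render_frame(scene: SyntheticScene, t: float, rng=None):
    """Render one frame: (pip3 volume, actin volume, binary mask, truth mesh).

    Volumes are (nz, ny, nx) float arrays; the shell is a Gaussian of width
    ``blur_sigma`` around the true surface (membrane after PSF blur), and
    Poisson noise, when enabled, is applied afterwards.
    """
    shape = scene.volume_shape()
    center = scene.center()
    dx, dy, dz = scene.voxel_size

    # dense surface sampling (finer than the analysis mesh) for the shell
    import trimesh
    unit = trimesh.creation.icosphere(subdivisions=6, radius=1.0)
    dirs = np.asarray(unit.vertices)
    pts, label, cap_param = scene_surface_points(scene, dirs, t)
    pip3_s, actin_s = _paint_channels(scene, dirs, label, cap_param, t)
    samples = center + pts

    # candidate voxels within ~4 sigma of the surface
    occ = np.zeros(shape, dtype=bool)
    iz = np.clip((samples[:, 2] / dz).astype(int), 0, shape[0] - 1)
    iy = np.clip((samples[:, 1] / dy).astype(int), 0, shape[1] - 1)
    ix = np.clip((samples[:, 0] / dx).astype(int), 0, shape[2] - 1)
    occ[iz, iy, ix] = True
    reach = (int(np.ceil(3.5 * scene.blur_sigma / dz)),
             int(np.ceil(3.5 * scene.blur_sigma / dy)),
             int(np.ceil(3.5 * scene.blur_sigma / dx)))
    occ = ndimage.maximum_filter(
        occ.astype(np.uint8), size=(2 * reach[0] + 1, 2 * reach[1] + 1,
                                    2 * reach[2] + 1)).astype(bool)
    cand = np.argwhere(occ)
    world = np.column_stack([(cand[:, 2] + 0.5) * dx, (cand[:, 1] + 0.5) * dy,
                             (cand[:, 0] + 0.5) * dz])
    tree = cKDTree(samples)
    dist, idx = tree.query(world, workers=-1)
    fall = np.exp(-dist ** 2 / (2 * scene.blur_sigma ** 2))
    vol_pip3 = np.zeros(shape)
    vol_actin = np.zeros(shape)
    vol_pip3[cand[:, 0], cand[:, 1], cand[:, 2]] = pip3_s[idx] * fall
    vol_actin[cand[:, 0], cand[:, 1], cand[:, 2]] = actin_s[idx] * fall

    if scene.noise_model == "poisson":
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        s = scene.noise_scale
        vol_pip3 = rng.poisson(vol_pip3 * s).astype(float) / s
        vol_actin = rng.poisson(vol_actin * s).astype(float) / s
    elif scene.noise_model != "none":
        raise ValueError(f"unknown noise model {scene.noise_model!r}")

    # binary cell mask from the star-convex radius function
    x, y, z = _voxel_centers_world(shape, scene.voxel_size)
    p = np.stack([x - center[0], y - center[1], z - center[2]], axis=-1)
    rad = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore"):
        u = p / np.maximum(rad, 1e-12)[..., None]
    rfun = scene_radius_function(scene, u.reshape(-1, 3), t)
    mask = (rad <= rfun.reshape(shape)).astype(np.uint8)

    mesh = scene_mesh(scene, t)
    return vol_pip3, vol_actin, mask, mesh


def make_cell_volume(scene: SyntheticScene, frame_times):
    """Render a two-channel volume series with ground truth per frame.

    Returns a list of dicts with keys ``t, pip3, actin, mask, mesh``.  The
    truth mesh carries per-vertex ``label`` (cup index), ``pip3_truth`` and
    ``actin_truth`` channels.  The same seed reproduces identical bytes; the
    ground truth is independent of the seed (only noise varies).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) > 1 and np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    rng = np.random.default_rng(scene.seed)
    frames = []
    for t in frame_times:
        pip3, actin, mask, mesh = render_frame(scene, float(t), rng=rng)
        frames.append({"t": float(t), "pip3": pip3, "actin": actin,
                       "mask": mask, "mesh": mesh})
    return frames


def truth_markers(scene: SyntheticScene, frame_times) -> pd.DataFrame:
    """Marker table (frame, t, x, y, z, track, label) at each cup apex."""
    rows = []
    center = scene.center()
    for fi, t in enumerate(np.asarray(frame_times, dtype=float)):
        for k, cup in enumerate(scene.cups, start=1):
            axis = np.asarray(cup.axis)
            pts, _, _ = scene_surface_points(scene, axis[None, :], t)
            p = center + pts[0]
            rows.append({"frame": fi, "t": t, "x": p[0], "y": p[1], "z": p[2],
                         "track": k, "label": f"cup{k}"})
    return pd.DataFrame(rows)


# -- domain life-history table ------------------------------------------------------


def make_domain_timeseries(n_domains: int, rate_mean: float = 0.3,
                           rate_sd: float = 0.34,
                           lifetime_range=(30.0, 130.0),
                           stall_fraction: float = 0.6, dt: float = 2.5,
                           seed: int = 0, cell_radius: float = 5.0,
                           initial_area: float = 0.5,
                           closure_s: float = 20.0) -> pd.DataFrame:
    """Closed-form domain tracks: linear expansion, stall, then closure.

    Each track's area grows linearly at its own rate (Gaussian across the
    cohort) until ``stall_fraction`` of its lifetime, then holds; perimeter
    and depth follow the cup-on-sphere closed forms, with the perimeter
    tapered to zero over the final ``closure_s`` seconds (lip closure).
    Columns: track, frame, t, area, perimeter, depth, plus per-track truth
    (rate_true, lifetime, stall_time).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not 0 < stall_fraction <= 1:
        raise ValueError("stall_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = lifetime_range
    rows = []
    for track in range(n_domains):
        rate = max(rate_mean + rate_sd * rng.standard_normal(), 0.02)
        lifetime = float(rng.uniform(lo, hi))
        t_stall = stall_fraction * lifetime
        times = np.arange(0.0, lifetime, dt)
        times = np.r_[times, lifetime]      # closure frame at exactly t = L
        area = initial_area + rate * np.minimum(times, t_stall)
        area = np.minimum(area, 0.9 * 2 * np.pi * cell_radius ** 2)
        ang = np.arccos(1.0 - area / (2.0 * np.pi * cell_radius ** 2))
        perim = cap_perimeter(cell_radius, ang)
        depth = cap_depth(cell_radius, ang)
        taper = np.clip((lifetime - times) / closure_s, 0.0, 1.0)
        perim = perim * taper
        for fi, (t, a, p, d) in enumerate(zip(times, area, perim, depth)):
            rows.append({"track": track, "frame": fi, "t": t, "area": a,
                         "perimeter": p, "depth": d, "rate_true": rate,
                         "lifetime": lifetime, "stall_time": t_stall})
    return pd.DataFrame(rows)
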