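"""Stalled-wave contour model of macropinocytic cup mechanics.

The cell cross-section is an overdamped closed 2D polyline carrying four
forces per vertex:

* tension   — linear elastic stress from stretching each segment relative
              to its rest length (coefficient k_T);
* bending   — gradient of (k_B/2) * sum of squared exterior turning angles,
              a scale-invariant discrete curvature penalty whose gradient
              vanishes identically on the regular circle;
* area      — a pressure-like restoring force k_A (A/A0 - 1) applied along
              the (outward) area gradient, conserving the enclosed area;
* polymerization — k_P times a Gaussian (sigma_P) of arclength distance to
              each PIP3-domain boundary point, along the outward normal.

The PIP3 domain is an arc whose endpoints are material points tracked in
rest-arclength coordinates.  While expanding, the arc length d obeys
dd/dt = v_P / d; after ``stall_time`` the endpoints are frozen in material
coordinates.  Optionally the reaction to the polymerization force (the
retrograde-flow load) is applied to the cup membrane, directed along the
membrane from the lip toward the domain midpoint.

3D readouts (domain area, vesicle volume) come from surfaces of revolution
about the cup's symmetry axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree



@dataclass
class ModelParams:
    """Contour-model parameters (μm, s, force units with drag = 1)."""

    k_T: float = 20.0               # tension (elastic) coefficient
    k_B: float = 0.05               # bending coefficient (constant)
    k_A: float = 50.0               # area-conservation coefficient (constant)
    k_P: float = 50.0               # polymerization force coefficient
    sigma_P: float = 0.25           # μm, width of the boundary force
    v_P: float = 0.1                # μm²/s, domain expansion speed = v_P / d
    stall_time: float = 60.0        # s; domain frozen in material coords after
    retrograde_coupling: float = 0.0
    drag: float = 1.0
    radius: float = 5.0             # μm, initial circle
    n_segments: int = 1000
    domain_width0: float = 0.02     # μm, initial PIP3 patch
    t_max: float = 250.0            # s
    disp_cap: float = 0.01          # μm max vertex displacement per step
    dt_max: float = 2e-3            # s, further limited by stiffness
    contact_tol: float | None = None   # default: 2 x target segment length
    min_contact_arc: float = 1.0    # μm arc separation for a true contact
    lip_vicinity: float = 2.0       # μm; contact within this arc distance of
    #                                 a domain endpoint counts as lip contact
    check_every: int = 200          # integration steps between checks
    tube_aspect: float = 2.0        # depth/width threshold for "tube"

    def __post_init__(self):
        for name in ("k_T", "k_B", "k_A", "k_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.retrograde_coupling <= 1:
            raise ValueError("retrograde_coupling must be in [0, 1]")

    @property
    def target_segment(self) -> float:
        return 2 * np.pi * self.radius / self.n_segments

    def contact_distance(self) -> float:
        return (self.contact_tol if self.contact_tol is not None
                else 2.0 * self.target_segment)


@dataclass
class Contour:
    """State of the closed contour and its PIP3-domain arc."""

    x: np.ndarray                   # (n, 2) vertex positions, CCW
    rest: np.ndarray                # (n,) rest length of segment i -> i+1
    m1: float                       # material (rest-arclength) coords of the
    m2: float                       # domain endpoints, 0 <= m1 < m2 < M
    A0: float
    t: float = 0.0
    stalled: bool = False

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def M(self) -> float:
        return float(self.rest.sum())

    def seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.roll(self.x, -1, 0) - self.x, axis=1)

    def arclengths(self) -> np.ndarray:
        """Physical arclength coordinate of each vertex (vertex 0 at 0)."""
        L = self.seg_lengths()
        return np.r_[0.0, np.cumsum(L)[:-1]]

    def material_coords(self) -> np.ndarray:
        return np.r_[0.0, np.cumsum(self.rest)[:-1]]

    def phys_of_material(self, m: float) -> float:
        mc = np.r_[self.material_coords(), self.M]
        sc = np.r_[self.arclengths(), self.seg_lengths().sum()]
        return float(np.interp(m % self.M, mc, sc))

    def material_of_phys(self, s: float) -> float:
        mc = np.r_[self.material_coords(), self.M]
        Ltot = float(self.seg_lengths().sum())
        sc = np.r_[self.arclengths(), Ltot]
        return float(np.interp(s % Ltot, sc, mc))

    def domain_phys_length(self) -> float:
        s1 = self.phys_of_material(self.m1)
        s2 = self.phys_of_material(self.m2)
        Ltot = float(self.seg_lengths().sum())
        return (s2 - s1) % Ltot

    def domain_material_length(self) -> float:
        return (self.m2 - self.m1) % self.M

    def in_domain(self) -> np.ndarray:
        """Boolean per vertex: material coordinate within the domain arc."""
        mc = self.material_coords()
        if self.m1 <= self.m2:
            return (mc >= self.m1) & (mc <= self.m2)
        return (mc >= self.m1) | (mc <= self.m2)

    def area(self) -> float:
        x = self.x
        return float(0.5 * np.sum(x[:, 0] * np.roll(x[:, 1], -1)
                                  - np.roll(x[:, 0], -1) * x[:, 1]))


def make_circle(params: ModelParams) -> Contour:
    """Initial condition: circle of ``radius`` with the domain patch at the
    top (centred on the +y axis)."""
    n = params.n_segments
    phi = 2 * np.pi * (np.arange(n) + 0.5) / n + np.pi / 2
    x = params.radius * np.column_stack([np.cos(phi), np.sin(phi)])
    # rest length = the initial chord length, so the start state is an exact
    # force-free equilibrium of the discrete energies
    rest = np.full(n, 2 * params.radius * np.sin(np.pi / n))
    M = rest.sum()
    half = params.domain_width0 / 2
    # domain centred at material coordinate of the top vertex region; the
    # contour starts unstretched so material == physical arclength
    c = Contour(x=x, rest=rest, m1=0.0, m2=0.0, A0=0.0)
    s_top = 0.0  # vertex 0 sits at angle pi/2 + half step; use its arclength
    c.m1 = (s_top - half) % M
    c.m2 = (s_top + half) % M
    c.A0 = c.area()
    if c.A0 < 0:
        raise AssertionError("contour must be oriented counter-clockwise")
    return c


# -- forces (numpy reference implementation) ----------------------------------------


def _perp_cw(v):
    """Rotate -90 degrees: outward direction for a CCW contour's tangent."""
    return np.column_stack([v[:, 1], -v[:, 0]])


def compute_forces(c: Contour, p: ModelParams, parts: bool = False,
                   _geom=None):
    """Total force per vertex (and optionally the four components)."""
    x = c.x
    if _geom is None:
        seg = np.roll(x, -1, 0) - x
        L = np.sqrt(np.einsum("ij,ij->i", seg, seg))
        s = np.empty(len(x))
        s[0] = 0.0
        np.cumsum(L[:-1], out=s[1:])
        s1 = c.phys_of_material(c.m1)
        s2 = c.phys_of_material(c.m2)
    else:
        seg, L, s, s1, s2 = _geom
    tvec = seg / L[:, None]
    strain = (L - c.rest) / c.rest
    f_tension = p.k_T * (strain[:, None] * tvec
                         - np.roll(strain, 1)[:, None] * np.roll(tvec, 1, 0))

    u = x - np.roll(x, 1, 0)            # u_j = x_j - x_{j-1}
    v = seg                              # v_j = x_{j+1} - x_j
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = np.einsum("ij,ij->i", u, v)
    theta = np.arctan2(cross, dot)
    abar = 0.5 * (L + np.roll(L, 1))    # vertex-centred arclength weight
    perp_u = np.column_stack([-u[:, 1], u[:, 0]])
    perp_v = np.column_stack([-v[:, 1], v[:, 0]])
    gu = -perp_u / np.einsum("ij,ij->i", u, u)[:, None]
    gv = perp_v / np.einsum("ij,ij->i", v, v)[:, None]
    # E = (k_B/2) sum theta_j^2 / abar_j  (squared curvature x length)
    w = (theta / abar)[:, None]
    f_bending = -p.k_B * (np.roll(w * gv, 1, 0)          # dtheta_{i-1}/dx_i
                          + w * (gu - gv)                # dtheta_i/dx_i
                          - np.roll(w * gu, -1, 0))      # dtheta_{i+1}/dx_i
    # arclength-gradient part: d(1/abar_j)/dx via the two segment lengths
    cseg = -0.25 * (theta ** 2 / abar ** 2)              # per-segment weight
    wseg = cseg + np.roll(cseg, -1)                      # segment i in abar_i, abar_{i+1}
    f_bending += -p.k_B * (np.roll((wseg)[:, None] * tvec, 1, 0)
                           - (wseg)[:, None] * tvec)

    A = c.area()
    span = np.roll(x, -1, 0) - np.roll(x, 1, 0)
    grad_a = 0.5 * _perp_cw(span)
    f_area = -p.k_A * (A / c.A0 - 1.0) * grad_a

    ell = abar
    Ltot = float(L.sum())
    mag = _poly_magnitude(s, s1, s2, Ltot, p.sigma_P)
    normal = _perp_cw(span)
    normal /= np.sqrt(np.einsum("ij,ij->i", normal, normal))[:, None]
    f_poly = (p.k_P * ell * mag)[:, None] * normal

    f_retro = np.zeros_like(x)
    if p.retrograde_coupling > 0:
        total = p.retrograde_coupling * float(np.abs(p.k_P * ell * mag).sum())
        dom = c.in_domain()
        if dom.any():
            w = ell[dom] / ell[dom].sum()
            mid = (c.m1 + c.domain_material_length() / 2) % c.M
            mc = c.material_coords()[dom]
            ahead = ((mid - mc) % c.M) < c.M / 2   # midpoint lies forward
            tan = span / np.sqrt(np.einsum("ij,ij->i", span,
                                           span))[:, None]
            direction = np.where(ahead[:, None], tan[dom], -tan[dom])
            f_retro[dom] = (total * w)[:, None] * direction

    f = f_tension + f_bending + f_area + f_poly + f_retro
    if parts:
        return f, {"tension": f_tension, "bending": f_bending,
                   "area": f_area, "poly": f_poly, "retro": f_retro}
    return f


def _poly_magnitude(s, s1, s2, Ltot, sigma):
    d1 = np.abs((s - s1 + Ltot / 2) % Ltot - Ltot / 2)
    d2 = np.abs((s - s2 + Ltot / 2) % Ltot - Ltot / 2)
    g = (np.exp(-d1 ** 2 / (2 * sigma ** 2))
         + np.exp(-d2 ** 2 / (2 * sigma ** 2)))
    return g / (sigma * np.sqrt(2 * np.pi))


def tension_profile(c: Contour, p: ModelParams) -> np.ndarray:
    """Per-vertex elastic tension k_T * strain (mean of adjacent segments)."""
    L = c.seg_lengths()
    strain = (L - c.rest) / c.rest
    return p.k_T * 0.5 * (strain + np.roll(strain, 1))


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _forces_kernel(x, rest, s, L, s1, s2, M, mc, m1, m2, k_T, k_B, k_A,
                       k_P, sigma, coupling, A0):   # pragma: no cover
        n = x.shape[0]
        Ltot = 0.0
        for i in range(n):
            Ltot += L[i]
        A = 0.0
        for i in range(n):
            j = (i + 1) % n
            A += x[i, 0] * x[j, 1] - x[j, 0] * x[i, 1]
        A *= 0.5
        ca = -k_A * (A / A0 - 1.0)
        F = np.zeros((n, 2))
        theta = np.empty(n)
        wth = np.empty(n)
        cseg = np.empty(n)
        gux = np.empty(n)
        guy = np.empty(n)
        gvx = np.empty(n)
        gvy = np.empty(n)
        tot_poly = 0.0
        for j in range(n):
            jm = (j - 1) % n
            jp = (j + 1) % n
            ux = x[j, 0] - x[jm, 0]
            uy = x[j, 1] - x[jm, 1]
            vx = x[jp, 0] - x[j, 0]
            vy = x[jp, 1] - x[j, 1]
            theta[j] = np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)
            abar = 0.5 * (L[jm] + L[j])
            wth[j] = theta[j] / abar
            cseg[j] = -0.25 * theta[j] * theta[j] / (abar * abar)
            uu = ux * ux + uy * uy
            vv = vx * vx + vy * vy
            gux[j] = uy / uu
            guy[j] = -ux / uu
            gvx[j] = -vy / vv
            gvy[j] = vx / vv
        for i in range(n):
            im = (i - 1) % n
            ip = (i + 1) % n
            ti_x = (x[ip, 0] - x[i, 0]) / L[i]
            ti_y = (x[ip, 1] - x[i, 1]) / L[i]
            tm_x = (x[i, 0] - x[im, 0]) / L[im]
            tm_y = (x[i, 1] - x[im, 1]) / L[im]
            si = (L[i] - rest[i]) / rest[i]
            sm = (L[im] - rest[im]) / rest[im]
            F[i, 0] += k_T * (si * ti_x - sm * tm_x)
            F[i, 1] += k_T * (si * ti_y - sm * tm_y)
            gx = 0.5 * (x[ip, 1] - x[im, 1])
            gy = -0.5 * (x[ip, 0] - x[im, 0])
            F[i, 0] += ca * gx
            F[i, 1] += ca * gy
            d1 = abs((s[i] - s1 + Ltot / 2) % Ltot - Ltot / 2)
            d2 = abs((s[i] - s2 + Ltot / 2) % Ltot - Ltot / 2)
            g = 0.0
            if d1 < 8.0 * sigma:
                g += np.exp(-d1 * d1 / (2 * sigma * sigma))
            if d2 < 8.0 * sigma:
                g += np.exp(-d2 * d2 / (2 * sigma * sigma))
            if g > 0.0:
                g /= sigma * np.sqrt(2.0 * np.pi)
                ell = 0.5 * (L[i] + L[im])
                gn = np.sqrt(gx * gx + gy * gy)
                fp = k_P * ell * g
                tot_poly += fp
                F[i, 0] += fp * gx / gn
                F[i, 1] += fp * gy / gn
            # bending: theta part and arclength-gradient part
            fx = wth[im] * gvx[im] + wth[i] * (gux[i] - gvx[i]) \
                - wth[ip] * gux[ip]
            fy = wth[im] * gvy[im] + wth[i] * (guy[i] - gvy[i]) \
                - wth[ip] * guy[ip]
            F[i, 0] -= k_B * fx
            F[i, 1] -= k_B * fy
            wi = cseg[i] + cseg[ip]
            wm = cseg[im] + cseg[i]
            F[i, 0] += k_B * (wi * ti_x - wm * tm_x)
            F[i, 1] += k_B * (wi * ti_y - wm * tm_y)
        if coupling > 0.0:
            mm1 = m1 % M
            mm2 = m2 % M
            dlen = (mm2 - mm1) % M
            mid = (mm1 + dlen / 2.0) % M
            wsum = 0.0
            for i in range(n):
                if ((mc[i] - mm1) % M) <= dlen:
                    wsum += 0.5 * (L[i] + L[(i - 1) % n])
            if wsum > 0.0:
                tot = coupling * tot_poly
                for i in range(n):
                    if ((mc[i] - mm1) % M) <= dlen:
                        im = (i - 1) % n
                        ip = (i + 1) % n
                        ell = 0.5 * (L[i] + L[im])
                        tx = x[ip, 0] - x[im, 0]
                        ty = x[ip, 1] - x[im, 1]
                        tn = np.sqrt(tx * tx + ty * ty)
                        sgn = 1.0 if ((mid - mc[i]) % M) < M / 2 else -1.0
                        F[i, 0] += tot * ell / wsum * sgn * tx / tn
                        F[i, 1] += tot * ell / wsum * sgn * ty / tn
        return F

    HAVE_NUMBA = True
except ImportError:                                         # pragma: no cover
    HAVE_NUMBA = False


# -- integration --------------------------------------------------------------------


def _imex_spectrum(n: int, p: ModelParams, rest_min: float):
    """Implicit damping eigenvalues for the periodic uniform contour.

    The stiffest force linearisations are the tension chain (a graph
    Laplacian with spring constant k_T / rest) and the curvature penalty
    (a biharmonic with coefficient ~1.5 k_B / l^3).  Treating these
    spectrally (the contour is periodic and kept uniform by remeshing)
    makes the step unconditionally stable for both, leaving dt limited
    only by accuracy and by the soft polymerization/area forces.
    """
    k = np.arange(n // 2 + 1)
    d2 = 2.0 - 2.0 * np.cos(2.0 * np.pi * k / n)
    l0 = p.target_segment
    lam = (p.k_T / max(rest_min, 1e-6)) * d2 \
        + (1.5 * p.k_B / l0 ** 3) * d2 ** 2
    return lam


def step(c: Contour, p: ModelParams, dt: float | None = None) -> float:
    """Advance the contour one IMEX step; returns the dt actually taken.

    The full nonlinear force is evaluated explicitly and filtered through
    (1 + dt * lambda_k)^{-1} in Fourier space, where lambda_k bounds the
    tension and bending stiffness; the domain arc is then expanded (before
    stall) with dd/dt = v_P / d, both endpoints advancing symmetrically in
    physical arclength, and converted back to material coordinates.
    """
    x = c.x
    n = c.n
    seg = np.roll(x, -1, 0) - x
    L = np.sqrt(np.einsum("ij,ij->i", seg, seg))
    Ltot = float(L.sum())
    s = np.empty(n)
    s[0] = 0.0
    np.cumsum(L[:-1], out=s[1:])
    mc = np.empty(n)
    mc[0] = 0.0
    np.cumsum(c.rest[:-1], out=mc[1:])
    mc_ext = np.append(mc, c.M)
    s_ext = np.append(s, Ltot)
    s1 = float(np.interp(c.m1 % c.M, mc_ext, s_ext))
    s2 = float(np.interp(c.m2 % c.M, mc_ext, s_ext))

    if HAVE_NUMBA:
        F = _forces_kernel(x, c.rest, s, L, s1, s2, c.M, mc, c.m1, c.m2,
                           p.k_T, p.k_B, p.k_A, p.k_P, p.sigma_P,
                           p.retrograde_coupling, c.A0)
    else:
        F = compute_forces(c, p, _geom=(seg, L, s, s1, s2))
    if not np.isfinite(F).all():
        raise FloatingPointError("non-finite force (contour degenerate)")
    if dt is None:
        vmax = float(np.sqrt(np.einsum("ij,ij->i", F, F).max())) / p.drag
        dt = min(p.dt_max, p.disp_cap / max(vmax, 1e-12))
    lam = _imex_spectrum(n, p, float(c.rest.min()))
    fh = np.fft.rfft(F, axis=0)
    fh /= (1.0 + dt * lam)[:, None]
    c.x = x + (dt / p.drag) * np.fft.irfft(fh, n=n, axis=0)

    if not c.stalled:
        if c.t + dt >= p.stall_time:
            c.stalled = True
        d = (s2 - s1) % Ltot
        dd = dt * p.v_P / max(d, 1e-6)
        c.m1 = float(np.interp((s1 - dd / 2.0) % Ltot, s_ext, mc_ext))
        c.m2 = float(np.interp((s2 + dd / 2.0) % Ltot, s_ext, mc_ext))
    c.t += dt
    return dt


def advance(c: Contour, p: ModelParams, n_steps: int) -> Contour:
    for _ in range(n_steps):
        step(c, p)
    return c



# -- remeshing ----------------------------------------------------------------------


def remesh(c: Contour, p: ModelParams) -> Contour:
    """Resample the polyline to uniform ~target segment length.

    New vertices are placed uniformly in physical arclength along a
    periodic cubic spline through the old vertices (linear resampling would
    cut corners in stretched high-curvature regions and drift the
    readouts); each new segment's rest length is the material
    (rest-arclength) content of the physical span it covers, so the elastic
    state and the domain endpoints' material coordinates are preserved
    exactly.
    """
    from scipy.interpolate import CubicSpline
    L = c.seg_lengths()
    Ltot = float(L.sum())
    n_new = max(int(round(Ltot / p.target_segment)), 16)
    s_old = np.r_[c.arclengths(), Ltot]
    x_old = np.vstack([c.x, c.x[:1]])
    m_old = np.r_[c.material_coords(), c.M]
    s_new = Ltot * np.arange(n_new) / n_new
    spline = CubicSpline(s_old, x_old, bc_type="periodic", axis=0)
    x_new = spline(s_new)
    # monotone cubic for the material coordinate (no overshoot)
    from scipy.interpolate import PchipInterpolator
    m_new = PchipInterpolator(s_old, m_old)(s_new)
    rest_new = np.diff(np.r_[m_new, c.M])
    # keep the material origin anchored at old vertex 0 (s = 0)
    return Contour(x=x_new, rest=rest_new, m1=c.m1, m2=c.m2, A0=c.A0,
                   t=c.t, stalled=c.stalled)


def _needs_remesh(c: Contour, p: ModelParams) -> bool:
    L = c.seg_lengths()
    return bool((L.min() < 0.7 * p.target_segment)
                or (L.max() > 1.5 * p.target_segment))


# -- contact detection and readouts -------------------------------------------------


def find_contact(c: Contour, p: ModelParams):
    """Closest self-approach pair with arc separation > min_contact_arc.

    Returns ``(i, j)`` if two such vertices come within the contact
    tolerance, else None.
    """
    tol = p.contact_distance()
    s = c.arclengths()
    Ltot = float(c.seg_lengths().sum())
    pairs = cKDTree(c.x).query_pairs(tol, output_type="ndarray")
    if len(pairs) == 0:
        return None
    arc = np.abs((s[pairs[:, 0]] - s[pairs[:, 1]] + Ltot / 2) % Ltot
                 - Ltot / 2)
    ok = arc > p.min_contact_arc
    if not ok.any():
        return None
    d = np.linalg.norm(c.x[pairs[ok, 0]] - c.x[pairs[ok, 1]], axis=1)
    best = pairs[ok][int(np.argmin(d))]
    return int(best[0]), int(best[1])


def cup_geometry(c: Contour):
    """(depth, width, base, mouth_mid) of the cup from the domain arc.

    Width is the distance between the domain endpoints (the lip); depth is
    the distance from the domain-midpoint membrane (the base) to the
    midpoint of the lip chord.
    """
    p1 = _point_at_material(c, c.m1)
    p2 = _point_at_material(c, c.m2)
    mid = (c.m1 + c.domain_material_length() / 2) % c.M
    base = _point_at_material(c, mid)
    mouth = 0.5 * (p1 + p2)
    width = float(np.linalg.norm(p2 - p1))
    depth = float(np.linalg.norm(mouth - base))
    return depth, width, base, mouth


def _point_at_material(c: Contour, m: float) -> np.ndarray:
    s = c.phys_of_material(m)
    s_old = np.r_[c.arclengths(), float(c.seg_lengths().sum())]
    x_old = np.vstack([c.x, c.x[:1]])
    return np.array([np.interp(s, s_old, x_old[:, 0]),
                     np.interp(s, s_old, x_old[:, 1])])


def revolve_polyline(points, axis_point, axis_dir):
    """Surface area and volume of revolution of an open polyline.

    The polyline is expressed in (z, r) coordinates about the axis; segments
    are revolved as conical frusta (lateral area = pi (r1 + r2) slant,
    volume via the exact frustum formula), using |r|.  Returns
    ``(area, volume)``; volume is meaningful when the polyline spans a
    closed generatrix from axis to axis (or is closed by the caller).
    """
    a = np.asarray(axis_dir, dtype=float)
    a /= np.linalg.norm(a)
    rel = np.asarray(points, dtype=float) - np.asarray(axis_point)
    z = rel @ a
    r = np.abs(np.linalg.norm(rel - z[:, None] * a[None, :], axis=1))
    slant = np.hypot(np.diff(z), np.diff(r))
    area = float(np.sum(np.pi * (r[:-1] + r[1:]) * slant))
    vol = float(np.sum(np.pi / 3.0 * (r[:-1] ** 2 + r[:-1] * r[1:]
                                      + r[1:] ** 2) * np.diff(z)))
    return area, abs(vol)


def domain_surface_area(c: Contour) -> float:
    """3D area of the domain arc revolved about the cup symmetry axis."""
    axis_p, axis_d = symmetry_axis(c)
    pts = _arc_points(c, c.m1, c.m2)
    return revolve_polyline(pts, axis_p, axis_d)[0]


def symmetry_axis(c: Contour):
    mid = (c.m1 + c.domain_material_length() / 2) % c.M
    base = _point_at_material(c, mid)
    centroid = c.x.mean(axis=0)
    d = base - centroid
    n = np.linalg.norm(d)
    if n < 1e-12:
        d, n = np.array([0.0, 1.0]), 1.0
    return centroid, d / n


def _arc_points(c: Contour, ma: float, mb: float, n_samples: int = 400):
    dlen = (mb - ma) % c.M
    ms = (ma + dlen * np.linspace(0, 1, n_samples)) % c.M
    return np.vstack([_point_at_material(c, m) for m in ms])


# -- simulation driver --------------------------------------------------------------


@dataclass
class SimResult:
    classification: str             # lip_closure | tube | open_cup
    closure_time: float             # s; inf if no closure
    vesicle_volume: float           # μm³ (surface of revolution); 0 if open
    aspect_ratio: float             # cup depth / width at end or closure
    domain_perimeter: float         # μm, 2 pi x lip radius at end or closure
    domain_length: float            # μm, final physical arc length d
    base_closure_candidate: bool = False   # tube whose wall geometry admits
    #                                        the base-closure hand-off
    contour: Contour = field(repr=False, default=None)
    history: list = field(repr=False, default_factory=list)
    ambiguous: bool = False


def simulate(params: ModelParams, record_every: float = 5.0,
             contour: Contour | None = None) -> SimResult:
    """Run the contour model to closure or t_max and classify the outcome."""
    c = contour if contour is not None else make_circle(params)
    history = []
    contact = None
    next_record = 0.0
    while c.t < params.t_max:
        advance(c, params, params.check_every)
        if not np.isfinite(c.x).all():
            raise FloatingPointError(
                f"contour diverged at t={c.t:.2f}s (NaN in state)")
        if c.t >= next_record:
            depth, width, _, _ = cup_geometry(c)
            history.append({"t": c.t, "d": c.domain_phys_length(),
                            "depth": depth, "width": width,
                            "area": c.area()})
            next_record = c.t + record_every
        contact = find_contact(c, params)
        if contact is not None:
            break
        if _needs_remesh(c, params):
            c = remesh(c, params)
    depth, width, base, mouth = cup_geometry(c)
    aspect = depth / max(width, 1e-9)
    d_phys = c.domain_phys_length()
    lip_r = width / 2.0
    if contact is not None:
        cls, vol = _classify_contact(c, contact, params)
        if cls == "lip_closure":
            return SimResult(cls, c.t, vol, aspect, 2 * np.pi * lip_r,
                             d_phys, contour=c, history=history)
        # waist (wall-wall) contact: a tube whose 3D pinch is decided by the
        # axisymmetric base-closure model
        return SimResult("tube", np.inf, 0.0, aspect, 2 * np.pi * lip_r,
                         d_phys, base_closure_candidate=True, contour=c,
                         history=history)
    if aspect >= params.tube_aspect:
        # a delaminated wall section of ~0.8 x the tube depth supports the
        # base-closure hand-off when its length-to-width ratio exceeds 0.66
        candidate = 0.8 * depth / max(width, 1e-9) > 0.66
        return SimResult("tube", np.inf, 0.0, aspect, 2 * np.pi * lip_r,
                         d_phys, base_closure_candidate=candidate,
                         contour=c, history=history)
    return SimResult("open_cup", np.inf, 0.0, aspect, 2 * np.pi * lip_r,
                     d_phys, contour=c, history=history)


def _classify_contact(c: Contour, contact, p: ModelParams):
    """Classify a self-contact and measure the enclosed vesicle.

    A contact with both points within ``lip_vicinity`` arc distance of a
    domain endpoint is a lip closure (the flanks seal the orifice); contact
    further away is a waist/wall contact of a tube.  For lip closures the
    vesicle is the cut-off arc closed by the contact chord, revolved about
    the symmetry axis.
    """
    i, j = contact
    s = c.arclengths()
    Ltot = float(c.seg_lengths().sum())
    s_marks = (c.phys_of_material(c.m1), c.phys_of_material(c.m2))

    def arc_to_marks(si):
        return min(abs((si - sm + Ltot / 2) % Ltot - Ltot / 2)
                   for sm in s_marks)

    if max(arc_to_marks(s[i]), arc_to_marks(s[j])) > p.lip_vicinity:
        return "waist", 0.0
    mc = c.material_coords()
    mi, mj = mc[i], mc[j]
    # the vesicle is the arc between the contact points that contains the
    # domain midpoint (the cup base)
    mid = (c.m1 + c.domain_material_length() / 2) % c.M

    def contains(ma, mb, m):
        return ((m - ma) % c.M) <= ((mb - ma) % c.M)

    lo, hi = (mi, mj) if contains(mi, mj, mid) else (mj, mi)
    axis_p, axis_d = symmetry_axis(c)
    pts = _arc_points(c, lo, hi, n_samples=600)
    closed = np.vstack([pts, pts[:1]])          # close with the contact chord
    _, vol = revolve_polyline(closed, axis_p, axis_d)
    return "lip_closure", vol


def expand_domain_closed_form(d0: float, v_P: float, t) -> np.ndarray:
    """Free-expansion solution d(t) = sqrt(d0^2 + 2 v_P t) of dd/dt = v_P/d."""
    return np.sqrt(d0 ** 2 + 2.0 * v_P * np.asarray(t, dtype=float))


def phase_scan(k_T_values, k_P_values, base: ModelParams,
               record_every: float = 10.0):
    """One deterministic run per (k_T, k_P) grid point.

    Returns a DataFrame of outcome class and the four readouts (domain
    perimeter, vesicle volume, closure time, aspect ratio); individual run
    failures are recorded and the scan continues.
    """
    import pandas as pd
    rows = []
    for kt in k_T_values:
        for kp in k_P_values:
            p = replace(base, k_T=float(kt), k_P=float(kp))
            try:
                r = simulate(p, record_every=record_every)
                rows.append({"k_T": kt, "k_P": kp,
                             "classification": r.classification,
                             "closure_time": r.closure_time,
                             "vesicle_volume": r.vesicle_volume,
                             "aspect_ratio": r.aspect_ratio,
                             "domain_perimeter": r.domain_perimeter})
            except (FloatingPointError, ValueError) as e:
                warnings.warn(f"run (k_T={kt}, k_P={kp}) failed: {e}")
                rows.append({"k_T": kt, "k_P": kp,
                             "classification": "failed",
                             "closure_time": np.nan, "vesicle_volume": np.nan,
                             "aspect_ratio": np.nan,
                             "domain_perimeter": np.nan})
    return pd.DataFrame(rows)
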