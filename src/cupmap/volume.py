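"""Volume-level preprocessing: channel registration, isosurface extraction
from the binary cell mask, and 3-way maximum-intensity projection montages."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

from .mesh import SurfaceMesh, from_trimesh


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalised cross-correlation of two equal-shape arrays."""
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a * a).sum() * (b * b).sum())
    if den == 0:
        raise ValueError("zero-variance volume: correlation undefined")
    return float((a * b).sum() / den)


def _shift_overlap(a, b, shift):
    """Overlapping views of a and b after translating b by ``shift``."""
    sl_a, sl_b = [], []
    for s, n in zip(shift, a.shape):
        if s >= 0:
            sl_a.append(slice(s, n))
            sl_b.append(slice(0, n - s))
        else:
            sl_a.append(slice(0, n + s))
            sl_b.append(slice(-s, n))
    return a[tuple(sl_a)], b[tuple(sl_b)]


def register_channels(vol_a, vol_b, max_shift: int = 5):
    """Integer translation of channel b onto channel a by exhaustive NCC.

    ``vol_a``/``vol_b`` may be single volumes or lists of volumes (frames of
    a video); the translation maximising the *mean* normalised
    cross-correlation over all frames is returned, so one constant shift is
    applied to a whole video.  Returns ``(shift, score)`` with shift in
    (z, y, x) voxels, each component in [-max_shift, max_shift]; applying
    the shift to ``vol_b`` (see :func:`apply_shift`) aligns it onto
    ``vol_a``.  If the optimum sits on the search boundary a warning notes
    that the true shift may lie out of range.
    """
    frames_a = vol_a if isinstance(vol_a, (list, tuple)) else [vol_a]
    frames_b = vol_b if isinstance(vol_b, (list, tuple)) else [vol_b]
    if len(frames_a) != len(frames_b):
        raise ValueError("channel videos differ in frame count")
    for fa, fb in zip(frames_a, frames_b):
        if fa.shape != fb.shape:
            raise ValueError("channel volumes differ in shape")
        if np.ptp(fa) == 0 or np.ptp(fb) == 0:
            raise ValueError("zero-variance volume: correlation undefined")
    best, best_score = None, -np.inf
    rng = range(-max_shift, max_shift + 1)
    for shift in itertools.product(rng, rng, rng):
        score = 0.0
        for fa, fb in zip(frames_a, frames_b):
            a, b = _shift_overlap(fa.astype(float), fb.astype(float), shift)
            score += _ncc(a, b)
        score /= len(frames_a)
        if score > best_score or (score == best_score and shift < best):
            best, best_score = shift, score
    if any(abs(s) == max_shift for s in best):
        warnings.warn(f"registration optimum {best} lies on the search "
                      f"boundary; the true shift may exceed {max_shift}")
    return best, best_score


def apply_shift(vol, shift):
    """Translate a volume by an integer (z, y, x) shift, zero-filling."""
    out = np.zeros_like(vol)
    a, b = _shift_overlap(out, vol, tuple(shift))
    a[...] = b
    return out


def extract_surface(binary_mask, voxel_size,
                    smooth_sigma: float = 1.0) -> SurfaceMesh:
    """Closed triangle mesh of the mask's largest component in μm coordinates.

    Marching cubes at level 0.5 on the zero-padded mask; ``voxel_size`` is
    (x, y, z) μm so anisotropy is honoured.  The binary mask is pre-smoothed
    with a Gaussian of ``smooth_sigma`` voxels so the staircase voxelisation
    does not inflate the surface area (objects too small to survive the
    smoothing fall back to the raw mask).  Output vertices are in world
    (x, y, z) μm with voxel centres at (i + 0.5) * pitch, matching the
    synthetic renderer's convention.
    """
    mask = np.asarray(binary_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask: no surface to extract")
    labels, n = ndimage.label(mask)
    if n > 1:
        warnings.warn(f"mask has {n} components; keeping the largest")
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    dx, dy, dz = voxel_size
    padded = np.pad(mask, 1).astype(float)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(padded, smooth_sigma)
        if smoothed.max() > 0.5:
            padded = smoothed
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=(dz, dy, dx))
    # marching-cubes vertices are (z, y, x); convert to world (x, y, z) and
    # undo the 1-voxel pad, placing voxel centres at (i + 0.5) * pitch
    world = np.column_stack([verts[:, 2] - dx / 2, verts[:, 1] - dy / 2,
                             verts[:, 0] - dz / 2])
    import trimesh
    tm = trimesh.Trimesh(world, faces[:, ::-1], process=True)
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    return from_trimesh(tm)


def threeway_projection(volume, voxel_size):
    """3-way maximum-intensity projection montage of one volume.

    The volume is rescaled in z to isotropic resolution, then the z
    projection (x-y plane) is placed top-left, the y projection (x-z) bottom
    left and the x projection (y-z, transposed) top-right, with shared axes
    aligned.  The canvas is (Y + Z) tall by (X + Z) wide.
    """
    dx, dy, dz = voxel_size
    vol = np.asarray(volume, dtype=float)
    zoom = dz / dx
    if abs(zoom - 1) > 1e-6:
        vol = ndimage.zoom(vol, (zoom, 1, 1), order=1)
    nz, ny, nx = vol.shape
    pz = vol.max(axis=0)            # (y, x)
    py = vol.max(axis=1)            # (z, x)
    px = vol.max(axis=2).T          # (y, z)
    canvas = np.zeros((ny + nz, nx + nz), dtype=vol.dtype)
    canvas[:ny, :nx] = pz
    canvas[ny:, :nx] = py
    canvas[:ny, nx:] = px
    return canvas


def threeway_projection_series(volumes, voxel_size):
    return [threeway_projection(v, voxel_size) for v in volumes]


def preprocess_video(frames_a, frames_b, max_shift: int = 5,
                     deconvolver=None):
    """Register channel b onto channel a across a whole video.

    ``deconvolver``, if given, is a callable applied to every frame first —
    the hook for an external deconvolution implementation (deconvolution
    itself is out of scope here).  Returns ``(frames_a, aligned_b, shift)``.
    """
    if deconvolver is not None:
        frames_a = [deconvolver(f) for f in frames_a]
        frames_b = [deconvolver(f) for f in frames_b]
    shift, _ = register_channels(frames_a, frames_b, max_shift)
    aligned = [apply_shift(f, shift) for f in frames_b]
    return frames_a, aligned, shift
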