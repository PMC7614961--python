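"""End-to-end pipelines tying the stages together.

Two pipelines share the package: the image-analysis pipeline
(synthesize/load -> preprocess -> project -> segment -> profile/geometry)
and the model pipeline (contour simulation / phase scan -> base closure).
``run_pipeline`` drives the image pipeline from a config dict and writes
every stage's outputs, with provenance headers, into an artifact directory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import mesh as mm
from . import profiling as prof
from . import projection as proj
from . import segmentation as seg
from . import synth

log = logging.getLogger("cupmap")

DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {
        "cell_radius": 5.0,
        "noise_model": "poisson",
        "noise_scale": 1.0,
        "cups": [{"axis": (0.0, 0.0, 1.0), "opening_angle": 0.7,
                  "lifetime_s": 80.0, "stall_fraction": 0.6}],
    },
    "frame_times": [0.0, 10.0, 20.0, 30.0, 40.0, 50.0],
    "background_tophat_radius": 0,      # voxels; 0 disables (synthetic data
    #                                     has no diffuse background)
    "use_truth_mesh": True,
    "smooth_iterations": 3,
}


def _merged(config: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        out[k] = v
    return out


def analyse_frame(mesh, pip3_vol, actin_vol, voxel_size, markers_row,
                  tophat_radius: int = 0):
    """Project both channels onto the mesh and segment every marker."""
    if tophat_radius:
        pip3_vol = proj.subtract_background(pip3_vol, tophat_radius)
        actin_vol = proj.subtract_background(actin_vol, tophat_radius)
    pip3 = proj.project_fluorescence(mesh, pip3_vol, voxel_size)
    actin = proj.project_actin(mesh, actin_vol, voxel_size,
                               shrink_displacement=0.5)
    curv = mm.vertex_mean_curvature(mesh)
    mesh.scalars.update({"pip3": pip3, "actin": actin, "curvature": curv})
    markers = [seg.Marker(frame=int(r.frame), position=[r.x, r.y, r.z],
                          track=int(r.track), label=str(r.label))
               for r in markers_row.itertuples()]
    return seg.segment_frame(mesh, pip3, curv, markers)


def run_pipeline(config: dict | None, outdir) -> Path:
    """Run synthesize -> project -> segment -> profile -> geometry.

    Every stage writes its outputs under ``outdir``; tables carry a
    provenance header (package version, seed, config hash, stage).  Returns
    the artifact directory.  Reruns with the same config and seed reproduce
    identical tables.
    """
    cfg = _merged(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.save_config(outdir / "config.yaml", cfg)
    seed = int(cfg["seed"])

    log.info("stage synth: rendering %d frames", len(cfg["frame_times"]))
    scene = synth.SyntheticScene(seed=seed, **cfg["scene"])
    frames = synth.make_cell_volume(scene, cfg["frame_times"])
    markers_df = synth.truth_markers(scene, cfg["frame_times"])
    cio.save_table(outdir / "markers.csv", markers_df, seed, cfg, "synth")

    tracked = seg.track_markers(markers_df)
    geo_rows, event_rows = [], []
    profiles_by_track: dict = {}
    for fi, frame in enumerate(frames):
        mesh = frame["mesh"]
        cio.save_volume(outdir / f"pip3_f{fi:03d}.tif", frame["pip3"])
        cio.save_mask(outdir / f"mask_f{fi:03d}.tif", frame["mask"])
        rows = tracked[tracked["frame"] == fi]
        segs = analyse_frame(mesh, frame["pip3"], frame["actin"],
                             scene.voxel_size, rows,
                             cfg["background_tophat_radius"])
        label = np.zeros(mesh.n_vertices)
        for s in segs:
            track = s.marker.track
            if not s.is_false_domain and not s.is_split:
                area, perim, depth = prof.domain_geometry(mesh, s.domain)
                geo_rows.append({"track": track, "frame": fi,
                                 "t": frame["t"], "area": area,
                                 "perimeter": perim, "depth": depth})
                bands = prof.band_partition(mesh, s.domain, depth)
                p = prof.band_profile(bands, mesh.scalars["pip3"])
                profiles_by_track.setdefault(track, []).append(
                    (frame["t"], p))
            label[s.domain.indices] = track
            event_rows.append({"track": track, "frame": fi,
                               "present": not s.is_false_domain,
                               "split": s.is_split,
                               "threshold": s.threshold})
        mesh.scalars["domain"] = label
        mm.save_ply(mesh, outdir / f"surface_f{fi:03d}.ply")

    geometry = pd.DataFrame(geo_rows)
    cio.save_table(outdir / "geometry.csv", geometry, seed, cfg, "geometry")
    cio.save_table(outdir / "events.csv", pd.DataFrame(event_rows), seed,
                   cfg, "segment")

    prof_rows = []
    for track, plist in profiles_by_track.items():
        try:
            normed, bg = prof.normalize_profile([p for _, p in plist])
        except ValueError as e:
            log.warning("track %s not normalisable: %s", track, e)
            continue
        mean_inside = np.nanmean(np.stack([p.inside_mean for p in normed]),
                                 axis=0)
        mean_outside = np.nanmean(np.stack([p.outside_mean for p in normed]),
                                  axis=0)
        for c, v in zip(normed[0].inside_centers, mean_inside):
            prof_rows.append({"track": track, "kind": "inside",
                              "position": c, "mean": v, "background": bg})
        for c, v in zip(normed[0].outside_centers, mean_outside):
            prof_rows.append({"track": track, "kind": "outside",
                              "position": c, "mean": v, "background": bg})
    cio.save_table(outdir / "profiles.csv", pd.DataFrame(prof_rows), seed,
                   cfg, "profile")

    if len(geometry) and geometry.groupby("track").size().max() >= 2:
        _, summary = prof.double_normalize(geometry)
        cio.save_table(outdir / "geometry_normalized.csv", summary, seed,
                       cfg, "geometry")
    log.info("pipeline complete: %s", outdir)
    return outdir
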