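import numpy as np
import pytest

from cupmap import mesh as mm
from cupmap import projection as proj
from cupmap import synth


@pytest.fixture(scope="session")
def unit_icosphere4():
    return mm.icosphere(1.0, 4)


def tube_mesh(radius=1.0, z0=4.0, z1=8.0, n_theta=60, n_z=40,
              center_xy=(4.0, 4.0)):
    """Closed cylinder with a smooth (exactly on-radius) wall tessellation."""
    import trimesh
    cx, cy = center_xy
    th = 2 * np.pi * np.arange(n_theta) / n_theta
    zs = np.linspace(z0, z1, n_z)
    verts = [[cx + radius * np.cos(t), cy + radius * np.sin(t), z]
             for z in zs for t in th]
    faces = []
    for j in range(n_z - 1):
        for i in range(n_theta):
            a = j * n_theta + i
            b = j * n_theta + (i + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces += [[a, b, c], [b, d, c]]
    lo = len(verts)
    verts.append([cx, cy, z0])
    hi = len(verts)
    verts.append([cx, cy, z1])
    for i in range(n_theta):
        faces.append([lo, (i + 1) % n_theta, i])
        base = (n_z - 1) * n_theta
        faces.append([hi, base + i, base + (i + 1) % n_theta])
    tm = trimesh.Trimesh(np.asarray(verts, dtype=float),
                         np.asarray(faces), process=True)
    trimesh.repair.fix_normals(tm)
    if tm.volume < 0:
        tm.invert()
    return mm.from_trimesh(tm)


@pytest.fixture(scope="session")
def cup_scene():
    """One-cup synthetic scene with Poisson noise, rendered at stall."""
    scene = synth.SyntheticScene(cups=[synth.CupSpec()], seed=7,
                                 noise_model="poisson", noise_scale=1.0)
    t = scene.cups[0].stall_time()
    pip3, actin, mask, mesh = synth.render_frame(scene, t)
    return {"scene": scene, "t": t, "pip3": pip3, "actin": actin,
            "mask": mask, "mesh": mesh}


@pytest.fixture(scope="session")
def cup_scene_clean():
    """Same geometry without noise (projection-fidelity oracle)."""
    scene = synth.SyntheticScene(cups=[synth.CupSpec()], seed=7,
                                 noise_model="none")
    t = scene.cups[0].stall_time()
    pip3, actin, mask, mesh = synth.render_frame(scene, t)
    return {"scene": scene, "t": t, "pip3": pip3, "actin": actin,
            "mask": mask, "mesh": mesh}


@pytest.fixture(scope="session")
def projected_cup(cup_scene):
    """Projected PIP3 and curvature on the truth mesh of the noisy scene."""
    mesh = cup_scene["mesh"]
    vals = proj.project_fluorescence(mesh, np.maximum(cup_scene["pip3"], 0),
                                     cup_scene["scene"].voxel_size)
    curv = mm.vertex_mean_curvature(mesh)
    return {**cup_scene, "pip3": vals, "curvature": curv}
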