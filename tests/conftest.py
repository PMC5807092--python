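import numpy as np
import pytest
import trimesh

from viscperc.synth import MeshFrame


@pytest.fixture(scope="session")
def icosphere():
    """Unit icosphere at subdivision 4."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return MeshFrame(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def torus_2_05():
    """Torus with major radius 2 and minor radius 0.5."""
    t = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5,
                               major_sections=96, minor_sections=48)
    return MeshFrame(np.asarray(t.vertices), np.asarray(t.faces))


def open_cylinder(radius: float, height: float, n_theta: int = 96,
                  n_z: int = 24) -> MeshFrame:
    """Open-ended cylinder grid mesh (boundary rings flagged, no caps)."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    verts = np.column_stack([radius * np.cos(tt).ravel(),
                             radius * np.sin(tt).ravel(), zz.ravel()])
    idx = np.arange(n_theta * n_z).reshape(n_theta, n_z)
    a = idx[:, :-1]
    b = np.roll(idx, -1, axis=0)[:, :-1]
    c = np.roll(idx, -1, axis=0)[:, 1:]
    d = idx[:, 1:]
    faces = np.concatenate([
        np.column_stack([a.ravel(), b.ravel(), c.ravel()]),
        np.column_stack([a.ravel(), c.ravel(), d.ravel()]),
    ])
    return MeshFrame(verts, faces)


@pytest.fixture(scope="session")
def cylinder_r2():
    return open_cylinder(2.0, 8.0)


def saddle_patch(n: int = 41, extent: float = 1.0) -> MeshFrame:
    """Triangulated graph of z = x^2 - y^2 around the origin."""
    xs = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), (xx**2 - yy**2).ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return MeshFrame(verts, faces)
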