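import numpy as np
import pytest
import trimesh

from cheekmorph._surface import structured_grid_mesh
from cheekmorph.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Canonical pre-operative phantom shared by read-only tests."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def frame(phantom):
    return phantom.frame


@pytest.fixture(scope="session")
def planes(phantom):
    return phantom.planes


def random_rigid(rng, max_angle_deg=25.0, max_translation=40.0):
    """A random proper rigid transform (R, t)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


def flat_patch(size=10.0, res=0.5, y=50.0, x0=0.0, z0=0.0):
    """Flat anterior-facing square patch at constant y."""
    xs = np.arange(x0, x0 + size + res / 2, res)
    zs = np.arange(z0, z0 + size + res / 2, res)
    Y = np.full((len(xs), len(zs)), float(y))
    return structured_grid_mesh(xs, zs, Y)


def transformed_mesh(mesh, R, t):
    out = mesh.copy()
    out.vertices = mesh.vertices @ np.asarray(R).T + np.asarray(t)
    return out


def brute_force_heights(mesh, xs, zs):
    """Independent height-field oracle: exact ray/triangle intersection of
    every +y ray against every triangle (Moller-Trumbore), outermost hit."""
    tri = mesh.vertices[mesh.faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = b - a, c - a
    d = np.array([0.0, 1.0, 0.0])
    out = np.full((len(xs), len(zs)), np.nan)
    for i, x in enumerate(xs):
        for j, z in enumerate(zs):
            o = np.array([x, -1e4, z])
            p = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, p)
            ok = np.abs(det) > 1e-12
            inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
            s = o - a
            u = np.einsum("ij,ij->i", s, p) * inv
            q = np.cross(s, e1)
            v = (q @ d) * inv
            tpar = np.einsum("ij,ij->i", e2, q) * inv
            hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
            if np.any(hit):
                out[i, j] = (o[1] + tpar[hit]).max()
    return out
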