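import numpy as np
import pytest

from cardiomesh.hermite import HermiteMesh
from cardiomesh.register import rasterize_mesh
from cardiomesh.templates import TemplateSpec, synthesize_biv, synthesize_lv


def make_identity_cube() -> HermiteMesh:
    """Single element whose DOFs encode the identity map on the unit cube."""
    dofs = np.zeros((8, 2, 2, 2, 3))
    for k in range(8):
        corner = np.array([k & 1, (k >> 1) & 1, (k >> 2) & 1], dtype=float)
        dofs[k, 0, 0, 0] = corner
        dofs[k, 1, 0, 0] = [1.0, 0.0, 0.0]
        dofs[k, 0, 1, 0] = [0.0, 1.0, 0.0]
        dofs[k, 0, 0, 1] = [0.0, 0.0, 1.0]
    faces = {"all": np.array([[0, f] for f in range(6)])}
    return HermiteMesh(dofs, np.arange(8).reshape(1, 8), surface_faces=faces)


def make_affine_mesh(A, b) -> HermiteMesh:
    """Single element carrying the affine map x -> A x + b of the unit cube."""
    return make_identity_cube().transform_affine(np.asarray(A, float), np.asarray(b, float))


def sinusoid_field(seed: int, wavelength=None, amplitude=None):
    """Deterministic smooth displacement field (callable on (N, 3) points)."""
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.6, 1.2, size=3) * (amplitude if amplitude else 1.0)
    L = wavelength if wavelength else rng.uniform(12.0, 20.0)
    ph = rng.uniform(0, 2 * np.pi, size=3)

    def f(p):
        p = np.asarray(p, dtype=float)
        u = np.empty_like(p)
        k = 2 * np.pi / L
        for i in range(3):
            j, l = (i + 1) % 3, (i + 2) % 3
            u[..., i] = amp[i] * np.sin(k * (p[..., j] + p[..., l]) + ph[i])
        return u

    return f


def nodal_warp(mesh: HermiteMesh, field) -> HermiteMesh:
    """Reference oracle: warp each node position independently by the field
    (derivative DOFs untouched) — the non-variational technique the L2
    projection must beat in residual."""
    out = mesh.copy()
    pos = out.node_dofs[:, 0, 0, 0, :]
    out.node_dofs[:, 0, 0, 0, :] = pos + field(pos)
    return out


@pytest.fixture(scope="session")
def lv_template() -> HermiteMesh:
    return synthesize_lv(TemplateSpec())


@pytest.fixture(scope="session")
def biv_template() -> HermiteMesh:
    return synthesize_biv(TemplateSpec(topology="BiV", resolution=(2, 9, 8)))


@pytest.fixture(scope="session")
def lv_template_mask(lv_template):
    """LV template rasterized at 1 mm isotropic spacing."""
    lo, hi = lv_template.bounding_box()
    origin = lo - 5.0
    shape = tuple(np.ceil(hi - lo + 10.0).astype(int) + 1)
    return rasterize_mesh(lv_template, (shape, (1.0, 1.0, 1.0), origin))


@pytest.fixture(scope="session")
def identity_cube() -> HermiteMesh:
    return make_identity_cube()
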