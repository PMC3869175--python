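"""Structured tricubic-Hermite ventricular meshes.

Geometry is interpolated per hexahedral element as a tensor product of 1-D
cubic Hermite polynomials.  Every node carries eight degree-of-freedom
vectors per coordinate: the position and the seven partial derivatives with
respect to the element-local coordinates ``(xi1, xi2, xi3)`` (first, mixed
second and the mixed third derivative).  Derivatives are taken with respect
to *unit* local coordinates (unit scale factors); arc-length scaling is not
supported.

Local-coordinate convention: ``xi1`` is circumferential, ``xi2``
longitudinal (apex -> base), ``xi3`` radial/transmural (endo -> epi).
Element node ordering is xi1-fastest: local node ``k = i1 + 2*i2 + 4*i3``
sits at the corner ``(i1, i2, i3)`` of the unit cube.

Collapsed-apex meshes store coincident apex nodes as distinct entries tied
to a common position (see :attr:`HermiteMesh.position_ties`); quadrature
points are always strictly interior so the Jacobian determinant stays
positive and finite on such elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "hermite_basis_1d",
    "hermite_basis_1d_deriv",
    "gauss_1d",
    "HermiteNode",
    "HermiteElement",
    "HermiteMesh",
    "evaluate_element",
    "element_jacobian",
    "mesh_volume",
    "external_surface_points",
    "LagrangeMesh",
    "convert_to_lagrange",
]

# DOF index order within the (2, 2, 2) derivative block: axis j index 0 means
# "value direction", 1 means "differentiate along xi_j".
DOF_NAMES = {
    (0, 0, 0): "position",
    (1, 0, 0): "d_xi1",
    (0, 1, 0): "d_xi2",
    (0, 0, 1): "d_xi3",
    (1, 1, 0): "d_xi1xi2",
    (1, 0, 1): "d_xi1xi3",
    (0, 1, 1): "d_xi2xi3",
    (1, 1, 1): "d_xi1xi2xi3",
}

FACE_AXES = [(1, 2), (1, 2), (0, 2), (0, 2), (0, 1), (0, 1)]  # free axes per face id


def hermite_basis_1d(xi):
    """Cubic Hermite shape functions at ``xi`` in [0, 1].

    Returns the four functions ``(value-at-0, value-at-1, derivative-at-0,
    derivative-at-1)``; the two value functions sum to one.  Accepts scalars
    or arrays (last axis of the result has length 4).
    """
    x = np.asarray(xi, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("xi outside [0, 1]")
    x2 = x * x
    x3 = x2 * x
    return np.stack(
        [1 - 3 * x2 + 2 * x3, 3 * x2 - 2 * x3, x * (x - 1) ** 2, x2 * (x - 1)],
        axis=-1,
    )


def hermite_basis_1d_deriv(xi):
    """First derivatives of :func:`hermite_basis_1d` with respect to xi."""
    x = np.asarray(xi, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("xi outside [0, 1]")
    x2 = x * x
    return np.stack(
        [
            -6 * x + 6 * x2,
            6 * x - 6 * x2,
            3 * x2 - 4 * x + 1,
            3 * x2 - 2 * x,
        ],
        axis=-1,
    )


def _phi_matrix(xi, deriv: bool = False) -> np.ndarray:
    """Basis values arranged as ``[..., d, a]`` with d = derivative flag of
    the DOF, a = corner index (0/1).

    No domain check: internal callers (e.g. Newton inversion during
    rasterization) evaluate the polynomial extension slightly outside
    [0, 1].
    """
    x = np.asarray(xi, dtype=float)
    x2 = x * x
    x3 = x2 * x
    if deriv:
        b = np.stack(
            [-6 * x + 6 * x2, 6 * x - 6 * x2, 3 * x2 - 4 * x + 1, 3 * x2 - 2 * x],
            axis=-1,
        )
    else:
        b = np.stack(
            [1 - 3 * x2 + 2 * x3, 3 * x2 - 2 * x3, x * (x - 1) ** 2, x2 * (x - 1)],
            axis=-1,
        )
    out = np.empty(b.shape[:-1] + (2, 2))
    out[..., 0, 0] = b[..., 0]
    out[..., 0, 1] = b[..., 1]
    out[..., 1, 0] = b[..., 2]
    out[..., 1, 1] = b[..., 3]
    return out


def gauss_1d(order: int) -> Tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre points/weights on the open interval (0, 1)."""
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    p, w = np.polynomial.legendre.leggauss(order)
    return 0.5 * (p + 1.0), 0.5 * w


def gauss_3d(order: int) -> Tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss points (n^3, 3) and weights (n^3,) on (0,1)^3."""
    p, w = gauss_1d(order)
    P = np.stack(np.meshgrid(p, p, p, indexing="ij"), axis=-1).reshape(-1, 3)
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).reshape(-1)
    return P, W


@dataclass
class HermiteNode:
    """Read/write view of one node's eight DOF vectors (mm, mm/unit-xi)."""

    dofs: np.ndarray  # shape (2, 2, 2, 3); dofs[d1, d2, d3] is a 3-vector

    @property
    def position(self) -> np.ndarray:
        return self.dofs[0, 0, 0]

    @property
    def d_xi1(self) -> np.ndarray:
        return self.dofs[1, 0, 0]

    @property
    def d_xi2(self) -> np.ndarray:
        return self.dofs[0, 1, 0]

    @property
    def d_xi3(self) -> np.ndarray:
        return self.dofs[0, 0, 1]

    @property
    def d_xi1xi2(self) -> np.ndarray:
        return self.dofs[1, 1, 0]

    @property
    def d_xi1xi3(self) -> np.ndarray:
        return self.dofs[1, 0, 1]

    @property
    def d_xi2xi3(self) -> np.ndarray:
        return self.dofs[0, 1, 1]

    @property
    def d_xi1xi2xi3(self) -> np.ndarray:
        return self.dofs[1, 1, 1]


@dataclass
class HermiteElement:
    """Eight node references in xi1-fastest tensor-product order."""

    node_ids: np.ndarray  # (8,) int
    material_labels: Dict[str, str] = field(
        default_factory=lambda: {
            "xi1": "circumferential",
            "xi2": "longitudinal",
            "xi3": "radial",
        }
    )


class HermiteMesh:
    """Structured tricubic-Hermite hexahedral mesh.

    Parameters
    ----------
    node_dofs:
        Array ``(n_nodes, 2, 2, 2, 3)`` of nodal DOFs.
    elements:
        Integer array ``(n_elements, 8)`` of node ids, xi1-fastest order.
    topology:
        ``"LV"`` or ``"BiV"`` (or ``None`` for ad-hoc meshes, e.g. tests).
    resolution:
        ``(n_radial, n_circumferential, n_longitudinal)`` element counts of
        the LV wall region.
    surface_faces:
        Mapping from face-set label (``endo_LV``, ``endo_RV``, ``epi``,
        ``base``) to an integer array ``(n, 2)`` of ``(element, face_id)``
        pairs, ``face_id = 2*axis + side``.
    regions:
        Mapping region label -> node-id grid, shape
        ``(n_circ_nodes, n_long_nodes, n_rad_nodes)`` (circumferential axis
        periodic for the LV wall).
    position_ties:
        Groups of node ids constrained to share one position (collapsed
        apex rings, RV insertion lines).
    """

    def __init__(
        self,
        node_dofs: np.ndarray,
        elements: np.ndarray,
        topology: Optional[str] = None,
        resolution: Optional[Tuple[int, int, int]] = None,
        apex_style: str = "collapsed",
        surface_faces: Optional[Dict[str, np.ndarray]] = None,
        regions: Optional[Dict[str, np.ndarray]] = None,
        position_ties: Optional[List[np.ndarray]] = None,
        solid_faces: Optional[Dict[str, np.ndarray]] = None,
    ):
        self.node_dofs = np.asarray(node_dofs, dtype=float)
        if self.node_dofs.ndim != 5 or self.node_dofs.shape[1:] != (2, 2, 2, 3):
            raise ValueError("node_dofs must have shape (n, 2, 2, 2, 3)")
        if not np.all(np.isfinite(self.node_dofs)):
            raise ValueError("non-finite DOF values")
        self.elements = np.asarray(elements, dtype=int).reshape(-1, 8)
        self.topology = topology
        self.resolution = tuple(resolution) if resolution is not None else None
        self.apex_style = apex_style
        self.surface_faces = {
            k: np.asarray(v, dtype=int).reshape(-1, 2)
            for k, v in (surface_faces or {}).items()
        }
        self.regions = {k: np.asarray(v, dtype=int) for k, v in (regions or {}).items()}
        self.position_ties = [np.asarray(g, dtype=int) for g in (position_ties or [])]
        # closed boundary face lists per solid wall region (rasterization);
        # defaults to the union of all labelled surface faces as one solid
        self.solid_faces = {
            k: np.asarray(v, dtype=int).reshape(-1, 2)
            for k, v in (solid_faces or {}).items()
        }

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_dofs.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def node(self, i: int) -> HermiteNode:
        return HermiteNode(self.node_dofs[i])

    def element(self, e: int) -> HermiteElement:
        return HermiteElement(self.elements[e].copy())

    def copy(self) -> "HermiteMesh":
        return HermiteMesh(
            self.node_dofs.copy(),
            self.elements.copy(),
            topology=self.topology,
            resolution=self.resolution,
            apex_style=self.apex_style,
            surface_faces={k: v.copy() for k, v in self.surface_faces.items()},
            regions={k: v.copy() for k, v in self.regions.items()},
            position_ties=[g.copy() for g in self.position_ties],
            solid_faces={k: v.copy() for k, v in self.solid_faces.items()},
        )

    def element_dof_tensor(self, element_ids=None) -> np.ndarray:
        """DOFs gathered per element, arranged ``(E, a1, a2, a3, d1, d2, d3, 3)``."""
        if element_ids is None:
            conn = self.elements
        else:
            conn = self.elements[np.atleast_1d(element_ids)]
        D = self.node_dofs[conn]  # (E, 8, 2, 2, 2, 3)
        E = D.shape[0]
        # local node index k = a1 + 2*a2 + 4*a3 -> row-major reshape yields
        # (a3, a2, a1); transpose into (a1, a2, a3).
        return D.reshape(E, 2, 2, 2, 2, 2, 2, 3).transpose(0, 3, 2, 1, 4, 5, 6, 7)

    def transform_affine(self, A: np.ndarray, b: np.ndarray) -> "HermiteMesh":
        """Return a new mesh with every DOF mapped through ``x -> A x + b``.

        Positions gain the translation; all derivative DOFs transform
        linearly (exact for an affine map).
        """
        A = np.asarray(A, dtype=float).reshape(3, 3)
        b = np.asarray(b, dtype=float).reshape(3)
        out = self.copy()
        out.node_dofs = np.einsum("ij,ndefj->ndefi", A, self.node_dofs)
        out.node_dofs[:, 0, 0, 0, :] += b
        return out

    def bounding_box(self) -> Tuple[np.ndarray, np.ndarray]:
        p = self.node_dofs[:, 0, 0, 0, :]
        return p.min(axis=0), p.max(axis=0)


# ----------------------------------------------------------------------
# evaluation


def _check_element(mesh: HermiteMesh, element_id: int) -> None:
    if not (0 <= element_id < mesh.n_elements):
        raise IndexError(f"invalid element id {element_id}")


def _eval_tensor(Dg: np.ndarray, xi: np.ndarray, deriv_axis: Optional[int] = None) -> np.ndarray:
    """Evaluate one element's interpolant (or a first partial) at points.

    ``Dg`` has shape ``(a1, a2, a3, d1, d2, d3, 3)``; ``xi`` is ``(N, 3)``.
    """
    F = [
        _phi_matrix(xi[:, j], deriv=(deriv_axis == j))
        for j in range(3)
    ]
    return np.einsum("nda,neb,nfc,abcdefk->nk", F[0], F[1], F[2], Dg, optimize=True)


def evaluate_element(mesh: HermiteMesh, element_id: int, xi) -> np.ndarray:
    """Tensor-product Hermite interpolant of element ``element_id`` at ``xi``.

    ``xi`` may be a single 3-vector or an ``(N, 3)`` array in the unit cube;
    returns a matching ``(3,)`` or ``(N, 3)`` array of world positions (mm).
    """
    _check_element(mesh, element_id)
    pts = np.atleast_2d(np.asarray(xi, dtype=float))
    Dg = mesh.element_dof_tensor([element_id])[0]
    out = _eval_tensor(Dg, pts)
    return out[0] if np.asarray(xi).ndim == 1 else out


def element_jacobian(mesh: HermiteMesh, element_id: int, xi):
    """Analytic Jacobian ``J = dx/dxi`` (3x3) and ``det J`` at ``xi``.

    Columns of J are the partial derivatives along xi1, xi2, xi3.  For an
    ``(N, 3)`` batch of points returns ``(N, 3, 3)`` and ``(N,)``.
    """
    _check_element(mesh, element_id)
    single = np.asarray(xi).ndim == 1
    pts = np.atleast_2d(np.asarray(xi, dtype=float))
    Dg = mesh.element_dof_tensor([element_id])[0]
    cols = [_eval_tensor(Dg, pts, deriv_axis=j) for j in range(3)]
    J = np.stack(cols, axis=-1)  # (N, 3, 3), column j = d/dxi_j
    detJ = np.linalg.det(J)
    if single:
        return J[0], detJ[0]
    return J, detJ


def all_jacobian_dets(mesh: HermiteMesh, quad_order: int = 4) -> Tuple[np.ndarray, np.ndarray]:
    """``det J`` at interior Gauss points for every element.

    Returns ``(dets (E, n_q), weights (n_q,))``; the workhorse behind
    volume and quality computations.
    """
    P, W = gauss_3d(quad_order)
    Dg = mesh.element_dof_tensor()  # (E, ...)
    F = [_phi_matrix(P[:, j]) for j in range(3)]
    dF = [_phi_matrix(P[:, j], deriv=True) for j in range(3)]
    cols = []
    for j in range(3):
        B = [dF[k] if k == j else F[k] for k in range(3)]
        cols.append(
            np.einsum("nda,neb,nfc,Eabcdefk->Enk", B[0], B[1], B[2], Dg, optimize=True)
        )
    J = np.stack(cols, axis=-1)  # (E, n_q, 3, 3)
    return np.linalg.det(J), W


def mesh_volume(mesh: HermiteMesh, quad_order: int = 4) -> float:
    """Mesh volume (mm^3) by tensor-product Gauss quadrature of det J."""
    dets, W = all_jacobian_dets(mesh, quad_order)
    return float(np.sum(dets @ W))


# ----------------------------------------------------------------------
# surfaces


def _face_xi(face_id: int, uv: np.ndarray) -> np.ndarray:
    """Embed (N, 2) face parameters into (N, 3) element coordinates."""
    axis, side = divmod(face_id, 2)
    xi = np.empty((uv.shape[0], 3))
    free = FACE_AXES[face_id]
    xi[:, axis] = float(side)
    xi[:, free[0]] = uv[:, 0]
    xi[:, free[1]] = uv[:, 1]
    return xi


def face_surface_eval(mesh: HermiteMesh, element_id: int, face_id: int, uv: np.ndarray):
    """Positions and (unnormalized) outward-area vectors on a face patch."""
    uv = np.atleast_2d(uv)
    xi = _face_xi(face_id, uv)
    Dg = mesh.element_dof_tensor([element_id])[0]
    pos = _eval_tensor(Dg, xi)
    free = FACE_AXES[face_id]
    tu = _eval_tensor(Dg, xi, deriv_axis=free[0])
    tv = _eval_tensor(Dg, xi, deriv_axis=free[1])
    return pos, np.cross(tu, tv)


def external_surface_points(
    mesh: HermiteMesh,
    face_set: Iterable[str] | str,
    quad_order: int = 4,
):
    """Gauss points and area weights on the selected labelled surface faces.

    Returns ``(points (N, 3), weights (N,))`` where each weight is the Gauss
    weight times the local surface area element, so ``weights.sum()``
    approximates the area of the selected patches.
    """
    if isinstance(face_set, str):
        face_set = [face_set]
    faces: List[np.ndarray] = []
    for name in face_set:
        if name not in mesh.surface_faces:
            raise KeyError(f"unknown face set {name!r}")
        faces.append(mesh.surface_faces[name])
    if not faces or sum(len(f) for f in faces) == 0:
        raise ValueError("empty face set")
    fl = np.concatenate(faces, axis=0)
    p1, w1 = gauss_1d(quad_order)
    UV = np.stack(np.meshgrid(p1, p1, indexing="ij"), axis=-1).reshape(-1, 2)
    WW = (w1[:, None] * w1[None, :]).reshape(-1)
    pts, wts = [], []
    for elem, fid in fl:
        pos, area_vec = face_surface_eval(mesh, int(elem), int(fid), UV)
        pts.append(pos)
        wts.append(WW * np.linalg.norm(area_vec, axis=1))
    return np.concatenate(pts, axis=0), np.concatenate(wts, axis=0)


# ----------------------------------------------------------------------
# Lagrange conversion


@dataclass
class LagrangeMesh:
    """Cubic-Lagrange mesh: positions only, 4x4x4 nodes per element."""

    points: np.ndarray  # (n_points, 3)
    cells: np.ndarray  # (n_elements, 4, 4, 4) point ids, index order (i1, i2, i3)
    degree: int = 3


def convert_to_lagrange(mesh: HermiteMesh, tol: float = 1e-6) -> LagrangeMesh:
    """Sample the Hermite geometry at the 4^3 lattice xi in {0, 1/3, 2/3, 1}^3.

    Lattice points shared between elements (coincident within ``tol`` mm)
    are merged into a single Lagrange node.
    """
    t = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    lattice = np.stack(np.meshgrid(t, t, t, indexing="ij"), axis=-1).reshape(-1, 3)
    points: List[np.ndarray] = []
    index: Dict[Tuple[int, int, int], int] = {}
    cells = np.empty((mesh.n_elements, 64), dtype=int)
    for e in range(mesh.n_elements):
        pos = evaluate_element(mesh, e, lattice)
        for k, p in enumerate(pos):
            key = tuple(np.round(p / tol).astype(np.int64))
            idx = index.get(key)
            if idx is None:
                idx = len(points)
                index[key] = idx
                points.append(p)
            cells[e, k] = idx
    return LagrangeMesh(np.asarray(points), cells.reshape(-1, 4, 4, 4))
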