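"""Variational mesh warping: L2 projection of a displacement field onto
the Hermite degrees of freedom.

The whole continuum represented by the mesh is deformed at once: the DOF
increments minimize the L2 norm of the projection error over the mesh
volume (Gauss quadrature, weighted by the volume differential), rather
than warping each nodal DOF independently.  The resulting normal equations
share one sparse symmetric matrix for the three coordinates.

Collapsed-apex position ties are honoured: tied value DOFs are reduced to
a single unknown, so coincident apex nodes stay coincident after warping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .hermite import HermiteMesh, _phi_matrix, gauss_3d
from .register import DisplacementField

__all__ = ["ProjectionProblem", "project_displacement", "l2_residual"]

FieldLike = Union[DisplacementField, Callable[[np.ndarray], np.ndarray]]


@dataclass
class ProjectionProblem:
    mesh: HermiteMesh
    field: FieldLike
    quad_order: int = 4
    # trace-scaled Tikhonov weight: regularizes DOFs with little quadrature
    # support (apex mixed derivatives) without visibly biasing the geometry
    regularization_eps: float = 1e-12

    def __post_init__(self):
        if self.quad_order < 3:
            raise ValueError("quad_order must be >= 3 for cubic integrands")


def _sample_field(field: FieldLike, points: np.ndarray) -> np.ndarray:
    u = field.sample(points) if isinstance(field, DisplacementField) else field(points)
    u = np.asarray(u, dtype=float)
    if u.shape != points.shape:
        raise ValueError("field sample shape mismatch")
    if not np.all(np.isfinite(u)):
        raise ValueError("field undefined (non-finite) at a quadrature point")
    return u


def _dof_columns(mesh: HermiteMesh):
    """Global DOF -> solver column map, merging tied value DOFs.

    Raw DOF index = ``node * 8 + (d1 * 4 + d2 * 2 + d3)``.  Value DOFs
    (d = 0) of nodes in a position-tie group share one column.
    """
    n_raw = mesh.n_nodes * 8
    col = np.arange(n_raw)
    for group in mesh.position_ties:
        master = int(group[0]) * 8
        for nid in group[1:]:
            col[int(nid) * 8] = master
    # compress to consecutive ids
    uniq, inv = np.unique(col, return_inverse=True)
    return inv, len(uniq)


def _basis_rows(mesh: HermiteMesh, quad_order: int):
    """Quadrature geometry + sparse basis matrix for the whole mesh.

    Returns ``(B, wdet, points)``: ``B`` is (n_q_total, n_columns) with the
    64 tensor-basis values per quadrature point, ``wdet`` the quadrature
    weights times det J, ``points`` the world positions.
    """
    P, W = gauss_3d(quad_order)
    nq = len(P)
    F = [_phi_matrix(P[:, j]) for j in range(3)]
    dF = [_phi_matrix(P[:, j], deriv=True) for j in range(3)]
    # basis value of (corner a1 a2 a3, dof d1 d2 d3) at each point
    basis = np.einsum("nda,neb,nfc->nabcdef", F[0], F[1], F[2]).reshape(nq, 64)
    Dg = mesh.element_dof_tensor()
    x = np.einsum("nda,neb,nfc,Eabcdefk->Enk", F[0], F[1], F[2], Dg, optimize=True)
    cols = []
    for j in range(3):
        Bj = [dF[k] if k == j else F[k] for k in range(3)]
        cols.append(
            np.einsum("nda,neb,nfc,Eabcdefk->Enk", Bj[0], Bj[1], Bj[2], Dg, optimize=True)
        )
    J = np.stack(cols, axis=-1)
    detJ = np.linalg.det(J)  # (E, nq)

    col_map, n_cols = _dof_columns(mesh)
    E = mesh.n_elements
    # raw DOF ids per element: (E, 64) in (a1,a2,a3,d1,d2,d3) flat order
    # local node index k = a1 + 2 a2 + 4 a3
    a1, a2, a3, d1, d2, d3 = np.meshgrid(
        *(np.arange(2),) * 6, indexing="ij"
    )
    local_node = (a1 + 2 * a2 + 4 * a3).reshape(64)
    local_dof = (d1 * 4 + d2 * 2 + d3).reshape(64)
    node_ids = mesh.elements[:, local_node]  # (E, 64)
    raw = node_ids * 8 + local_dof[None, :]
    cols_e = col_map[raw]  # (E, 64)

    rows = np.repeat(np.arange(E * nq), 64)
    col_idx = np.repeat(cols_e[:, None, :], nq, axis=1).reshape(-1)
    vals = np.tile(basis, (E, 1)).reshape(-1)
    B = sparse.csr_matrix((vals, (rows, col_idx)), shape=(E * nq, n_cols))
    return B, (W[None, :] * detJ).reshape(-1), x.reshape(-1, 3), col_map


def project_displacement(problem: ProjectionProblem) -> HermiteMesh:
    """Warp the mesh by the L2-optimal DOF increment for the given field.

    Solves ``min_delta  sum_g w_g |B delta - u(x_g)|^2 + eps ||delta||^2``
    per coordinate (one sparse symmetric factorization, three solves) and
    returns a new mesh with ``dofs + delta``.
    """
    mesh = problem.mesh
    B, wdet, points, col_map = _basis_rows(mesh, problem.quad_order)
    if np.any(wdet < 0):
        raise ValueError("negative Jacobian at quadrature points; invalid mesh")
    u = _sample_field(problem.field, points)
    Wm = sparse.diags(wdet)
    N = (B.T @ Wm @ B).tocsc()
    scale = problem.regularization_eps * (N.diagonal().mean() + 1e-300)
    N = N + scale * sparse.identity(N.shape[0], format="csc")
    try:
        lu = splu(N)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise np.linalg.LinAlgError(
            f"singular projection system ({err}); check for unsupported DOFs"
        )
    rhs = B.T @ (wdet[:, None] * u)
    delta_cols = np.stack([lu.solve(rhs[:, c]) for c in range(3)], axis=-1)

    out = mesh.copy()
    delta_raw = delta_cols[col_map]  # (n_nodes * 8, 3)
    out.node_dofs += delta_raw.reshape(mesh.n_nodes, 2, 2, 2, 3)
    return out


def l2_residual(
    mesh_before: HermiteMesh,
    mesh_after: HermiteMesh,
    field: FieldLike,
    quad_order: int = 4,
) -> float:
    """RMS (mm) over Gauss points of |projected displacement - field|.

    The projected displacement is the geometry difference of the two
    meshes evaluated at the quadrature points of ``mesh_before``.
    """
    P, _ = gauss_3d(quad_order)
    F = [_phi_matrix(P[:, j]) for j in range(3)]
    Dg_b = mesh_before.element_dof_tensor()
    Dg_a = mesh_after.element_dof_tensor()
    xb = np.einsum("nda,neb,nfc,Eabcdefk->Enk", F[0], F[1], F[2], Dg_b, optimize=True)
    xa = np.einsum("nda,neb,nfc,Eabcdefk->Enk", F[0], F[1], F[2], Dg_a, optimize=True)
    pts = xb.reshape(-1, 3)
    u = _sample_field(field, pts)
    diff = (xa - xb).reshape(-1, 3) - u
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
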