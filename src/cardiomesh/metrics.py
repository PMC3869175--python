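"""Mesh quality, fitting accuracy, success criterion and the transmural
linearization step.

Quality of an element is the Jacobian ratio: min/max of det J over the
element's interior quadrature points (homogeneity of the volume
differential).  Collapsed-apex elements are included in the aggregates;
because Gauss points are strictly interior their ratio is finite but small,
which is why whole-mesh quality values sit well below typical hexahedral
standards.

Fitting error is the Euclidean distance (mm) from the nodes of the 0.5
isosurface of the binary mask to the closest point of the mesh's external
surface.  Both the plain isosurface-vertex mean and a mesh-surface
Gauss-quadrature-weighted mean are reported; the vertex mean is the
headline number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .hermite import (
    FACE_AXES,
    HermiteMesh,
    all_jacobian_dets,
    external_surface_points,
    face_surface_eval,
)
from .shape import BinaryMask

__all__ = [
    "QualityReport",
    "jacobian_ratio",
    "mesh_quality",
    "fitting_error",
    "success",
    "linearize_transmural",
    "QUALITY_THRESHOLD",
]

QUALITY_THRESHOLD = 0.33  # empirical simulation-stability threshold


@dataclass
class QualityReport:
    per_element_q: List[float]
    mesh_quality_min: float
    mesh_quality_mean: float
    fitting_error_mean: float
    fitting_error_max: float
    fitting_error_weighted: float
    per_isosurface_node_error: Optional[np.ndarray] = None
    success: Optional[bool] = None
    quality_threshold: float = QUALITY_THRESHOLD
    error_threshold: Optional[float] = None
    inverted_elements: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "mesh_quality_min": self.mesh_quality_min,
            "mesh_quality_mean": self.mesh_quality_mean,
            "fitting_error_mean": self.fitting_error_mean,
            "fitting_error_max": self.fitting_error_max,
            "fitting_error_weighted": self.fitting_error_weighted,
            "success": self.success,
            "quality_threshold": self.quality_threshold,
            "error_threshold": self.error_threshold,
            "per_element_q": list(map(float, self.per_element_q)),
            "inverted_elements": list(map(int, self.inverted_elements)),
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ----------------------------------------------------------------------
# quality


def jacobian_ratio(mesh: HermiteMesh, element_id: int, quad_order: int = 4) -> float:
    """Per-element quality ``Q = min_i det J_i / max_i det J_i`` in (0, 1].

    Quadrature points are strictly interior Gauss points, so collapsed
    faces give a small but finite ratio.  A non-positive determinant
    anywhere yields quality 0 (inverted element).
    """
    from .hermite import element_jacobian, gauss_3d

    P, _ = gauss_3d(quad_order)
    _, dets = element_jacobian(mesh, element_id, P)
    if np.min(dets) <= 0:
        return 0.0
    return float(np.min(dets) / np.max(dets))


def element_qualities(mesh: HermiteMesh, quad_order: int = 4):
    dets, _ = all_jacobian_dets(mesh, quad_order)
    mn = dets.min(axis=1)
    mx = dets.max(axis=1)
    q = np.where(mn > 0, mn / np.maximum(mx, 1e-300), 0.0)
    inverted = np.flatnonzero(mn <= 0)
    return q, inverted


def mesh_quality(mesh: HermiteMesh, quad_order: int = 4) -> Tuple[float, float]:
    """(min, mean) Jacobian ratio over all elements (apex included)."""
    q, _ = element_qualities(mesh, quad_order)
    return float(q.min()), float(q.mean())


# ----------------------------------------------------------------------
# fitting error


def _closest_point_distances(
    mesh: HermiteMesh,
    points: np.ndarray,
    seed_subdiv: int = 6,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> np.ndarray:
    """Distance from each point to the mesh external surface.

    Seeds come from the nearest vertex of a subdivided surface cloud, then
    a clamped Gauss-Newton refinement in the face parameters polishes the
    closest point; on non-convergence the seed distance is kept.
    """
    faces = np.concatenate(list(mesh.surface_faces.values()), axis=0)
    t = np.linspace(0.0, 1.0, seed_subdiv + 1)
    UV = np.stack(np.meshgrid(t, t, indexing="ij"), axis=-1).reshape(-1, 2)
    seed_pos = []
    for elem, fid in faces:
        pos, _ = face_surface_eval(mesh, int(elem), int(fid), UV)
        seed_pos.append(pos)
    seed_pos = np.stack(seed_pos)  # (F, S, 3)
    nf, ns = seed_pos.shape[:2]
    tree = cKDTree(seed_pos.reshape(-1, 3))
    k = min(3, nf * ns)
    d_seed, idx = tree.query(points, k=k)
    d_seed = np.atleast_2d(d_seed.T).T
    idx = np.atleast_2d(idx.T).T

    from .hermite import _phi_matrix, _face_xi

    Dg_all = mesh.element_dof_tensor()

    def eval_batch(D, xi, deriv_axis=None):
        # per-point DOF tensors D (M, a1 a2 a3 d1 d2 d3, 3)
        F = [_phi_matrix(xi[:, j], deriv=(deriv_axis == j)) for j in range(3)]
        return np.einsum(
            "nda,neb,nfc,nabcdefk->nk", F[0], F[1], F[2], D, optimize=True
        )

    best = d_seed[:, 0].copy()
    for start in range(k):
        f_idx = idx[:, start] // ns
        uv0 = UV[idx[:, start] % ns]
        elem_ids = faces[f_idx, 0]
        fids = faces[f_idx, 1]
        # group by face id (fixed local axis), vectorize over all points
        for fid in np.unique(fids):
            sel = np.flatnonzero(fids == fid)
            D = Dg_all[elem_ids[sel]]
            free = FACE_AXES[int(fid)]
            p = points[sel]
            x = uv0[sel].copy()
            active = np.arange(len(sel))
            for _ in range(max_iter):
                xi = _face_xi(int(fid), x[active])
                Da = D[active]
                pos = eval_batch(Da, xi)
                tu = eval_batch(Da, xi, deriv_axis=free[0])
                tv = eval_batch(Da, xi, deriv_axis=free[1])
                r = pos - p[active]
                g1 = np.sum(tu * r, axis=1)
                g2 = np.sum(tv * r, axis=1)
                a = np.sum(tu * tu, axis=1)
                b = np.sum(tu * tv, axis=1)
                c = np.sum(tv * tv, axis=1)
                det = a * c - b * b + 1e-30
                du = (c * g1 - b * g2) / det
                dv = (a * g2 - b * g1) / det
                x_new = np.clip(
                    x[active] - np.stack([du, dv], axis=1), 0.0, 1.0
                )
                moved = np.max(np.abs(x_new - x[active]), axis=1) >= tol
                x[active] = x_new
                active = active[moved]
                if len(active) == 0:
                    break
            xi = _face_xi(int(fid), x)
            pos = eval_batch(D, xi)
            d = np.linalg.norm(pos - p, axis=1)
            best[sel] = np.minimum(best[sel], d)
    return best


def fitting_error(
    mesh: HermiteMesh,
    mask: BinaryMask,
    quad_order: int = 4,
    seed_subdiv: int = 6,
):
    """Isosurface-to-mesh distance statistics (mm).

    Returns ``(mean, max, weighted_mean, per_vertex)`` where ``weighted``
    integrates the error over the mesh surface with Gaussian quadrature
    (distance from each surface Gauss point to the nearest isosurface
    vertex).
    """
    verts, _, _, _ = marching_cubes(
        mask.voxels.astype(np.float32), level=0.5, spacing=tuple(mask.spacing)
    )
    if len(verts) == 0:
        raise ValueError("marching cubes produced no isosurface")
    verts = verts + mask.origin
    d = _closest_point_distances(mesh, verts, seed_subdiv=seed_subdiv)

    pts, wts = external_surface_points(mesh, list(mesh.surface_faces.keys()), quad_order)
    tree = cKDTree(verts)
    dq, _ = tree.query(pts)
    weighted = float(np.sum(dq * wts) / np.sum(wts))
    return float(d.mean()), float(d.max()), weighted, d


# ----------------------------------------------------------------------
# success


def success(report: QualityReport, mask: BinaryMask) -> bool:
    """Success criterion: mean error < voxel diagonal AND quality >= 0.33.

    Boundary behaviour is strict: an error exactly equal to the voxel
    diagonal fails.  Quality is the mean element Jacobian ratio (the
    conservative per-mesh minimum is also reported but is dominated by the
    collapsed apex and would reject every collapsed-apex mesh).
    """
    thr = mask.voxel_diagonal
    report.error_threshold = thr
    ok = (report.fitting_error_mean < thr) and (
        report.mesh_quality_mean >= report.quality_threshold
    )
    report.success = bool(ok)
    return report.success


def build_report(
    mesh: HermiteMesh,
    mask: BinaryMask,
    quad_order: int = 4,
    seed_subdiv: int = 6,
) -> QualityReport:
    """Full quality + accuracy report with the success flag set."""
    q, inverted = element_qualities(mesh, quad_order)
    err_mean, err_max, err_w, per_vertex = fitting_error(
        mesh, mask, quad_order, seed_subdiv
    )
    report = QualityReport(
        per_element_q=list(map(float, q)),
        mesh_quality_min=float(q.min()),
        mesh_quality_mean=float(q.mean()),
        fitting_error_mean=err_mean,
        fitting_error_max=err_max,
        fitting_error_weighted=err_w,
        per_isosurface_node_error=per_vertex,
        inverted_elements=list(inverted),
    )
    success(report, mask)
    return report


# ----------------------------------------------------------------------
# transmural linearization


def linearize_transmural(mesh: HermiteMesh) -> HermiteMesh:
    """Straighten material lines across the wall without moving the walls.

    For every transmural node column the radial (xi3) derivative DOFs are
    replaced by the straight chord between the opposite wall-surface
    nodes (scaled by the per-element span), interior nodes are placed on
    the chord, and the xi3-mixed derivatives become chord differences of
    the corresponding in-surface derivatives.  DOFs not involving xi3 are
    untouched, so the endo- and epicardial surfaces are unchanged.
    """
    if not mesh.regions:
        raise ValueError("mesh has no structured regions; cannot pair wall nodes")
    out = mesh.copy()
    for grid in mesh.regions.values():
        nc, nl, nrad1 = grid.shape
        nr = nrad1 - 1
        if nr < 1:
            continue
        cols = grid.reshape(-1, nrad1)
        endo = out.node_dofs[cols[:, 0]]
        epi = out.node_dofs[cols[:, -1]]
        chord = (epi[:, 0, 0, 0, :] - endo[:, 0, 0, 0, :]) / nr
        for k in range(nrad1):
            ids = cols[:, k]
            frac = k / nr
            if 0 < k < nr:
                out.node_dofs[ids, 0, 0, 0, :] = (
                    endo[:, 0, 0, 0, :] + frac * nr * chord
                )
            out.node_dofs[ids, 0, 0, 1, :] = chord
            for d1, d2 in ((1, 0), (0, 1), (1, 1)):
                out.node_dofs[ids, d1, d2, 1, :] = (
                    epi[:, d1, d2, 0, :] - endo[:, d1, d2, 0, :]
                ) / nr
    return out
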