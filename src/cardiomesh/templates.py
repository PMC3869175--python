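"""Idealized truncated-ellipsoid ventricular template meshes.

The LV wall is the shell between two truncated ellipsoids sharing axes and
centre (inner semi-axes = outer minus wall thickness), truncated by a flat
basal plane ``z = z_base`` (the template base is the xi2 = 1 surface).  The
apex is collapsed by default.  The BiV template adds an RV free wall as a
smooth bulge of the LV epicardium spanning a few circumferential sectors,
attached along a squared insertion line (two meridians plus one parallel);
the insertion nodes lie exactly on the LV epicardial surface.  The squared
insertion is anatomically incorrect near the RV apex (the true insertion
line is closer to an ellipse) but keeps the mesh structured.

Template frame: long axis = +z (base up), apex at z = -c_outer, the RV
bulge centred near the +x direction.  All meshes are centred so that shape
analysis of a rasterized template recovers the canonical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .hermite import HermiteMesh

__all__ = [
    "TemplateSpec",
    "synthesize",
    "synthesize_lv",
    "synthesize_biv",
    "tailor_template",
    "lv_shell_volume",
    "truncated_ellipsoid_volume",
]


@dataclass
class TemplateSpec:
    topology: str = "LV"  # "LV" | "BiV"
    resolution: Tuple[int, int, int] = (1, 12, 6)  # (n_radial, n_circ, n_long)
    apex_style: str = "collapsed"  # "collapsed" | "hole" | "patch"
    lv_outer_radii: Tuple[float, float, float] = (35.0, 35.0, 50.0)
    lv_wall_thickness: float = 10.0
    rv_size: Tuple[float, float, float] = (25.0, 35.0, 40.0)
    rv_insertion_level: float = 0.6  # RV length as fraction of LV long extent
    rv_wall_thickness: float = 5.0
    truncate_base: bool = True
    basal_offset: float = 5.0
    base_level: float = 0.5  # z_base as a fraction of the inner long semi-axis
    hole_level: float = 0.12  # apical-hole start (fraction of the apex-base span)
    # quadratic longitudinal grading: negative values enlarge the apical
    # elements, homogenizing det J near the apex (raises the min element
    # quality of the ideal template)
    long_grading: float = -0.4

    def validate(self) -> None:
        if self.topology not in ("LV", "BiV"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.apex_style not in ("collapsed", "hole", "patch"):
            raise ValueError(f"unknown apex style {self.apex_style!r}")
        radii = np.asarray(self.lv_outer_radii, dtype=float)
        if np.any(radii <= 0):
            raise ValueError("lv_outer_radii must be positive")
        if not (0 < self.lv_wall_thickness < radii.min()):
            raise ValueError("wall thickness must be positive and smaller than "
                             "the smallest outer radius")
        nr, nc, nl = self.resolution
        if min(nr, nc, nl) < 1 or nc < 3:
            raise ValueError("invalid resolution")
        if not (0.0 < self.base_level < 1.0):
            raise ValueError("base_level must be in (0, 1)")
        if self.topology == "BiV":
            if not (0.0 < self.rv_insertion_level < 1.0):
                raise ValueError("rv_insertion_level must be in (0, 1)")
            if np.any(np.asarray(self.rv_size, dtype=float) <= 0):
                raise ValueError("rv_size must be positive")
            c_out = radii[2]
            if np.asarray(self.rv_size, dtype=float)[2] > c_out:
                raise ValueError("RV longer than LV")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateSpec":
        return cls(**d)


# ----------------------------------------------------------------------
# analytic volumes (used as test oracles and by documentation)


def truncated_ellipsoid_volume(a: float, b: float, c: float, z_cut: float) -> float:
    """Volume of a solid ellipsoid restricted to ``z <= z_cut`` (centre 0)."""
    z = float(np.clip(z_cut, -c, c))
    return float(np.pi * a * b * (z - z**3 / (3 * c * c) + 2.0 * c / 3.0))


def lv_shell_volume(spec: TemplateSpec) -> float:
    """Analytic volume of the undistorted LV template shell."""
    ao, bo, co = spec.lv_outer_radii
    t = spec.lv_wall_thickness
    ai, bi, ci = ao - t, bo - t, co - t
    zb = spec.base_level * ci
    return truncated_ellipsoid_volume(ao, bo, co, zb) - truncated_ellipsoid_volume(
        ai, bi, ci, zb
    )


# ----------------------------------------------------------------------
# parameterizations


class _LVParam:
    """Smooth map (lam, v, t) -> R^3 for the LV wall shell."""

    def __init__(self, spec: TemplateSpec):
        ao, bo, co = (float(r) for r in spec.lv_outer_radii)
        t = float(spec.lv_wall_thickness)
        self.outer = np.array([ao, bo, co])
        self.inner = np.array([ao - t, bo - t, co - t])
        self.z_base = spec.base_level * self.inner[2]
        # apical-hole meshes start above the pole
        self.v0 = spec.hole_level if spec.apex_style == "hole" else 0.0
        self.grading = spec.long_grading

    def __call__(self, lam, v, t):
        lam, v, t = np.broadcast_arrays(
            np.asarray(lam, float), np.asarray(v, float), np.asarray(t, float)
        )
        v = (1.0 - self.grading) * v + self.grading * v * v
        a = self.inner[0] + t * (self.outer[0] - self.inner[0])
        b = self.inner[1] + t * (self.outer[1] - self.inner[1])
        c = self.inner[2] + t * (self.outer[2] - self.inner[2])
        phi_b = np.arccos(np.clip(self.z_base / c, -1.0, 1.0))
        vv = self.v0 + v * (1.0 - self.v0)
        phi = np.pi + vv * (phi_b - np.pi)
        sp = np.sin(phi)
        return np.stack(
            [a * sp * np.cos(lam), b * sp * np.sin(lam), c * np.cos(phi)], axis=-1
        )


def _stencil_dofs(fun, params: np.ndarray, spans: Tuple[float, float, float],
                  h: Tuple[float, float, float]) -> np.ndarray:
    """All 8 Hermite DOF vectors of ``fun`` at each parameter triple.

    Mixed partials are taken by nested central differences of the smooth
    parameterization, then scaled by the per-axis element spans so that the
    derivatives are with respect to unit local coordinates.
    """
    params = np.asarray(params, dtype=float)  # (N, 3)
    n = params.shape[0]
    offs = np.array([-1.0, 0.0, 1.0])
    # evaluate on the full 3^3 stencil around every node
    grid = np.empty((n, 3, 3, 3, 3))
    for i, oi in enumerate(offs):
        for j, oj in enumerate(offs):
            for k, ok in enumerate(offs):
                grid[:, i, j, k, :] = fun(
                    params[:, 0] + oi * h[0],
                    params[:, 1] + oj * h[1],
                    params[:, 2] + ok * h[2],
                )
    dofs = np.empty((n, 2, 2, 2, 3))
    for d1 in range(2):
        for d2 in range(2):
            for d3 in range(2):
                g = grid
                for axis, (d, hh, span) in enumerate(
                    zip((d1, d2, d3), h, spans)
                ):
                    ax = 1  # after each reduction the stencil axes shift down
                    if d == 0:
                        g = np.take(g, 1, axis=ax)
                    else:
                        g = (np.take(g, 2, axis=ax) - np.take(g, 0, axis=ax)) / (
                            2.0 * hh
                        ) * span
                dofs[:, d1, d2, d3, :] = g
    return dofs


# ----------------------------------------------------------------------
# LV synthesis


def synthesize_lv(spec: TemplateSpec) -> HermiteMesh:
    """Build the LV template mesh for ``spec`` (topology must be LV)."""
    spec.validate()
    if spec.topology != "LV":
        raise ValueError("synthesize_lv requires topology='LV'")
    if spec.apex_style == "patch":
        raise NotImplementedError("squared-patch apex topology is not implemented")
    nr, nc, nl = spec.resolution
    param = _LVParam(spec)

    node_grid = np.arange(nc * (nl + 1) * (nr + 1)).reshape(nc, nl + 1, nr + 1)
    ic, il, ir = np.meshgrid(
        np.arange(nc), np.arange(nl + 1), np.arange(nr + 1), indexing="ij"
    )
    lam = 2.0 * np.pi * ic.ravel() / nc
    v = il.ravel() / nl
    t = ir.ravel() / nr
    spans = (2.0 * np.pi / nc, 1.0 / nl, 1.0 / nr)
    h = (1e-3 * spans[0], 1e-3 * spans[1], 1e-3 * spans[2])
    dofs = _stencil_dofs(param, np.stack([lam, v, t], axis=1), spans, h)

    ties: List[np.ndarray] = []
    if spec.apex_style == "collapsed":
        # force exact coincidence of each apex ring and zero the
        # circumferential tangent there (the pole is a true singular point)
        apex = node_grid[:, 0, :]  # (nc, nr+1)
        for k in range(nr + 1):
            ids = apex[:, k]
            c_k = param.inner[2] + (k / nr) * (param.outer[2] - param.inner[2])
            dofs[ids, 0, 0, 0, :] = np.array([0.0, 0.0, -c_k])
            ties.append(ids.copy())

    elements = []
    for e_ic in range(nc):
        for e_il in range(nl):
            for e_ir in range(nr):
                conn = [
                    node_grid[(e_ic + i1) % nc, e_il + i2, e_ir + i3]
                    for i3 in range(2)
                    for i2 in range(2)
                    for i1 in range(2)
                ]
                elements.append(conn)
    elements = np.asarray(elements, dtype=int)

    def eid(e_ic, e_il, e_ir):
        return (e_ic * nl + e_il) * nr + e_ir

    endo = [(eid(a, b, 0), 4) for a in range(nc) for b in range(nl)]
    epi = [(eid(a, b, nr - 1), 5) for a in range(nc) for b in range(nl)]
    base = [(eid(a, nl - 1, c), 3) for a in range(nc) for c in range(nr)]
    faces = {
        "endo_LV": np.asarray(endo),
        "epi": np.asarray(epi),
        "base": np.asarray(base),
    }
    if spec.apex_style == "hole":
        faces["apex"] = np.asarray([(eid(a, 0, c), 2) for a in range(nc) for c in range(nr)])

    solid = np.concatenate([faces[k] for k in faces], axis=0)
    return HermiteMesh(
        dofs,
        elements,
        topology="LV",
        resolution=spec.resolution,
        apex_style=spec.apex_style,
        surface_faces=faces,
        regions={"lv": node_grid},
        position_ties=ties,
        solid_faces={"lv": solid},
    )


# ----------------------------------------------------------------------
# BiV synthesis


class _RVParam:
    """RV free wall as a smooth outward bulge of the LV epicardium.

    ``(u, v, t)``: u sweeps the insertion arc, v the longitudinal span from
    the insertion parallel (v = v0) to the base, t the transmural direction
    (RV endo -> RV epi).  The bulge magnitude vanishes on the squared
    insertion line so boundary nodes coincide with LV epicardial nodes.
    """

    def __init__(self, spec: TemplateSpec, lv: _LVParam, lam0: float, lam_span: float,
                 v0: float):
        self.lv = lv
        self.lam0 = lam0
        self.lam_span = lam_span
        self.v0 = v0
        self.bulge = float(spec.rv_size[0])
        self.thick = float(spec.rv_wall_thickness)

    def _epi_and_normal(self, lam, v):
        q = self.lv(lam, v, 1.0)
        h = 1e-5
        tl = (self.lv(lam + h, v, 1.0) - self.lv(lam - h, v, 1.0)) / (2 * h)
        tv = (self.lv(lam, v + h, 1.0) - self.lv(lam, v - h, 1.0)) / (2 * h)
        n = np.cross(tl, tv)
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        # orient away from the long axis regardless of parameter handedness
        radial = q.copy()
        radial[..., 2] = 0.0
        flip = np.sum(n * radial, axis=-1) < 0
        n[flip] *= -1.0
        return q, n

    def __call__(self, u, v, t):
        u, v, t = np.broadcast_arrays(
            np.asarray(u, float), np.asarray(v, float), np.asarray(t, float)
        )
        lam = self.lam0 + u * self.lam_span
        q, n = self._epi_and_normal(lam, v)
        vt = (v - self.v0) / (1.0 - self.v0)
        s = np.sin(np.pi * u) * np.sin(0.5 * np.pi * vt)
        off = self.bulge * s + t * self.thick * s
        return q + off[..., None] * n


def synthesize_biv(spec: TemplateSpec) -> HermiteMesh:
    """Build the BiV template: LV shell plus attached RV free wall."""
    spec.validate()
    if spec.topology != "BiV":
        raise ValueError("synthesize_biv requires topology='BiV'")
    nr, nc, nl = spec.resolution
    lv_spec = TemplateSpec(**{**spec.to_dict(), "topology": "LV"})
    mesh = synthesize_lv(lv_spec)
    mesh.topology = "BiV"
    lv_param = _LVParam(spec)
    lv_grid = mesh.regions["lv"]

    # RV footprint: k_circ consecutive LV sectors centred near +x, from the
    # insertion parallel at longitudinal index j0 up to the base
    k_circ = max(2, int(round(nc / 3.0)))
    j0 = int(np.clip(round(nl * (1.0 - spec.rv_insertion_level)), 1, nl - 1))
    nl_rv = nl - j0
    i0 = (-(k_circ // 2)) % nc
    lam0 = 2.0 * np.pi * i0 / nc
    lam_span = 2.0 * np.pi * k_circ / nc
    v0 = j0 / nl
    rv = _RVParam(spec, lv_param, lam0, lam_span, v0)

    n_lv = mesh.n_nodes
    rv_grid = n_lv + np.arange((k_circ + 1) * (nl_rv + 1) * (nr + 1)).reshape(
        k_circ + 1, nl_rv + 1, nr + 1
    )
    iu, il, ir = np.meshgrid(
        np.arange(k_circ + 1), np.arange(nl_rv + 1), np.arange(nr + 1), indexing="ij"
    )
    u = iu.ravel() / k_circ
    v = v0 + (il.ravel() / nl_rv) * (1.0 - v0)
    t = ir.ravel() / nr
    spans = (1.0 / k_circ, (1.0 - v0) / nl_rv, 1.0 / nr)
    h = tuple(1e-3 * s for s in spans)
    rv_dofs = _stencil_dofs(rv, np.stack([u, v, t], axis=1), spans, h)

    # boundary columns collapse onto the LV epicardium exactly
    ties = list(mesh.position_ties)
    boundary: Dict[int, List[int]] = {}
    for a in range(k_circ + 1):
        for b in range(nl_rv + 1):
            on_edge = a in (0, k_circ) or b == 0
            if not on_edge:
                continue
            lv_node = lv_grid[(i0 + a) % nc, j0 + b, nr]
            q = mesh.node_dofs[lv_node, 0, 0, 0, :]
            ids = rv_grid[a, b, :] - n_lv
            rv_dofs[ids, 0, 0, 0, :] = q
            boundary.setdefault(lv_node, []).extend((ids + n_lv).tolist())
    for lv_node, group in boundary.items():
        ties.append(np.asarray([lv_node] + group, dtype=int))

    node_dofs = np.concatenate([mesh.node_dofs, rv_dofs], axis=0)

    rv_elements = []
    for a in range(k_circ):
        for b in range(nl_rv):
            for c in range(nr):
                conn = [
                    rv_grid[a + i1, b + i2, c + i3]
                    for i3 in range(2)
                    for i2 in range(2)
                    for i1 in range(2)
                ]
                rv_elements.append(conn)
    rv_elements = np.asarray(rv_elements, dtype=int)
    e0 = mesh.n_elements
    elements = np.concatenate([mesh.elements, rv_elements], axis=0)

    def rv_eid(a, b, c):
        return e0 + (a * nl_rv + b) * nr + c

    faces = {k: v.copy() for k, v in mesh.surface_faces.items()}
    endo_rv = [(rv_eid(a, b, 0), 4) for a in range(k_circ) for b in range(nl_rv)]
    epi_rv = [(rv_eid(a, b, nr - 1), 5) for a in range(k_circ) for b in range(nl_rv)]
    base_rv = [(rv_eid(a, nl_rv - 1, c), 3) for a in range(k_circ) for c in range(nr)]
    faces["endo_RV"] = np.asarray(endo_rv)
    faces["epi"] = np.concatenate([faces["epi"], np.asarray(epi_rv)], axis=0)
    faces["base"] = np.concatenate([faces["base"], np.asarray(base_rv)], axis=0)

    solids = {
        "lv": np.concatenate(
            [v for v in mesh.solid_faces.values()], axis=0
        ),
        "rv": np.concatenate(
            [np.asarray(endo_rv), np.asarray(epi_rv), np.asarray(base_rv)], axis=0
        ),
    }
    return HermiteMesh(
        node_dofs,
        elements,
        topology="BiV",
        resolution=spec.resolution,
        apex_style=spec.apex_style,
        surface_faces=faces,
        regions={"lv": lv_grid, "rv": rv_grid},
        position_ties=ties,
        solid_faces=solids,
    )


def synthesize(spec: TemplateSpec) -> HermiteMesh:
    """Dispatch on ``spec.topology``."""
    return synthesize_lv(spec) if spec.topology == "LV" else synthesize_biv(spec)


# ----------------------------------------------------------------------
# tailoring


def tailor_template(descriptor, base_spec: Optional[TemplateSpec] = None) -> TemplateSpec:
    """Fill a :class:`TemplateSpec` with dimensions measured from a mask.

    ``descriptor`` is a :class:`cardiomesh.shape.ShapeDescriptor`; wall
    thickness and the size of the cavities (and, for BiV, the relative RV
    size and insertion level) drive the tailoring.  The remaining template
    options come from ``base_spec``.
    """
    spec = TemplateSpec(**(base_spec.to_dict() if base_spec is not None else {}))
    if descriptor.lv_cavity_radii is None:
        raise ValueError("descriptor carries no LV cavity measurements")
    thick = float(descriptor.wall_thickness)
    inner = np.maximum(np.asarray(descriptor.lv_cavity_radii, dtype=float), 2.0 * thick)
    spec.lv_outer_radii = tuple(inner + thick)
    spec.lv_wall_thickness = thick
    if descriptor.basal_height is not None:
        spec.base_level = float(np.clip(descriptor.basal_height / inner[2], 0.2, 0.85))
    if spec.topology == "BiV":
        if descriptor.rv_centroid is None or descriptor.rv_size is None:
            raise ValueError("BiV template requested but descriptor has no RV fields")
        rv_size = np.asarray(descriptor.rv_size, dtype=float)
        # measured pool extents can be noisy; keep the RV shorter than the LV
        rv_size[2] = min(rv_size[2], 0.95 * float(spec.lv_outer_radii[2]))
        spec.rv_size = tuple(rv_size)
        if descriptor.rv_insertion_level is not None:
            spec.rv_insertion_level = float(
                np.clip(descriptor.rv_insertion_level, 0.2, 0.9)
            )
        spec.rv_wall_thickness = 0.5 * thick
    spec.validate()
    return spec
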