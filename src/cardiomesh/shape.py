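"""Shape analysis of binary ventricular masks.

Extracts blood pools and valve openings (convex hull + morphology),
characteristic orientation axes, cavity dimensions, wall thickness and the
anisotropic scaling factors, and provides the initial affine alignment
between a template and a target anatomy.

Coordinate convention: images are axis-aligned; voxel index ``i`` maps to
world position ``origin + i * spacing`` (mm).  Direction matrices must be
pre-applied by the reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "BinaryMask",
    "ShapeDescriptor",
    "find_pools_and_valves",
    "fit_basal_plane",
    "compute_axes",
    "measure_dimensions",
    "analyze_mask",
    "truncate_base",
    "initial_affine",
    "load_mask",
    "save_mask",
]

_BALL6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


@dataclass
class BinaryMask:
    """3-D boolean voxel grid with spacing/origin in mm.

    ``data_slices`` optionally lists the slice indices along ``slice_axis``
    that carry original data (sparse dynamic studies); all other slices are
    null filler.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    data_slices: Optional[List[int]] = None
    slice_axis: int = 2

    def __post_init__(self):
        # C-contiguous: flat views are relied upon (e.g. the hull fill);
        # NIfTI readers hand back Fortran-ordered arrays
        self.voxels = np.ascontiguousarray(np.asarray(self.voxels).astype(bool))
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if not self.voxels.any():
            raise ValueError("mask has no foreground voxels")

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World positions (mm) of (N, 3) voxel indices."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def foreground_world(self) -> np.ndarray:
        return self.world(np.argwhere(self.voxels))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def copy(self) -> "BinaryMask":
        return BinaryMask(
            self.voxels.copy(),
            self.spacing.copy(),
            self.origin.copy(),
            None if self.data_slices is None else list(self.data_slices),
            self.slice_axis,
        )


@dataclass
class ShapeDescriptor:
    """Orientation axes, basal plane and size measurements of a mask.

    ``axis_lr``, ``axis_third``, ``axis_long`` form a right-handed
    orthonormal frame; ``basal_plane = (point, normal)`` with the normal
    oriented toward the valve (apex-free) side.  Sizes derive from
    coordinate variances along the axes; ``lv_cavity_radii`` are refined
    ellipsoid semi-axis estimates of the LV blood pool used for template
    tailoring.  RV fields are ``None`` for LV-only masks.
    """

    axis_long: np.ndarray
    axis_lr: np.ndarray
    axis_third: np.ndarray
    basal_plane: Tuple[np.ndarray, np.ndarray]
    centroid: np.ndarray
    lv_centroid: np.ndarray
    lv_size: np.ndarray
    scaling: np.ndarray
    wall_thickness: float
    lv_cavity_radii: Optional[np.ndarray] = None
    basal_height: Optional[float] = None
    rv_centroid: Optional[np.ndarray] = None
    rv_size: Optional[np.ndarray] = None
    rv_insertion_level: Optional[float] = None
    valve_voxels: Optional[np.ndarray] = None
    lv_pool: Optional[np.ndarray] = None
    rv_pool: Optional[np.ndarray] = None

    @property
    def frame(self) -> np.ndarray:
        """Rotation matrix with columns (axis_lr, axis_third, axis_long)."""
        return np.stack([self.axis_lr, self.axis_third, self.axis_long], axis=1)


# ----------------------------------------------------------------------
# pools and valves


def convex_hull_fill(fg: np.ndarray) -> np.ndarray:
    """Voxelized convex hull of a boolean grid (voxel-centre inside test).

    The hull of the boundary voxels is intersected with every vertical
    voxel column (a convex set meets a line in an interval), which is much
    faster than a dense point-in-hull test on large grids.
    """
    surf = fg & ~ndimage.binary_erosion(fg, _BALL6)
    pts = np.argwhere(surf).astype(float)
    if pts.shape[0] < 4:
        return fg.copy()
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return fg.copy()
    eq = hull.equations  # n . x + d <= 0 inside
    nx, ny, nz = fg.shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cols = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(float)
    lo = np.full(cols.shape[0], 0.0)
    hi = np.full(cols.shape[0], float(nz - 1))
    feasible = np.ones(cols.shape[0], dtype=bool)
    tol = 1e-9
    for a, b, c, d in eq:
        rhs = -(d + a * cols[:, 0] + b * cols[:, 1])
        if c > tol:
            hi = np.minimum(hi, rhs / c)
        elif c < -tol:
            lo = np.maximum(lo, rhs / c)
        else:
            feasible &= rhs >= -1e-9
    lo_i = np.ceil(lo - 1e-9).astype(int)
    hi_i = np.floor(hi + 1e-9).astype(int)
    out = np.zeros(fg.shape, dtype=bool)  # C-order: reshaped below as a view
    z = np.arange(nz)
    ok = feasible & (lo_i <= hi_i)
    flat = out.reshape(-1, nz)
    band = (z[None, :] >= lo_i[ok, None]) & (z[None, :] <= hi_i[ok, None])
    flat[np.flatnonzero(ok)] = band
    return out | fg


def find_pools_and_valves(mask: BinaryMask, max_erosions: int = 5):
    """Identify the blood pools and valve-opening voxels of a mask.

    The cavity is the convex-hull fill minus the myocardium; voxels of the
    cavity that reach the hull boundary mark the valve openings.  Connected
    components of the remaining cavity are separated, eroding adaptively
    (6-connected ball) until a second sizable component appears; the two
    largest components are the LV and RV pools.  The LV is the pool with
    the larger volume-to-surface ratio (more convex), ties broken by
    volume.

    Returns ``(lv_pool, rv_pool_or_None, valve_voxels)`` as boolean grids.
    """
    fg = mask.voxels
    hull = convex_hull_fill(fg)
    cavity = hull & ~fg
    if not cavity.any():
        raise ValueError("no cavity found: the mask is a solid blob")

    outside = ~hull
    # one erosion strips the thin hull-vs-shell discretization slivers
    core = ndimage.binary_erosion(cavity, _BALL6)
    if not core.any():
        raise ValueError("cavity is a thin shell along the hull; no pool found")

    min_pool = max(30, int(0.02 * core.sum()))
    near_hull = ndimage.binary_dilation(outside, _BALL6, iterations=3)
    eroded = core
    chosen = None
    for _ in range(max_erosions + 1):
        lbl, n = ndimage.label(eroded, structure=_BALL6)
        if n == 0:
            break
        sizes = np.bincount(lbl.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        # true blood pools touch the hull boundary only at their basal
        # opening; hull-concavity gap regions hug it over most of their
        # surface and are rejected by their hull-contact ratio
        keep = []
        for k in order:
            if sizes[k] < min_pool:
                break
            comp = lbl == k + 1
            contact = np.count_nonzero(comp & near_hull) / sizes[k]
            if contact < 0.25:
                keep.append(k + 1)
            if len(keep) == 2:
                break
        if keep:
            chosen = (lbl, np.asarray(keep))
            break
        eroded = ndimage.binary_erosion(eroded, _BALL6)
    if chosen is None:
        raise ValueError("no pool found after erosion")
    lbl, keep = chosen

    # grow the (possibly eroded) pool labels back over the cavity core, but
    # only within the un-eroded components that contain the seeds (so pools
    # never leak into disjoint hull-concavity regions)
    base_lbl, _ = ndimage.label(core, structure=_BALL6)
    seeds = np.where(np.isin(lbl, keep), lbl, 0)
    _, (ix, iy, iz) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
    grown = np.zeros_like(lbl)
    grown[core] = seeds[ix[core], iy[core], iz[core]]
    pools = []
    for k in keep:
        base_ids = np.unique(base_lbl[(seeds == k) & (base_lbl > 0)])
        pools.append((grown == k) & np.isin(base_lbl, base_ids))
    # valve openings: cavity voxels that reach the hull boundary next to a pool
    any_pool = np.zeros_like(fg)
    for p in pools:
        any_pool |= p
    near_pool = ndimage.binary_dilation(any_pool, _BALL6, iterations=2)
    valve = cavity & ndimage.binary_dilation(outside, _BALL6) & near_pool
    if not valve.any():
        raise ValueError("no valve opening found (closed shell)")
    # spurious hull-contact voxels (e.g. along the RV insertion) come in
    # small fragments; the opening is the dominant connected patch
    vlbl, vn = ndimage.label(valve, structure=np.ones((3, 3, 3), dtype=bool))
    if vn > 1:
        vsizes = np.bincount(vlbl.ravel())[1:]
        valve = vlbl == (int(np.argmax(vsizes)) + 1)
    if len(pools) == 1:
        return pools[0], None, valve

    def vs_ratio(p):
        surf = p & ~ndimage.binary_erosion(p, _BALL6)
        return p.sum() / max(surf.sum(), 1)

    r = [vs_ratio(p) for p in pools]
    v = [p.sum() for p in pools]
    if abs(r[0] - r[1]) / max(r) > 0.05:
        lv_i = int(np.argmax(r))
    else:
        lv_i = int(np.argmax(v))
    return pools[lv_i], pools[1 - lv_i], valve


# ----------------------------------------------------------------------
# basal plane and axes


def fit_basal_plane(
    valve_voxels: np.ndarray,
    spacing,
    origin,
    reference_point: Optional[np.ndarray] = None,
):
    """Total-least-squares plane through the valve voxel centres (world mm).

    Returns ``(point, normal)``.  When ``reference_point`` is given (e.g.
    the LV pool centroid) the normal is oriented away from it, i.e. toward
    the apex-free side.
    """
    idx = np.argwhere(np.asarray(valve_voxels, dtype=bool))
    if idx.shape[0] < 3:
        raise ValueError("need at least 3 valve voxels to fit a plane")
    pts = np.asarray(origin, float) + idx * np.asarray(spacing, float)
    sel = np.ones(len(pts), dtype=bool)
    for _ in range(3):  # trimmed TLS: re-fit on inliers
        centre = pts[sel].mean(axis=0)
        u, s, vt = np.linalg.svd(pts[sel] - centre, full_matrices=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError("valve voxels are collinear; cannot fit a plane")
        normal = vt[2]
        res = np.abs((pts - centre) @ normal)
        cut = max(3.0 * np.median(res[sel]), float(np.max(spacing)))
        new_sel = res <= cut
        if new_sel.sum() < 3 or np.array_equal(new_sel, sel):
            break
        sel = new_sel
    if reference_point is not None and np.dot(normal, centre - np.asarray(reference_point, float)) < 0:
        normal = -normal
    return centre, normal


def compute_axes(
    mask: BinaryMask,
    lv_pool: np.ndarray,
    rv_pool: Optional[np.ndarray],
    plane,
):
    """Characteristic orientation frame of the anatomy.

    The long axis is the basal-plane normal — or the slice-stack normal when
    ``mask.data_slices`` is set.  The left-right axis is the in-plane
    projection of the LV->RV centroid vector (for LV-only masks: the larger
    in-plane principal inertia direction of the LV pool).  The third axis
    closes a right-handed frame.
    """
    point, normal = plane
    if mask.data_slices is not None:
        axis_long = np.zeros(3)
        axis_long[mask.slice_axis] = 1.0
        if np.dot(axis_long, normal) < 0:
            axis_long = -axis_long
    else:
        axis_long = normal / np.linalg.norm(normal)

    lv_c = mask.world(np.argwhere(lv_pool)).mean(axis=0)
    if rv_pool is not None:
        rv_c = mask.world(np.argwhere(rv_pool)).mean(axis=0)
        d = rv_c - lv_c
        d -= np.dot(d, axis_long) * axis_long
        if np.linalg.norm(d) < 1e-9:
            raise ValueError("LV->RV vector has zero in-plane projection")
        axis_lr = d / np.linalg.norm(d)
    else:
        pts = mask.world(np.argwhere(lv_pool)) - lv_c
        pts -= np.outer(pts @ axis_long, axis_long)
        cov = pts.T @ pts / len(pts)
        w, v = np.linalg.eigh(cov)
        axis_lr = v[:, np.argmax(w)]
        rv_c = None
    axis_third = np.cross(axis_long, axis_lr)
    axis_third /= np.linalg.norm(axis_third)
    axis_lr = np.cross(axis_third, axis_long)  # enforce exact orthonormality
    return axis_long, axis_lr, axis_third, lv_c, rv_c


# ----------------------------------------------------------------------
# dimensions


def _std_sizes(pts: np.ndarray, frame: np.ndarray, factor: float) -> np.ndarray:
    q = (pts - pts.mean(axis=0)) @ frame
    return factor * q.std(axis=0)


def measure_dimensions(
    mask: BinaryMask,
    descriptor: ShapeDescriptor,
) -> ShapeDescriptor:
    """Fill in cavity sizes, wall thickness and the RV insertion level.

    Variance-based sizes use the uniform-solid-ellipsoid moment (semi-axis
    = sqrt(5) * std).  Refined LV cavity radii come from the maximal
    cross-section slab (in-plane semi-axes = 2 * in-plane std of a solid
    ellipse) and the apex extent; these drive template tailoring.  Wall
    thickness is twice the modal ridge value of the Euclidean distance
    transform of the myocardium.
    """
    frame = descriptor.frame
    lv_pts = mask.world(np.argwhere(descriptor.lv_pool))
    descriptor.lv_size = _std_sizes(lv_pts, frame, np.sqrt(5.0))

    # refined cavity radii in the characteristic frame
    q = (lv_pts - descriptor.lv_centroid) @ frame
    z = q[:, 2]
    dz = float(np.mean(mask.spacing))
    bins = np.arange(z.min() - 0.5 * dz, z.max() + 1.5 * dz, dz)
    hist, edges = np.histogram(z, bins=bins)
    if len(hist) >= 5:
        kernel = np.ones(5) / 5.0
        hist = np.convolve(hist, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    plateau = hist >= 0.97 * hist.max()
    z0 = float(centers[plateau].mean())
    slab_half = max(2.0 * dz, 0.08 * (z.max() - z.min()))
    slab = np.abs(z - z0) <= slab_half
    a = 2.0 * q[slab, 0].std()
    b = 2.0 * q[slab, 1].std()
    # +1 voxel: the pool was eroded once during cavity extraction
    c = z0 - z.min() + 1.5 * dz
    descriptor.lv_cavity_radii = np.array([a, b, c])

    plane_pt, plane_n = descriptor.basal_plane
    centre_world = descriptor.lv_centroid + frame @ np.array([0.0, 0.0, z0])
    descriptor.basal_height = float(np.dot(plane_pt - centre_world, plane_n))

    # wall thickness: mode of the distance-transform ridge, restricted to
    # the LV wall (voxels nearer the LV pool than the RV pool) so the
    # thinner RV free wall cannot capture the mode
    dt = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    ridge = (ndimage.maximum_filter(dt, size=3) == dt) & mask.voxels & (dt > 0.25 * dt.max())
    if descriptor.rv_pool is not None:
        d_lv = ndimage.distance_transform_edt(~descriptor.lv_pool, sampling=mask.spacing)
        d_rv = ndimage.distance_transform_edt(~descriptor.rv_pool, sampling=mask.spacing)
        ridge &= d_lv <= d_rv
    vals = 2.0 * dt[ridge]
    step = float(np.min(mask.spacing))
    hist, edges = np.histogram(vals, bins=np.arange(0, vals.max() + 2 * step, step))
    k = int(np.argmax(hist))
    descriptor.wall_thickness = float(0.5 * (edges[k] + edges[k + 1]))

    if descriptor.rv_pool is not None:
        rv_pts = mask.world(np.argwhere(descriptor.rv_pool))
        descriptor.rv_size = _std_sizes(rv_pts, frame, np.sqrt(5.0))
        rv_z = (rv_pts - descriptor.lv_centroid) @ descriptor.axis_long
        lv_z = z
        rv_extent = rv_z.max() - rv_z.min()
        lv_extent = lv_z.max() - lv_z.min()
        descriptor.rv_insertion_level = float(np.clip(rv_extent / lv_extent, 0.05, 0.95))
    return descriptor


def analyze_mask(mask: BinaryMask) -> ShapeDescriptor:
    """Full shape analysis: pools, valves, basal plane, axes, dimensions."""
    lv_pool, rv_pool, valve = find_pools_and_valves(mask)
    lv_c0 = mask.world(np.argwhere(lv_pool)).mean(axis=0)
    plane = fit_basal_plane(valve, mask.spacing, mask.origin, reference_point=lv_c0)
    axis_long, axis_lr, axis_third, lv_c, rv_c = compute_axes(mask, lv_pool, rv_pool, plane)
    fg_pts = mask.foreground_world()
    frame = np.stack([axis_lr, axis_third, axis_long], axis=1)
    desc = ShapeDescriptor(
        axis_long=axis_long,
        axis_lr=axis_lr,
        axis_third=axis_third,
        basal_plane=plane,
        centroid=fg_pts.mean(axis=0),
        lv_centroid=lv_c,
        lv_size=np.zeros(3),
        scaling=_std_sizes(fg_pts, frame, 1.0),
        wall_thickness=0.0,
        rv_centroid=rv_c,
        valve_voxels=valve,
        lv_pool=lv_pool,
        rv_pool=rv_pool,
    )
    return measure_dimensions(mask, desc)


# ----------------------------------------------------------------------
# basal truncation


def truncate_base(mask: BinaryMask, plane, offset_mm: float = 5.0) -> BinaryMask:
    """Remove anatomy above the basal plane shifted ``offset_mm`` apex-ward.

    The plane normal must point toward the valve side; voxels on that side
    of the shifted plane are cleared.  Truncating twice is a no-op.
    """
    point, normal = plane
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    shifted = np.asarray(point, float) - offset_mm * normal
    nx, ny, nz = mask.voxels.shape
    ii = np.arange(nx)[:, None, None] * mask.spacing[0]
    jj = np.arange(ny)[None, :, None] * mask.spacing[1]
    kk = np.arange(nz)[None, None, :] * mask.spacing[2]
    d = (
        (mask.origin[0] - shifted[0]) * normal[0]
        + (mask.origin[1] - shifted[1]) * normal[1]
        + (mask.origin[2] - shifted[2]) * normal[2]
        + ii * normal[0]
        + jj * normal[1]
        + kk * normal[2]
    )
    keep = d <= 0
    n_before = int(mask.voxels.sum())
    voxels = mask.voxels & keep
    n_after = int(voxels.sum())
    if n_after < 0.5 * n_before:
        raise ValueError(
            f"basal truncation would remove {100 * (1 - n_after / n_before):.0f}% "
            "of the foreground; check the basal plane"
        )
    out = mask.copy()
    out.voxels = voxels
    return out


# ----------------------------------------------------------------------
# initial affine


def initial_affine(template_descriptor: ShapeDescriptor, target_descriptor: ShapeDescriptor):
    """Affine (A, t) mapping template space onto target space.

    Composition of the rotation between the characteristic frames, the
    anisotropic scaling given by the ratio of scaling factors, and the
    translation between centroids:  ``x -> A x + t`` with
    ``A = R_target diag(s) R_template^T``.  ``det A > 0`` always (both
    frames are right-handed, scales positive).
    """
    for d in (template_descriptor, target_descriptor):
        F = d.frame
        if not np.allclose(F.T @ F, np.eye(3), atol=1e-8):
            raise ValueError("descriptor axes are not orthonormal")
    s = target_descriptor.scaling / template_descriptor.scaling
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("invalid scaling factors")
    A = target_descriptor.frame @ np.diag(s) @ template_descriptor.frame.T
    t = target_descriptor.centroid - A @ template_descriptor.centroid
    return A, t


# ----------------------------------------------------------------------
# I/O


def load_mask(path: str) -> BinaryMask:
    """Read a binary mask from NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha).

    Any nonzero voxel is foreground.  The image grid is assumed
    axis-aligned: spacing comes from the header, origin from the affine
    translation / offset.
    """
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return BinaryMask(data != 0, spacing, origin)
    if lower.endswith((".mhd", ".mha")):
        return _load_metaimage(path)
    raise ValueError(f"unsupported mask format: {path}")


def save_mask(mask: BinaryMask, path: str) -> str:
    """Write a mask as NIfTI (uint8)."""
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    img.to_filename(path)
    return path


_META_DTYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def _load_metaimage(path: str) -> BinaryMask:
    header = {}
    with open(path, "rb") as fh:
        data_start = None
        while True:
            line = fh.readline()
            if not line:
                break
            text = line.decode("ascii", errors="replace").strip()
            if "=" not in text:
                continue
            key, val = (t.strip() for t in text.split("=", 1))
            header[key] = val
            if key == "ElementDataFile":
                data_start = fh.tell()
                break
    dims = [int(t) for t in header["DimSize"].split()]
    spacing = [float(t) for t in header.get("ElementSpacing", "1 1 1").split()]
    origin = [float(t) for t in header.get("Offset", header.get("Position", "0 0 0")).split()]
    dtype = _META_DTYPES[header.get("ElementType", "MET_UCHAR")]
    if header.get("CompressedData", "False").lower() == "true":
        raise ValueError("compressed MetaImage data is not supported")
    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        with open(path, "rb") as fh:
            fh.seek(data_start)
            raw = fh.read()
    else:
        with open(os.path.join(os.path.dirname(path), datafile), "rb") as fh:
            raw = fh.read()
    n = int(np.prod(dims))
    data = np.frombuffer(raw, dtype=dtype, count=n)
    # MetaImage stores x-fastest; transpose to (x, y, z) index order
    vol = data.reshape(dims[::-1]).transpose(2, 1, 0)
    return BinaryMask(vol != 0, spacing, origin)
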