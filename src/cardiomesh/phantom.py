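"""Synthetic ventricular phantoms with analytic ground truth.

Masks are produced by an analytic inside test of a (optionally deformed and
rigidly posed) truncated-ellipsoid myocardial shell evaluated at voxel
centres — no mesh rasterization is involved, so the generator is an
independent oracle for the whole pipeline.  Deformations are restricted to
analytic, invertible families (affine, radial inflation, sinusoidal bump)
so the ground-truth displacement is known exactly at any point.

The BiV phantom adds an RV free wall as a crescent: the set inside an
offset RV-epicardial ellipsoid, outside the RV-endocardial ellipsoid and
outside the LV epicardial ellipsoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .shape import BinaryMask

__all__ = [
    "Deformation",
    "AffineDeformation",
    "RadialInflation",
    "SinusoidalBump",
    "PhantomSpec",
    "GroundTruth",
    "generate_mask",
    "sparsify",
    "apply_slice_shift",
    "random_cohort",
    "rotation_matrix",
]


def rotation_matrix(axis: Sequence[float], angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle_rad``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


class Deformation:
    """Invertible analytic map of world space; identity by default."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float)

    def displacement(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x) - np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {"kind": "identity"}


class AffineDeformation(Deformation):
    def __init__(self, A, b):
        self.A = np.asarray(A, dtype=float).reshape(3, 3)
        self.b = np.asarray(b, dtype=float).reshape(3)
        self.Ainv = np.linalg.inv(self.A)

    def forward(self, x):
        return np.asarray(x, float) @ self.A.T + self.b

    def inverse(self, y):
        return (np.asarray(y, float) - self.b) @ self.Ainv.T

    def to_dict(self):
        return {"kind": "affine", "A": self.A.tolist(), "b": self.b.tolist()}


class RadialInflation(Deformation):
    """Isotropic inflation about a centre: x -> c + f * (x - c)."""

    def __init__(self, center, factor: float):
        self.center = np.asarray(center, dtype=float).reshape(3)
        self.factor = float(factor)

    def forward(self, x):
        return self.center + self.factor * (np.asarray(x, float) - self.center)

    def inverse(self, y):
        return self.center + (np.asarray(y, float) - self.center) / self.factor

    def to_dict(self):
        return {"kind": "radial", "center": self.center.tolist(), "factor": self.factor}


class SinusoidalBump(Deformation):
    """Smooth periodic displacement; a contraction, inverted by iteration.

    ``u_i(x) = amplitude_i * sin(2 pi (x_j + x_k) / wavelength + phase_i)``
    with (j, k) the other two coordinates.  Invertibility requires
    ``max|amplitude| * 2 pi sqrt(2) / wavelength < 1``.
    """

    def __init__(self, amplitude, wavelength: float, phase=(0.0, 0.0, 0.0)):
        self.amplitude = np.asarray(amplitude, dtype=float).reshape(3)
        self.wavelength = float(wavelength)
        self.phase = np.asarray(phase, dtype=float).reshape(3)
        lip = np.abs(self.amplitude).max() * 2 * np.pi * np.sqrt(2) / self.wavelength
        if lip >= 0.95:
            raise ValueError("bump amplitude too large for invertibility")

    def displacement(self, x):
        x = np.asarray(x, dtype=float)
        u = np.empty_like(x)
        k = 2 * np.pi / self.wavelength
        for i in range(3):
            j, l = (i + 1) % 3, (i + 2) % 3
            u[..., i] = self.amplitude[i] * np.sin(k * (x[..., j] + x[..., l]) + self.phase[i])
        return u

    def forward(self, x):
        return np.asarray(x, float) + self.displacement(x)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        x = y.copy()
        for _ in range(50):
            x_new = y - self.displacement(x)
            if np.max(np.abs(x_new - x)) < 1e-10:
                x = x_new
                break
            x = x_new
        return x

    def to_dict(self):
        return {
            "kind": "bump",
            "amplitude": self.amplitude.tolist(),
            "wavelength": self.wavelength,
            "phase": self.phase.tolist(),
        }


@dataclass
class PhantomSpec:
    """Parameters of one synthetic anatomy; output is deterministic."""

    topology: str = "LV"
    lv_outer_radii: Tuple[float, float, float] = (35.0, 35.0, 50.0)
    wall_thickness: float = 10.0
    rv_outer_radii: Tuple[float, float, float] = (30.0, 32.0, 42.0)
    rv_wall_thickness: float = 5.0
    rv_center_offset: float = 28.0  # RV ellipsoid centre shift along +x (mm)
    rv_center_height: float = 0.0  # and along +z (mm)
    base_level: float = 0.5  # truncation height as fraction of inner long semi-axis
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin: float = 6.0  # empty border around the anatomy (mm)
    rotation_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle_deg: float = 0.0
    translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation: Optional[Deformation] = None
    seed: int = 0

    def pose(self) -> Tuple[np.ndarray, np.ndarray]:
        R = rotation_matrix(self.rotation_axis, np.deg2rad(self.rotation_angle_deg))
        return R, np.asarray(self.translation, dtype=float)


@dataclass
class GroundTruth:
    """Analytic description of the generated anatomy."""

    spec: PhantomSpec
    R: np.ndarray
    t: np.ndarray
    z_base: float

    def canonical(self, world_pts: np.ndarray) -> np.ndarray:
        """Map world points back to the canonical (undeformed) frame."""
        p = np.asarray(world_pts, dtype=float)
        if self.spec.deformation is not None:
            p = self.spec.deformation.inverse(p)
        return (p - self.t) @ self.R

    def to_json(self) -> str:
        d = {
            "topology": self.spec.topology,
            "lv_outer_radii": list(self.spec.lv_outer_radii),
            "wall_thickness": self.spec.wall_thickness,
            "z_base": self.z_base,
            "rotation": self.R.tolist(),
            "translation": self.t.tolist(),
            "deformation": (self.spec.deformation or Deformation()).to_dict(),
        }
        return json.dumps(d, indent=2)


def _inside_ellipsoid(q: np.ndarray, radii, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    r = np.asarray(radii, dtype=float)
    c = np.asarray(center, dtype=float)
    s = (q - c) / r
    return np.einsum("...i,...i->...", s, s) <= 1.0


def _inside_canonical(q: np.ndarray, spec: PhantomSpec, z_base: float) -> np.ndarray:
    outer = np.asarray(spec.lv_outer_radii, dtype=float)
    inner = outer - spec.wall_thickness
    below = q[..., 2] <= z_base
    lv = _inside_ellipsoid(q, outer) & ~_inside_ellipsoid(q, inner) & below
    if spec.topology != "BiV":
        return lv
    rv_c = np.array([spec.rv_center_offset, 0.0, spec.rv_center_height])
    rv_out = np.asarray(spec.rv_outer_radii, dtype=float)
    rv_in = rv_out - spec.rv_wall_thickness
    rv = (
        _inside_ellipsoid(q, rv_out, rv_c)
        & ~_inside_ellipsoid(q, rv_in, rv_c)
        & ~_inside_ellipsoid(q, outer)
        & below
    )
    return lv | rv


def generate_mask(spec: PhantomSpec) -> Tuple[BinaryMask, GroundTruth]:
    """Rasterize the phantom: foreground iff the voxel centre is inside the
    (deformed, posed) myocardial shell.  Deterministic for a fixed spec."""
    if spec.wall_thickness < max(spec.spacing):
        import warnings

        warnings.warn("wall thinner than voxel spacing; shell may be broken")
    R, t = spec.pose()
    outer = np.asarray(spec.lv_outer_radii, dtype=float)
    inner = outer - spec.wall_thickness
    z_base = spec.base_level * inner[2]

    reach = float(np.max(outer))
    if spec.topology == "BiV":
        reach = max(
            reach,
            spec.rv_center_offset + float(np.max(spec.rv_outer_radii)),
            abs(spec.rv_center_height) + float(np.max(spec.rv_outer_radii)),
        )
    if spec.deformation is not None:
        reach *= 1.15
    half = reach + spec.margin
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = np.ceil(2 * half / spacing).astype(int) + 1
    origin = t - (shape - 1) * spacing / 2.0

    idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = origin + idx * spacing
    q = pts
    if spec.deformation is not None:
        q = spec.deformation.inverse(q)
    q = (q - t) @ R
    inside = _inside_canonical(q, spec, z_base).reshape(tuple(shape))
    mask = BinaryMask(inside, spacing, origin)
    return mask, GroundTruth(spec, R, t, z_base)


def sparsify(mask: BinaryMask, interslice_distance: float, axis: int = 2) -> BinaryMask:
    """Keep only slices at the requested spacing; the rest become null.

    Retained slice indices are recorded in ``data_slices`` (the grid and
    spacing are unchanged: filler slices carry zero intensity, matching a
    near-isotropic rebuild of a sparse stack).
    """
    step = interslice_distance / mask.spacing[axis]
    if step < 1.0 - 1e-9:
        raise ValueError("interslice distance smaller than slice spacing")
    stride = int(round(step))
    n = mask.voxels.shape[axis]
    keep = list(range(0, n, stride))
    if len(keep) < 3:
        raise ValueError("fewer than 3 slices retained")
    out = mask.copy()
    sl = [slice(None)] * 3
    for i in range(n):
        if i not in keep:
            sl[axis] = i
            out.voxels[tuple(sl)] = False
    out.data_slices = keep
    out.slice_axis = axis
    return out


def apply_slice_shift(mask: BinaryMask, shifts, axis: int = 2) -> BinaryMask:
    """Translate each slice in-plane by its (2-vector, mm) shift.

    Nearest-voxel shifts emulate breath-hold misregistration; voxels pushed
    over the edge are clipped.
    """
    shifts = np.asarray(shifts, dtype=float)
    n = mask.voxels.shape[axis]
    if shifts.shape != (n, 2):
        raise ValueError(f"need one 2-vector per slice: expected {(n, 2)}")
    inplane = [a for a in range(3) if a != axis]
    extents = [mask.voxels.shape[a] * mask.spacing[a] for a in inplane]
    if np.any(np.abs(shifts) > np.asarray(extents)):
        raise ValueError("slice shift larger than the field of view")
    out = mask.copy()
    sl = [slice(None)] * 3
    for i in range(n):
        sl[axis] = i
        plane = mask.voxels[tuple(sl)]
        sv = [int(round(shifts[i, k] / mask.spacing[inplane[k]])) for k in range(2)]
        shifted = np.zeros_like(plane)
        src = [slice(max(0, -sv[k]), plane.shape[k] - max(0, sv[k])) for k in range(2)]
        dst = [slice(max(0, sv[k]), plane.shape[k] - max(0, -sv[k])) for k in range(2)]
        shifted[tuple(dst)] = plane[tuple(src)]
        out.voxels[tuple(sl)] = shifted
    return out


def random_cohort(
    n: int,
    base_spec: PhantomSpec,
    radii_frac: float = 0.2,
    thickness_frac: float = 0.3,
    rotation_deg: float = 20.0,
    translation_mm: float = 5.0,
    seed: int = 0,
) -> List[PhantomSpec]:
    """``n`` reproducible phantom specs with uniformly varied shape and pose."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, v in (("radii_frac", radii_frac), ("thickness_frac", thickness_frac)):
        if not (0 <= v < 1):
            raise ValueError(f"invalid range for {name}")
    rng = np.random.default_rng(seed)
    base_radii = np.asarray(base_spec.lv_outer_radii, dtype=float)
    specs = []
    for i in range(n):
        radii = base_radii * (1 + rng.uniform(-radii_frac, radii_frac, size=3))
        thick = base_spec.wall_thickness * (1 + rng.uniform(-thickness_frac, thickness_frac))
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        ang = rng.uniform(-rotation_deg, rotation_deg)
        tr = rng.uniform(-translation_mm, translation_mm, size=3)
        specs.append(
            PhantomSpec(
                topology=base_spec.topology,
                lv_outer_radii=tuple(radii),
                wall_thickness=float(thick),
                rv_outer_radii=base_spec.rv_outer_radii,
                rv_wall_thickness=base_spec.rv_wall_thickness,
                rv_center_offset=base_spec.rv_center_offset,
                base_level=base_spec.base_level,
                spacing=base_spec.spacing,
                margin=base_spec.margin,
                rotation_axis=tuple(ax),
                rotation_angle_deg=float(ang),
                translation=tuple(tr),
                deformation=base_spec.deformation,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return specs
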