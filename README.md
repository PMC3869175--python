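# cardiomesh

Fully automatic personalization of high-order (tricubic Hermite)
ventricular meshes from binary segmentation masks.

Given a 3-D binary mask of the ventricular myocardium (LV-only or
biventricular, NIfTI or MetaImage), the pipeline runs four steps:

1. **Shape analysis & template synthesis** — blood pools and valve
   openings are found via convex-hull/morphology analysis, a basal plane
   and characteristic axes are fitted, and an idealized truncated-ellipsoid
   template mesh (collapsed apex, optional apical hole) is tailored to the
   measured dimensions.
2. **Registration** — after an affine alignment from the characteristic
   axes/scales, a multi-pass control-grid registration (level-of-detail
   1–5: 1–5 passes, node spacing 10→2 voxels in steps of 2) computes a
   dense displacement field. Sparse short-axis stacks are supported: the
   similarity is evaluated only on the slices carrying original data.
3. **Variational warping** — the field is projected onto the mesh's
   Hermite degrees of freedom by minimizing the L2 norm of the projection
   error over the mesh volume.
4. **Quality enhancement & metrics** — transmural linearization raises
   element quality without moving the wall surfaces; the report contains
   per-element Jacobian ratios, isosurface fitting-error statistics and a
   success flag (mean error < voxel diagonal AND mean Jacobian ratio
   ≥ 0.33).

A synthetic phantom generator (`cardiomesh.phantom`) produces analytic
truncated-ellipsoid masks with known ground truth (rigid pose, affine /
radial / sinusoidal deformations, sparsified slice stacks, slice-shift
artifacts, seeded random cohorts) for end-to-end testing.

## CLI

```sh
cardiomesh --input mask.nii.gz --topology auto --lod 3 \
    --output-ex fitted --output-vtk fitted.vtk --report report.json
```

Flags: `--topology {auto,lv,biv}`, `--resolution R,C,L` (radial,
circumferential, longitudinal element counts; defaults 1,12,6 for LV and
2,9,8 for BiV), `--apex {collapsed,hole}`, `--lod 1..5`,
`--truncate-base/--no-truncate-base`, `--basal-offset MM`,
`--no-linearize`, `--seed N`, `--verbose`. A JSON `--config` file mirrors
all flags (flags win).

Python API:

```python
from cardiomesh import PipelineConfig, run_pipeline
from cardiomesh.shape import load_mask

result = run_pipeline(load_mask("mask.nii.gz"), PipelineConfig(lod=3))
print(result.report.fitting_error_mean, result.report.success)
```

Meshes are written as EX (`.exnode`/`.exelem`, minimal cmGui dialect with
8 DOF components per node per coordinate — see
`cardiomesh/exformat.py` for the exact layout) and as legacy-ASCII VTK
(per-element subdivided hexahedra) for visualization.

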