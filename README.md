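# fmindreg

Non-rigid **multi-modal 3D image registration** with foveated
self-similarity descriptors. The package is aimed at medical-imaging
researchers who need to align volumes whose intensities are related by an
arbitrary — possibly non-monotone — mapping (T1/T2/PD MR, CT–MR, CT–PET),
where intensity-based metrics fail and a structural representation is
needed.

## Method

Every voxel x of a volume I is described by a short vector over a search
window R (the 3D six-neighborhood by default):

```
FMIND(I, x, r) = (1/n) exp( − d_FOV(I, x, x+r) / V_FOV(I, x) ),   r ∈ R
```

where `d_FOV` is the squared distance between *foveated* patches — each
patch value is the image blurred by an anisotropic, radially elongated
Gaussian kernel whose blur grows with distance from the fixation point,
mimicking retinal acuity fall-off — `V_FOV` is the mean foveated distance
over the 5×5 patch support (a local contrast scale), and n normalizes the
per-voxel maximum to 1. Two volumes are compared voxelwise by the mean sum
of absolute differences of their descriptors, `SAD_F ∈ [0, 1)`.

The transform is a cubic B-spline free-form deformation. Its control
vertices are first **partitioned**: a vertex whose surrounding patch
(radius `R_LP = 7`) has more than a fraction ε = 0.9 of voxels with
similarity `1 − SAD_F > δ = 0.8` is frozen (static); the rest are dynamic.
Displacements of the dynamic vertices are found by minimizing the
first-order MRF energy

```
E(l) = (1/|G|) Σ_p [ V_p(l_p) + λ Σ_{q ∈ N(p)} ‖T_lp − T_lq‖₁ ],   λ = 0.01
```

over discrete displacement labels with α-expansion (max-flow) moves, with
a label quantum that halves each outer iteration. Accuracy against a known
ground-truth field is reported as the target registration error

```
TRE = (1/N) Σ_i ‖ T_L(x_i) − T_D(x_i) ‖₂
```

over landmark positions x_i, in voxels (or mm).

A synthetic module generates complete, fully reproducible test cases: a
structured phantom, a second "modality" via nonlinear intensity remapping
plus noise, a smooth ground-truth warp built from Gaussian radial basis
functions, and automatically picked high-gradient landmarks.

## Worked example

```python
import numpy as np
from fmindreg import (SyntheticSpec, make_registration_case, register,
                      evaluate_tre, DeformationField)

case = make_registration_case(SyntheticSpec(seed=1), n_landmarks=30)  # 64³
zero = DeformationField(displacements=np.zeros(case.reference.shape + (3,)))
before = evaluate_tre(case.landmarks, case.true_field, zero)
result = register(case.reference, case.float_img)
after = evaluate_tre(case.landmarks, case.true_field, result.field)
print(f"TRE before: {before.mean:.3f} voxels")
print(f"TRE after:  {after.mean:.3f} voxels")
print(f"dynamic vertices: {result.partition.n_dynamic}/{result.grid.n_vertices}")
```

prints

```
TRE before: 1.843 voxels
TRE after:  0.579 voxels
dynamic vertices: 1312/1331
```

i.e. a 64³ multi-modal pair deformed by a 4-voxel-amplitude RBF warp is
brought from ~1.8 voxels mean landmark error to ~0.6 voxels; nearly all
control vertices are dynamic because the synthetic warp covers most of the
volume, while an identical pair would freeze all of them and return the
identity.

The same pipeline is scriptable from the shell:

```sh
fmindreg simulate --out case/ --seed 1
fmindreg register --ref case/ref.nii.gz --flt case/flt.nii.gz --out reg/
fmindreg tre --landmarks case/landmarks.csv --true case/tl_field.nii.gz \
             --est reg/field.nii.gz
```

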