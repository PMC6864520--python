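"""Free-form deformation: cubic B-spline control grid, densification, warping.

Displacements live on a coarse vertex lattice; the dense per-voxel field is
the cubic B-spline tensor-product interpolation of the vertex displacements.
Conventions: 0-based voxel indices, displacements in voxels, backward (pull)
warping with trilinear interpolation and nearest-edge clamping outside the
domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, ShapeMismatchError


@dataclass
class ControlGrid:
    """Cubic B-spline FFD vertex lattice covering an image domain.

    Vertex ``(i, j, k)`` sits at voxel position ``(i - 1) * spacing`` (one
    margin ring before the image origin, and two rings past its far edge,
    as cubic B-spline support requires).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    displacements: np.ndarray  # dims + (3,)
    image_shape: tuple[int, int, int]

    @property
    def n_vertices(self) -> int:
        return int(np.prod(self.dims))

    def vertex_position(self, index) -> np.ndarray:
        """Voxel-space position of a vertex (may lie outside the image)."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass
class DeformationField:
    """Dense per-voxel displacement field, in voxels."""

    displacements: np.ndarray  # shape + (3,)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]


def make_control_grid(image_shape, spacing=8) -> ControlGrid:
    """Zero-initialized control grid with ceil(shape/spacing) + 3 vertices per axis."""
    image_shape = tuple(int(s) for s in image_shape)
    if len(image_shape) != 3 or any(s < 1 for s in image_shape):
        raise InvalidArgumentError(f"invalid image shape {image_shape}")
    if np.isscalar(spacing):
        spacing = (spacing,) * 3
    spacing = tuple(float(s) for s in spacing)
    if any(s < 2 for s in spacing):
        raise InvalidArgumentError(f"grid spacing must be >= 2 voxels, got {spacing}")
    dims = tuple(int(np.ceil(s / sp)) + 3 for s, sp in zip(image_shape, spacing))
    origin = tuple(-sp for sp in spacing)
    disp = np.zeros(dims + (3,))
    return ControlGrid(dims=dims, spacing=spacing, origin=origin, displacements=disp,
                       image_shape=image_shape)


def bspline3_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at local coordinate t in [0, 1).

    Returns an array of shape ``t.shape + (4,)``.
    """
    t = np.asarray(t, dtype=float)
    w = np.empty(t.shape + (4,))
    w[..., 0] = (1 - t) ** 3 / 6.0
    w[..., 1] = (3 * t**3 - 6 * t**2 + 4) / 6.0
    w[..., 2] = (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6.0
    w[..., 3] = t**3 / 6.0
    return w


def _axis_support(n_vox: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel base vertex index and 4 basis weights along one axis.

    A voxel at coordinate x is influenced by vertices ``i0 .. i0 + 3`` with
    ``i0 = floor(x / spacing)`` (in our lattice indexing with one margin
    ring) and weights B_0..B_3 at ``t = x/spacing - floor(x/spacing)``.
    """
    x = np.arange(n_vox, dtype=float)
    s = x / spacing
    i0 = np.floor(s).astype(int)
    t = s - i0
    return i0, bspline3_weights(t)


def axis_weight_matrix(n_vox: int, spacing: float, n_vertices: int) -> np.ndarray:
    """Dense (n_vox, n_vertices) basis-weight matrix along one axis."""
    i0, w = _axis_support(n_vox, spacing)
    W = np.zeros((n_vox, n_vertices))
    rows = np.arange(n_vox)
    for a in range(4):
        W[rows, i0 + a] = w[:, a]
    return W


def densify(grid: ControlGrid) -> DeformationField:
    """Interpolate vertex displacements to a dense field over the image."""
    shape = grid.image_shape
    idx, wts = zip(*(_axis_support(n, sp) for n, sp in zip(shape, grid.spacing)))
    out = np.zeros(shape + (3,))
    disp = grid.displacements
    for a in range(4):
        wa = wts[0][:, a][:, None, None, None]
        ia = idx[0] + a
        for b in range(4):
            wb = wts[1][:, b][None, :, None, None]
            ib = idx[1] + b
            wab = wa * wb
            for c in range(4):
                wc = wts[2][:, c][None, None, :, None]
                ic = idx[2] + c
                out += wab * wc * disp[np.ix_(ia, ib, ic)]
    return DeformationField(displacements=out)


def warp(volume: np.ndarray, field: DeformationField) -> np.ndarray:
    """Backward-warp a volume: output(x) = volume(x + field(x)).

    Trilinear interpolation; samples outside the domain clamp to the
    nearest edge voxel.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != field.shape:
        raise ShapeMismatchError(
            f"volume shape {volume.shape} != field shape {field.shape}"
        )
    coords = np.indices(volume.shape, dtype=float)
    coords += np.moveaxis(field.displacements, 3, 0)
    return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


def warp_channels(stack: np.ndarray, field_disp: np.ndarray) -> np.ndarray:
    """Backward-warp each channel of a (..., C) array by a displacement array."""
    coords = np.indices(stack.shape[:3], dtype=float)
    coords += np.moveaxis(field_disp, 3, 0)
    out = np.empty_like(stack)
    for c in range(stack.shape[3]):
        out[..., c] = ndimage.map_coordinates(stack[..., c], coords, order=1, mode="nearest")
    return out


def sample_displacements(field: DeformationField, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample the displacement vectors at (possibly fractional) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = pts.T  # (3, N)
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            field.displacements[..., c], coords, order=1, mode="nearest"
        )
    return out


def invert_displacement(field: DeformationField, iterations: int = 30) -> DeformationField:
    """Fixed-point inverse of a displacement field.

    Finds D with D(y) = -T(y + D(y)), so that warping by D undoes (to
    interpolation accuracy) a warp by T.  Converges for moderately smooth
    fields (displacement Jacobian spectral radius < 1).
    """
    disp = field.displacements
    inv = np.zeros_like(disp)
    for _ in range(iterations):
        inv = -warp_channels(disp, inv)
    return DeformationField(displacements=inv)


def compose_displacements(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """Displacement of warp-by-inner followed by warp-by-outer.

    ``T(x) = inner(x) + outer(x + inner(x))`` so that
    ``warp(v, T) == warp(warp(v, outer), inner)`` up to interpolation.
    """
    moved = warp_channels(outer.displacements, inner.displacements)
    return DeformationField(displacements=inner.displacements + moved)


def count_field_variables(image_shape) -> int:
    """Number of unknowns of a dense per-voxel 3D displacement field."""
    image_shape = tuple(int(s) for s in image_shape)
    if any(s < 1 for s in image_shape):
        raise InvalidArgumentError(f"invalid image shape {image_shape}")
    return 3 * int(np.prod(image_shape))
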