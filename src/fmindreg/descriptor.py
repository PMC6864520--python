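"""Per-voxel foveated self-similarity descriptors and their SAD metric.

The descriptor of a voxel is a short vector, one channel per search-window
offset ``r``: ``exp(-d_FOV(x, x+r) / V_FOV(x))`` normalized so the largest
channel equals 1 at every voxel.  ``d_FOV`` is the squared distance between
foveated patches and ``V_FOV`` the mean foveated distance over the patch
support, which adapts the exponential decay to local contrast.  Because the
channels encode local *structure* rather than raw intensity, descriptors of
the same anatomy in two modalities are comparable voxel-by-voxel via the
mean sum of absolute differences (SAD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IncompatibleDescriptorsError, InvalidArgumentError
from .foveation import (
    FoveationOperator,
    blurred_stack,
    build_foveation_operator,
    default_variance_floor,
    _inplane_axes,
)

#: Default search window: the 3D six-neighborhood.
SIX_NEIGHBORHOOD: tuple[tuple[int, int, int], ...] = (
    (-1, 0, 0),
    (1, 0, 0),
    (0, -1, 0),
    (0, 1, 0),
    (0, 0, -1),
    (0, 0, 1),
)


@dataclass
class DescriptorField:
    """Dense descriptor volume: one channel per search offset.

    ``values`` has shape ``volume_shape + (|R|,)`` with every channel in
    (0, 1] and a per-voxel channel maximum of exactly 1.
    """

    values: np.ndarray
    search_offsets: tuple[tuple[int, int, int], ...]
    variance_map: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.values.shape[3]


@dataclass
class SimilarityMap:
    """Voxelwise mean SAD between two descriptor fields; values in [0, 1)."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def rescale_intensity(image: np.ndarray) -> np.ndarray:
    """Affinely map intensities to [0, 1]; constant images map to 0."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _shifted(stack_i: np.ndarray, pad, offset, shape) -> np.ndarray:
    sl = tuple(
        slice(p + o, p + o + s) for p, o, s in zip(pad, offset, shape)
    )
    return stack_i[sl]


def compute_fmind(
    image: np.ndarray,
    operator: FoveationOperator | None = None,
    search_offsets=SIX_NEIGHBORHOOD,
    plane_axis: int = 2,
    rescale: bool = True,
) -> DescriptorField:
    """Compute the foveated self-similarity descriptor field of a volume.

    Parameters
    ----------
    image : 3D array
        Scalar volume; by default intensities are rescaled to [0, 1] first
        so the variance floor and downstream thresholds are comparable
        across modalities.
    operator : FoveationOperator, optional
        Defaults to the 5x5, rho=2, theta=0 operator.
    search_offsets : sequence of 3-int tuples
        Nonzero, distinct offsets of the search window ``R``.
    plane_axis : int
        Axis orthogonal to the (2D) foveated patch plane.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise InvalidArgumentError(f"expected a 3D volume, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise InvalidArgumentError("image contains non-finite values")
    offsets = tuple(tuple(int(c) for c in r) for r in search_offsets)
    if len(offsets) == 0:
        raise InvalidArgumentError("search_offsets must be non-empty")
    if len(set(offsets)) != len(offsets) or any(all(c == 0 for c in r) for r in offsets):
        raise InvalidArgumentError("search_offsets must be distinct and nonzero")
    if operator is None:
        operator = build_foveation_operator()
    if rescale:
        image = rescale_intensity(image)
    floor = default_variance_floor(image)

    # pad needed for search offsets on top of in-plane patch offsets
    extra = [0, 0, 0]
    for r in offsets:
        for a in range(3):
            extra[a] = max(extra[a], abs(r[a]))
    stack, pad = blurred_stack(image, operator, plane_axis, tuple(extra))
    shape = image.shape
    a0, a1 = _inplane_axes(plane_axis)
    patch_offsets = operator.offsets  # 2D (in-plane) offsets, row-major

    def dist_field(offset3) -> np.ndarray:
        """d_FOV(x, x + offset3) for every voxel x."""
        d = np.zeros(shape)
        for i, (u0, u1) in enumerate(patch_offsets):
            u3 = [0, 0, 0]
            u3[a0], u3[a1] = u0, u1
            base = _shifted(stack[i], pad, u3, shape)
            moved = _shifted(stack[i], pad, tuple(o + u for o, u in zip(offset3, u3)), shape)
            d += (base - moved) ** 2
        return d

    # variance: mean foveated distance over the (in-plane) patch support
    var = np.zeros(shape)
    for (m0, m1) in patch_offsets:
        if (m0, m1) == (0, 0):
            continue
        m3 = [0, 0, 0]
        m3[a0], m3[a1] = m0, m1
        var += dist_field(tuple(m3))
    var /= len(patch_offsets)
    var = np.maximum(var, floor)

    channels = np.empty(shape + (len(offsets),))
    for j, r in enumerate(offsets):
        # cap the decay so exp() stays strictly positive in float64 even
        # where the variance floor makes the ratio huge
        channels[..., j] = np.exp(-np.minimum(dist_field(r) / var, 700.0))
    channels /= channels.max(axis=3, keepdims=True)
    return DescriptorField(values=channels, search_offsets=offsets, variance_map=var)


def similarity_sad(desc_a: DescriptorField, desc_b: DescriptorField) -> SimilarityMap:
    """Voxelwise mean absolute difference between two descriptor fields."""
    if desc_a.shape != desc_b.shape or desc_a.search_offsets != desc_b.search_offsets:
        raise IncompatibleDescriptorsError(
            "descriptor fields differ in shape or search offsets"
        )
    sad = np.mean(np.abs(desc_a.values - desc_b.values), axis=3)
    return SimilarityMap(values=sad)


def sad_between(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """Mean |a - b| over the channel (last) axis for raw channel arrays."""
    return np.mean(np.abs(values_a - values_b), axis=-1)
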