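"""Descriptor-driven spatial constraint: static/dynamic vertex partition.

For each control vertex a cubic patch of radius ``r_lp`` around its voxel
position is inspected: voxels whose descriptor similarity ``1 - SAD``
exceeds the threshold ``delta`` are counted, and the vertex is declared
*static* (clamped to zero displacement) when the counted fraction exceeds
the static factor ``epsilon``.  Dynamic vertices are everything else; their
B-spline support forms the automatically generated registration mask, so no
manual mask or segmentation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptor import SimilarityMap
from .errors import InvalidArgumentError
from .transform import ControlGrid


@dataclass
class VertexPartition:
    """Disjoint split of the control-vertex set into static and dynamic."""

    static_ids: np.ndarray  # sorted flat indices
    dynamic_ids: np.ndarray
    grid_dims: tuple[int, int, int]
    r_lp: int
    delta: float
    epsilon: float

    @property
    def n_static(self) -> int:
        return len(self.static_ids)

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic_ids)

    def summary(self) -> dict:
        n = int(np.prod(self.grid_dims))
        return {
            "n_vertices": n,
            "n_static": self.n_static,
            "n_dynamic": self.n_dynamic,
            "dynamic_fraction": self.n_dynamic / n,
            "r_lp": self.r_lp,
            "delta": self.delta,
            "epsilon": self.epsilon,
        }


def partition_vertices(
    similarity: SimilarityMap,
    grid: ControlGrid,
    r_lp: int = 7,
    delta: float = 0.8,
    epsilon: float = 0.9,
) -> VertexPartition:
    """Split the vertex set by the local-patch similarity ratio test.

    A vertex is static iff, within the clipped cube of radius ``r_lp``
    centred on its (clamped-to-volume) voxel position, the fraction of
    voxels with ``1 - SAD > delta`` exceeds ``epsilon``.  Both inequalities
    are strict.  Margin vertices outside the volume are clamped to the
    nearest in-volume voxel so every vertex sees a non-empty patch.
    """
    if not (0.0 <= delta <= 1.0) or not (0.0 <= epsilon <= 1.0):
        raise InvalidArgumentError("delta and epsilon must lie in [0, 1]")
    if r_lp < 1:
        raise InvalidArgumentError(f"r_lp must be >= 1, got {r_lp}")
    sim = similarity.values
    shape = sim.shape
    good = (1.0 - sim) > delta
    static, dynamic = [], []
    flat = 0
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                pos = grid.vertex_position((i, j, k))
                center = [
                    int(np.clip(round(p), 0, s - 1)) for p, s in zip(pos, shape)
                ]
                box = tuple(
                    slice(max(0, c - r_lp), min(s, c + r_lp + 1))
                    for c, s in zip(center, shape)
                )
                patch = good[box]
                con = int(patch.sum())
                if con / patch.size > epsilon:
                    static.append(flat)
                else:
                    dynamic.append(flat)
                flat += 1
    return VertexPartition(
        static_ids=np.asarray(static, dtype=int),
        dynamic_ids=np.asarray(dynamic, dtype=int),
        grid_dims=grid.dims,
        r_lp=int(r_lp),
        delta=float(delta),
        epsilon=float(epsilon),
    )


def mask_from_partition(
    partition: VertexPartition, image_shape, grid: ControlGrid
) -> np.ndarray:
    """Binary volume: 1 where any dynamic vertex's B-spline support reaches.

    Vertex ``j`` (per axis) influences voxels x with
    ``floor(x / spacing) in {j-3 .. j}``, i.e. x in [(j-3)*s, (j+1)*s).
    """
    mask = np.zeros(tuple(int(s) for s in image_shape), dtype=np.uint8)
    dims = partition.grid_dims
    for flat in partition.dynamic_ids:
        idx = np.unravel_index(flat, dims)
        box = []
        for j, sp, n in zip(idx, grid.spacing, image_shape):
            lo = int(np.ceil((j - 3) * sp))
            hi = int(np.ceil((j + 1) * sp))  # exclusive
            box.append(slice(max(0, lo), min(int(n), hi)))
        if all(b.stop > b.start for b in box):
            mask[tuple(box)] = 1
    return mask
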