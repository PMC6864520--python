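"""First-order MRF registration energy over discrete displacement labels.

The energy is

    E(l) = (1/|G|) * sum_p [ V_p(l_p) + lambda * sum_{q in N(p)} |T_lp - T_lq|_1 ]

where ``G`` is the FFD control-vertex set, ``V_p`` the basis-weighted
descriptor dissimilarity over the vertex's support for the candidate
displacement, and the pairwise term the L1 distance between neighboring
displacements (each undirected lattice edge appears in both vertices'
neighbor sums).  Static vertices are clamped to the zero label; dynamic
ones are optimized by alpha-expansion (the L1 pairwise cost is a metric, so
expansion moves apply and every accepted move lowers the energy) with an
ICM fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .errors import InvalidArgumentError, ShapeMismatchError
from .descriptor import DescriptorField, sad_between
from .transform import ControlGrid, axis_weight_matrix, warp_channels

_CAP_SCALE = 10**9  # float costs -> integer capacities for max-flow


@dataclass(frozen=True)
class LabelSpace:
    """Ordered candidate displacements; label 0 is the zero displacement."""

    labels: np.ndarray  # (L, 3) float, voxels
    quantum: float
    includes_zero: bool = True

    def __len__(self) -> int:
        return self.labels.shape[0]


def build_label_space(max_steps: int, quantum: float) -> LabelSpace:
    """Axis-aligned displacement sampling: {0} plus +-k*quantum per axis.

    Yields ``6 * max_steps + 1`` labels.
    """
    if max_steps < 1:
        raise InvalidArgumentError(f"max_steps must be >= 1, got {max_steps}")
    if not quantum > 0:
        raise InvalidArgumentError(f"quantum must be positive, got {quantum}")
    labels = [np.zeros(3)]
    for axis in range(3):
        for k in range(1, max_steps + 1):
            for sign in (+1, -1):
                v = np.zeros(3)
                v[axis] = sign * k * quantum
                labels.append(v)
    return LabelSpace(labels=np.array(labels), quantum=float(quantum))


def smooth_cost(label_a, label_b) -> float:
    """L1 distance between two candidate displacement vectors."""
    return float(np.abs(np.asarray(label_a, dtype=float) - np.asarray(label_b, dtype=float)).sum())


# ---------------------------------------------------------------------------
# data costs


def similarity_volumes(
    desc_ref: DescriptorField,
    desc_float: DescriptorField,
    space: LabelSpace,
    current_disp: np.ndarray | None = None,
) -> np.ndarray:
    """Per-label SAD volumes between the reference descriptors and the float
    descriptors resampled through (current field +) each candidate
    displacement.  Shape ``(L,) + volume_shape``."""
    shape = desc_ref.shape
    if current_disp is None:
        current_disp = np.zeros(shape + (3,))
    out = np.empty((len(space),) + shape)
    for li, d in enumerate(space.labels):
        disp = current_disp + d
        moved = warp_channels(desc_float.values, disp)
        out[li] = sad_between(desc_ref.values, moved)
    return out


def vertex_cost_tensor(
    sim_volume: np.ndarray, grid: ControlGrid, normalize: bool = False
) -> np.ndarray:
    """Basis-weighted sum of a similarity volume over every vertex support.

    Separable reduction: cost(p) = sum_x w_p(x) * sim(x) with w_p the
    tensor-product cubic B-spline weight of vertex p at voxel x, clipped to
    the image — the discretized integral of the dissimilarity over the
    vertex's influence region, which is the scale the default smoothness
    weight (0.01) is calibrated against.  ``normalize=True`` divides by the
    total weight, giving a per-vertex weighted *mean* instead.  Returns an
    array of shape ``grid.dims``.
    """
    Ws = [
        axis_weight_matrix(n, sp, d)
        for n, sp, d in zip(sim_volume.shape, grid.spacing, grid.dims)
    ]
    num = np.einsum("xi,xyz->iyz", Ws[0], sim_volume)
    num = np.einsum("yj,iyz->ijz", Ws[1], num)
    num = np.einsum("zk,ijz->ijk", Ws[2], num)
    if not normalize:
        return num
    sums = [W.sum(axis=0) for W in Ws]
    den = sums[0][:, None, None] * sums[1][None, :, None] * sums[2][None, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def data_cost(
    desc_ref: DescriptorField,
    desc_float: DescriptorField,
    grid: ControlGrid,
    vertex,
    label,
    current_disp: np.ndarray | None = None,
    normalize: bool = False,
) -> float:
    """Data term V_p of one vertex for one candidate displacement."""
    if desc_ref.shape != desc_float.shape:
        raise ShapeMismatchError("descriptor fields differ in shape")
    space = LabelSpace(labels=np.asarray(label, dtype=float)[None, :], quantum=1.0,
                       includes_zero=False)
    sim = similarity_volumes(desc_ref, desc_float, space, current_disp)[0]
    return float(vertex_cost_tensor(sim, grid, normalize)[tuple(vertex)])


# ---------------------------------------------------------------------------
# energy model


def _lattice_edges(dims) -> np.ndarray:
    """Undirected 6-neighborhood edges between flat vertex indices."""
    idx = np.arange(int(np.prod(dims))).reshape(dims)
    edges = []
    for axis in range(3):
        a = np.moveaxis(idx, axis, 0)
        edges.append(np.stack([a[:-1].ravel(), a[1:].ravel()], axis=1))
    return np.concatenate(edges, axis=0)


@dataclass
class EnergyModel:
    """Data costs for the dynamic vertices plus lattice structure.

    ``data_costs[i, l]`` is V_p(l) for the i-th dynamic vertex;
    ``static_zero_cost`` is the (constant) sum of V_p(0) over the static
    vertices, kept so reported energies cover the whole vertex set.
    """

    grid_dims: tuple[int, int, int]
    dynamic_ids: np.ndarray  # sorted flat indices into the vertex lattice
    data_costs: np.ndarray  # (n_dynamic, L)
    smooth_weight: float = 0.01
    static_zero_cost: float = 0.0
    # derived
    edges_dd: np.ndarray = field(init=False)  # (E1, 2) rows into dynamic order
    n_static_links: np.ndarray = field(init=False)  # per dynamic vertex

    def __post_init__(self):
        self.dynamic_ids = np.asarray(self.dynamic_ids, dtype=int)
        self.data_costs = np.asarray(self.data_costs, dtype=float)
        if np.any(self.data_costs < 0) or not np.all(np.isfinite(self.data_costs)):
            raise InvalidArgumentError("data costs must be finite and non-negative")
        if self.smooth_weight < 0:
            raise InvalidArgumentError("smooth_weight must be non-negative")
        n_total = int(np.prod(self.grid_dims))
        pos = np.full(n_total, -1, dtype=int)
        pos[self.dynamic_ids] = np.arange(len(self.dynamic_ids))
        edges = _lattice_edges(self.grid_dims)
        a, b = pos[edges[:, 0]], pos[edges[:, 1]]
        both = (a >= 0) & (b >= 0)
        self.edges_dd = np.stack([a[both], b[both]], axis=1)
        self.n_static_links = np.zeros(len(self.dynamic_ids), dtype=int)
        one_dyn = (a >= 0) ^ (b >= 0)
        dyn_side = np.where(a[one_dyn] >= 0, a[one_dyn], b[one_dyn])
        np.add.at(self.n_static_links, dyn_side, 1)

    @property
    def normalizer(self) -> float:
        return 1.0 / int(np.prod(self.grid_dims))

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic_ids)


def mrf_energy(model: EnergyModel, space: LabelSpace, labels: np.ndarray) -> float:
    """Evaluate the full MRF energy for a labeling of the dynamic vertices.

    Every undirected lattice edge contributes twice (once per endpoint's
    neighbor sum); static vertices sit at the zero label.
    """
    labels = np.asarray(labels, dtype=int)
    disp = space.labels[labels]  # (n_dyn, 3)
    e = model.static_zero_cost
    if model.n_dynamic:
        e += model.data_costs[np.arange(model.n_dynamic), labels].sum()
        lam = model.smooth_weight
        if model.edges_dd.size:
            diff = np.abs(disp[model.edges_dd[:, 0]] - disp[model.edges_dd[:, 1]]).sum(axis=1)
            e += 2.0 * lam * diff.sum()
        e += 2.0 * lam * (model.n_static_links * np.abs(disp).sum(axis=1)).sum()
    return float(e * model.normalizer)


@dataclass
class OptimizeResult:
    labels: np.ndarray
    energy: float
    trace: list
    n_moves: int
    method: str


def _expansion_move(model, space, labels, alpha, pair_w):
    """One alpha-expansion move; returns the proposed labeling.

    Binary variables: 0 = keep the current label, 1 = switch to alpha.
    Built as a min-cut on an s-t graph (source side = switch) and solved
    with integer-capacity max-flow; the pairwise L1 term is a metric so
    every term is submodular.
    """
    n = model.n_dynamic
    L = space.labels
    disp = L[labels]
    d_alpha = L[alpha]

    u0 = model.data_costs[np.arange(n), labels].copy()  # keep current label
    u1 = model.data_costs[:, alpha].copy()  # switch to alpha
    # static neighbors (fixed zero displacement)
    sl = model.n_static_links
    u0 += pair_w * sl * np.abs(disp).sum(axis=1)
    u1 += pair_w * sl * np.abs(d_alpha).sum()

    # pairwise decomposition (x = 1 means "switch", source side):
    #   theta(x_p, x_q) = t00 + (t10 - t00)[x_p=1] - t10 [x_q=1]
    #                     + (t01 + t10 - t00) [x_p=0][x_q=1]
    # the last coefficient is >= 0 because the L1 cost is a metric.
    rows, cols, caps = [], [], []
    for p, q in model.edges_dd:
        t00 = pair_w * np.abs(disp[p] - disp[q]).sum()
        t01 = pair_w * np.abs(disp[p] - d_alpha).sum()
        t10 = pair_w * np.abs(d_alpha - disp[q]).sum()
        u1[p] += t10 - t00
        u1[q] -= t10
        c = t01 + t10 - t00
        if c > 1e-15:
            # cut when q is on the source side (switch) and p on the sink side
            rows.append(q)
            cols.append(p)
            caps.append(c)

    # t-links: edge s->p is cut when x_p = 0 (charge for keeping), edge
    # p->t when x_p = 1 (charge for switching); only the difference matters,
    # the dropped constant is irrelevant since the true energy is recomputed.
    diff = u1 - u0
    s, t = n, n + 1
    for p in range(n):
        if diff[p] < 0:
            rows.append(s)
            cols.append(p)
            caps.append(-diff[p])
        elif diff[p] > 0:
            rows.append(p)
            cols.append(t)
            caps.append(diff[p])
    if not caps:
        return labels
    cap_int = np.maximum(np.rint(np.asarray(caps) * _CAP_SCALE).astype(np.int64), 0)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    graph = coo_matrix((cap_int, (rows, cols)), shape=(n + 2, n + 2)).tocsr()
    graph.sum_duplicates()
    res = maximum_flow(graph, s, t)
    flow = res.flow
    # residual graph: forward residual cap - flow, plus reverse residual = flow
    residual = graph - flow
    residual = residual.maximum(csr_matrix((n + 2, n + 2), dtype=np.int64))
    reachable = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    new_labels = labels.copy()
    switch = np.zeros(n, dtype=bool)
    for node in reachable:
        if node < n:
            switch[node] = True
    new_labels[switch] = alpha
    return new_labels


def optimize(
    model: EnergyModel,
    space: LabelSpace,
    max_cycles: int = 3,
    method: str = "expansion",
) -> OptimizeResult:
    """Minimize the MRF energy over the dynamic vertices.

    Visits labels in order of increasing L1 magnitude (then index) and
    accepts a move only if it strictly lowers the full energy, so the
    recorded trace is non-increasing and ties resolve toward the identity.
    """
    if method not in ("expansion", "icm"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    n = model.n_dynamic
    labels = np.zeros(n, dtype=int)
    energy = mrf_energy(model, space, labels)
    trace = [energy]
    if n == 0:
        return OptimizeResult(labels=labels, energy=energy, trace=trace, n_moves=0, method=method)
    order = sorted(
        range(len(space)), key=lambda l: (np.abs(space.labels[l]).sum(), l)
    )
    pair_w = 2.0 * model.smooth_weight  # each undirected edge counted twice
    n_moves = 0
    for _ in range(max_cycles):
        improved = False
        if method == "expansion":
            for alpha in order:
                proposal = _expansion_move(model, space, labels, alpha, pair_w)
                if np.array_equal(proposal, labels):
                    continue
                e_new = mrf_energy(model, space, proposal)
                if e_new < energy - 1e-14:
                    labels, energy = proposal, e_new
                    trace.append(energy)
                    n_moves += 1
                    improved = True
        else:  # ICM
            for p in range(n):
                best_l, best_e = labels[p], energy
                for l in order:
                    if l == labels[p]:
                        continue
                    cand = labels.copy()
                    cand[p] = l
                    e_new = mrf_energy(model, space, cand)
                    if e_new < best_e - 1e-14:
                        best_l, best_e = l, e_new
                if best_l != labels[p]:
                    labels = labels.copy()
                    labels[p] = best_l
                    energy = best_e
                    trace.append(energy)
                    n_moves += 1
                    improved = True
        if not improved:
            break
    return OptimizeResult(labels=labels, energy=energy, trace=trace, n_moves=n_moves, method=method)
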