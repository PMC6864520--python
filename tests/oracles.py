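"""Independent naive transcriptions of the method's formulas.

Everything here is written directly from the defining equations with plain
padding, slicing and loops — no calls into the package's optimized paths —
so it can serve as the oracle the fast implementations are checked against.
"""

from __future__ import annotations

import numpy as np


def pad_reflect(image: np.ndarray, margin: int) -> np.ndarray:
    widths = []
    for s in image.shape:
        widths.append((margin, margin))
    mode_ok = all(s > 1 for s in image.shape)
    if mode_ok:
        return np.pad(image, widths, mode="reflect")
    out = image
    for ax, s in enumerate(image.shape):
        w = [(0, 0)] * image.ndim
        w[ax] = (margin, margin)
        out = np.pad(out, w, mode="reflect" if out.shape[ax] > 1 else "edge")
    return out


def scalar_patch_value(image, x, u, kernel, plane_axis=2, margin=16):
    """Literal double sum: patch value at offset u = sum_t I(x+u+t) k(t)."""
    a0, a1 = [a for a in range(3) if a != plane_axis]
    pad = pad_reflect(np.asarray(image, dtype=float), margin)
    kr = kernel.shape[0] // 2
    total = 0.0
    for t0 in range(-kr, kr + 1):
        for t1 in range(-kr, kr + 1):
            pos = [c + margin for c in x]
            pos[a0] += u[0] + t0
            pos[a1] += u[1] + t1
            total += pad[tuple(pos)] * kernel[t0 + kr, t1 + kr]
    return total


def scalar_foveated_patch(image, x, operator, plane_axis=2):
    h0, h1 = operator.patch_shape[0] // 2, operator.patch_shape[1] // 2
    out = np.empty(operator.patch_shape)
    for (u0, u1), kern in operator.kernels.items():
        out[u0 + h0, u1 + h1] = scalar_patch_value(image, x, (u0, u1), kern, plane_axis)
    return out


def scalar_foveated_distance(image, x1, x2, operator, plane_axis=2):
    p1 = scalar_foveated_patch(image, x1, operator, plane_axis)
    p2 = scalar_foveated_patch(image, x2, operator, plane_axis)
    return float(((p1 - p2) ** 2).sum())


def scalar_foveated_variance(image, x, operator, plane_axis=2):
    """Raw (unfloored) mean foveated distance over the patch support."""
    a0, a1 = [a for a in range(3) if a != plane_axis]
    total = 0.0
    for (m0, m1) in operator.offsets:
        x2 = list(x)
        x2[a0] += m0
        x2[a1] += m1
        total += scalar_foveated_distance(image, x, tuple(x2), operator, plane_axis)
    return total / len(operator.offsets)


# ---------------------------------------------------------------------------
# full-field semi-naive versions (shift-and-add over explicit pads; no scipy)


def field_patch_stacks(image, operator, plane_axis=2, margin=12):
    """Per-offset blurred volumes on a padded grid: stacks[i][y] is the
    image blurred by the kernel of offset S[i], at padded coordinate y;
    the patch value at fixation x and offset u is stacks[i][x + margin + u]."""
    image = np.asarray(image, dtype=float)
    a0, a1 = [a for a in range(3) if a != plane_axis]
    kr_max = max(k.shape[0] // 2 for k in operator.kernels.values())
    u_max = max(max(abs(u[0]), abs(u[1])) for u in operator.offsets)
    big = margin + kr_max + u_max
    pad = pad_reflect(image, big)
    inner = tuple(slice(big - margin, big - margin + s + 2 * margin) for s in image.shape)
    stacks = []
    for u in operator.offsets:
        kern = operator.kernels[u]
        kr = kern.shape[0] // 2
        acc = np.zeros(tuple(s + 2 * margin for s in image.shape))
        for t0 in range(-kr, kr + 1):
            for t1 in range(-kr, kr + 1):
                shift = [0, 0, 0]
                shift[a0] = t0
                shift[a1] = t1
                sl = tuple(
                    slice(big - margin + sh, big - margin + sh + s + 2 * margin)
                    for sh, s in zip(shift, image.shape)
                )
                acc += kern[t0 + kr, t1 + kr] * pad[sl]
        stacks.append(acc)
    return stacks, margin


def field_distance(image, operator, offset3, plane_axis=2):
    """d_FOV(x, x+offset3) for every voxel, by definition."""
    image = np.asarray(image, dtype=float)
    a0, a1 = [a for a in range(3) if a != plane_axis]
    stacks, m = field_patch_stacks(image, operator, plane_axis)
    d = np.zeros(image.shape)
    for i, (u0, u1) in enumerate(operator.offsets):
        u3 = [0, 0, 0]
        u3[a0], u3[a1] = u0, u1
        base = stacks[i][tuple(slice(m + o, m + o + s) for o, s in zip(u3, image.shape))]
        off = [o + u for o, u in zip(offset3, u3)]
        moved = stacks[i][tuple(slice(m + o, m + o + s) for o, s in zip(off, image.shape))]
        d += (base - moved) ** 2
    return d


def naive_fmind(image, operator, search_offsets, plane_axis=2, rescale=True):
    """Literal per-voxel evaluation of the descriptor definition."""
    image = np.asarray(image, dtype=float)
    if rescale:
        lo, hi = image.min(), image.max()
        image = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    rng = image.max() - image.min()
    floor = 1e-6 * rng * rng if rng > 0 else 1e-6
    a0, a1 = [a for a in range(3) if a != plane_axis]
    var = np.zeros(image.shape)
    for (m0, m1) in operator.offsets:
        m3 = [0, 0, 0]
        m3[a0], m3[a1] = m0, m1
        var += field_distance(image, operator, m3, plane_axis)
    var /= len(operator.offsets)
    var = np.maximum(var, floor)
    chans = np.empty(image.shape + (len(search_offsets),))
    for j, r in enumerate(search_offsets):
        d = field_distance(image, operator, r, plane_axis)
        chans[..., j] = np.exp(-np.minimum(d / var, 700.0))
    chans /= chans.max(axis=3, keepdims=True)
    return chans, var


def naive_sad(chans_a, chans_b):
    return np.mean(np.abs(chans_a - chans_b), axis=3)


# ---------------------------------------------------------------------------
# vertex partition: line-by-line transcription of the ratio test


def naive_partition(sad_values, grid_dims, spacing, origin, r_lp, delta, epsilon):
    """Triple-loop transcription; returns (static, dynamic) flat index lists."""
    shape = sad_values.shape
    static, dynamic = [], []
    flat = 0
    for i in range(grid_dims[0]):
        for j in range(grid_dims[1]):
            for k in range(grid_dims[2]):
                pos = [origin[a] + (i, j, k)[a] * spacing[a] for a in range(3)]
                center = [min(max(int(round(p)), 0), shape[a] - 1) for a, p in enumerate(pos)]
                con = 0
                size = 0
                for xx in range(max(0, center[0] - r_lp), min(shape[0], center[0] + r_lp + 1)):
                    for yy in range(max(0, center[1] - r_lp), min(shape[1], center[1] + r_lp + 1)):
                        for zz in range(max(0, center[2] - r_lp), min(shape[2], center[2] + r_lp + 1)):
                            size += 1
                            if 1.0 - sad_values[xx, yy, zz] > delta:
                                con += 1
                if con / size > epsilon:
                    static.append(flat)
                else:
                    dynamic.append(flat)
                flat += 1
    return static, dynamic


# ---------------------------------------------------------------------------
# MRF brute force


def brute_force_min_energy(model, space):
    """Exhaustive minimum of the MRF energy over all labelings (vectorized)."""
    L = len(space)
    n = model.n_dynamic
    lab = np.indices((L,) * n).reshape(n, -1)
    e = np.zeros(lab.shape[1])
    for p in range(n):
        e += model.data_costs[p, lab[p]]
    disp = space.labels
    pair = np.abs(disp[:, None, :] - disp[None, :, :]).sum(axis=2)
    for p, q in model.edges_dd:
        e += 2.0 * model.smooth_weight * pair[lab[p], lab[q]]
    e *= model.normalizer
    e += model.static_zero_cost * model.normalizer
    return float(e.min())


def naive_vertex_data_cost(sim_volume, grid, vertex, normalize=False):
    """Voxel-loop basis-weighted cost of one vertex."""

    def basis(t, a):
        if a == 0:
            return (1 - t) ** 3 / 6
        if a == 1:
            return (3 * t**3 - 6 * t**2 + 4) / 6
        if a == 2:
            return (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6
        return t**3 / 6

    total, wsum = 0.0, 0.0
    shape = sim_volume.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                w = 1.0
                ok = True
                for c, (j, sp) in zip((x, y, z), zip(vertex, grid.spacing)):
                    s = c / sp
                    i0 = int(np.floor(s))
                    a = j - i0
                    if a < 0 or a > 3:
                        ok = False
                        break
                    w *= basis(s - i0, a)
                if ok:
                    total += w * sim_volume[x, y, z]
                    wsum += w
    if normalize:
        return total / wsum if wsum > 0 else 0.0
    return total
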