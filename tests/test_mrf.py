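"""Label space, MRF energy terms, and discrete optimization."""

import numpy as np
import pytest

from fmindreg import (
    EnergyModel,
    build_label_space,
    compute_fmind,
    data_cost,
    make_control_grid,
    mrf_energy,
    optimize,
    similarity_sad,
    smooth_cost,
)
from fmindreg.errors import InvalidArgumentError
from fmindreg.mrf import similarity_volumes, vertex_cost_tensor

from oracles import brute_force_min_energy, naive_vertex_data_cost


class TestLabelSpace:
    def test_unit_space(self):
        space = build_label_space(1, 1.0)
        assert len(space) == 7
        assert np.all(space.labels[0] == 0)
        mags = np.linalg.norm(space.labels[1:], axis=1)
        assert np.allclose(sorted(mags), 1.0)

    def test_three_steps(self):
        space = build_label_space(3, 2.0)
        assert len(space) == 19
        assert np.linalg.norm(space.labels, axis=1).max() == pytest.approx(6.0)

    def test_zero_label_first(self):
        for steps, q in [(1, 0.5), (2, 1.0), (4, 2.0)]:
            space = build_label_space(steps, q)
            assert np.all(space.labels[0] == 0.0)

    @pytest.mark.parametrize("steps,quantum", [(0, 1.0), (1, 0.0), (1, -2.0)])
    def test_invalid(self, steps, quantum):
        with pytest.raises(InvalidArgumentError):
            build_label_space(steps, quantum)


class TestSmoothCost:
    def test_identical_zero(self):
        assert smooth_cost((1.0, 2.0, -1.0), (1.0, 2.0, -1.0)) == 0.0

    def test_l1_example(self):
        assert smooth_cost((1, 0, 0), (0, 2, 0)) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            assert smooth_cost(a, b) == pytest.approx(smooth_cost(b, a), abs=1e-12)
            assert smooth_cost(a, b) >= 0


class TestDataCost:
    def test_identical_images_zero_label(self, rng):
        img = rng.random((12, 12, 12))
        desc = compute_fmind(img)
        grid = make_control_grid(img.shape, 4)
        c = data_cost(desc, desc, grid, (2, 2, 2), (0.0, 0.0, 0.0))
        assert c == pytest.approx(0.0, abs=1e-10)

    def test_matches_naive_voxel_loop(self, rng):
        img_a = rng.random((8, 8, 8))
        img_b = rng.random((8, 8, 8))
        da, db = compute_fmind(img_a), compute_fmind(img_b)
        grid = make_control_grid(img_a.shape, 4)
        sim = similarity_sad(da, db).values
        for vertex in [(1, 1, 1), (2, 3, 2), (0, 0, 0)]:
            got = vertex_cost_tensor(sim, grid)[vertex]
            want = naive_vertex_data_cost(sim, grid, vertex)
            assert got == pytest.approx(want, abs=1e-10), vertex
            got_norm = vertex_cost_tensor(sim, grid, normalize=True)[vertex]
            want_norm = naive_vertex_data_cost(sim, grid, vertex, normalize=True)
            assert got_norm == pytest.approx(want_norm, abs=1e-10), vertex

    def test_true_shift_label_beats_zero(self):
        # a pre-shifted pair should prefer the correcting label
        rng = np.random.default_rng(8)
        base = rng.random((16, 16, 16))
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(base, 2.0)
        shifted = np.roll(base, -2, axis=0)  # shifted(x) = base(x + 2)
        d_ref = compute_fmind(base)
        d_flt = compute_fmind(shifted)
        grid = make_control_grid(base.shape, 4)
        vertex = (3, 3, 3)
        c_zero = data_cost(d_ref, d_flt, grid, vertex, (0.0, 0.0, 0.0))
        c_true = data_cost(d_ref, d_flt, grid, vertex, (-2.0, 0.0, 0.0))
        assert c_zero >= c_true


class TestOptimize:
    def _random_model(self, rng, lam=0.01, n_labels=7):
        data = rng.random((8, n_labels))
        return EnergyModel(
            grid_dims=(2, 2, 2),
            dynamic_ids=np.arange(8),
            data_costs=data,
            smooth_weight=lam,
        )

    def test_all_static_returns_identity(self):
        model = EnergyModel(
            grid_dims=(3, 3, 3),
            dynamic_ids=np.empty(0, dtype=int),
            data_costs=np.empty((0, 7)),
            smooth_weight=0.01,
            static_zero_cost=1.5,
        )
        space = build_label_space(1, 1.0)
        res = optimize(model, space)
        assert res.labels.size == 0
        assert res.energy == pytest.approx(1.5 / 27)
        assert len(res.trace) == 1

    def test_single_dynamic_vertex_exhaustive(self, rng):
        space = build_label_space(1, 1.0)
        for _ in range(10):
            data = rng.random((1, 7))
            model = EnergyModel(
                grid_dims=(2, 2, 2),
                dynamic_ids=np.array([3]),
                data_costs=data,
                smooth_weight=0.05,
            )
            res = optimize(model, space)
            best = min(
                mrf_energy(model, space, np.array([l])) for l in range(7)
            )
            assert res.energy == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("method", ["expansion", "icm"])
    def test_monotone_trace_and_near_optimal(self, rng, method):
        space = build_label_space(1, 1.0)
        for _ in range(5):
            model = self._random_model(rng)
            res = optimize(model, space, method=method)
            assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))
            best = brute_force_min_energy(model, space)
            assert res.energy <= 2.0 * best + 1e-12

    def test_zero_cost_fixed_point(self, rng):
        img = rng.random((12, 12, 12))
        desc = compute_fmind(img)
        grid = make_control_grid(img.shape, 4)
        space = build_label_space(1, 1.0)
        sims = similarity_volumes(desc, desc, space)
        data = np.stack(
            [vertex_cost_tensor(sims[li], grid).ravel() for li in range(len(space))],
            axis=1,
        )
        model = EnergyModel(
            grid_dims=grid.dims,
            dynamic_ids=np.arange(grid.n_vertices),
            data_costs=np.maximum(data, 0.0),
            smooth_weight=0.01,
        )
        res = optimize(model, space)
        assert np.all(res.labels == 0)
        assert res.energy == pytest.approx(0.0, abs=1e-9)

    def test_label_mirror_symmetry(self, rng):
        # swapping +d and -d labels (with costs swapped) mirrors the solution
        space = build_label_space(1, 1.0)
        data = rng.random((8, 7))
        # labels 1..6 come in (+,-) pairs per axis: swap each pair
        perm = np.array([0, 2, 1, 4, 3, 6, 5])
        model = EnergyModel(
            grid_dims=(2, 2, 2), dynamic_ids=np.arange(8), data_costs=data,
            smooth_weight=0.02,
        )
        mirrored = EnergyModel(
            grid_dims=(2, 2, 2), dynamic_ids=np.arange(8), data_costs=data[:, perm],
            smooth_weight=0.02,
        )
        r1 = optimize(model, space)
        r2 = optimize(mirrored, space)
        assert r1.energy == pytest.approx(r2.energy, abs=1e-10)
        assert np.array_equal(perm[r1.labels], r2.labels)

    def test_invalid_method(self, rng):
        model = self._random_model(rng)
        with pytest.raises(InvalidArgumentError):
            optimize(model, build_label_space(1, 1.0), method="anneal")
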