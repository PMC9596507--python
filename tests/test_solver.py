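"""Current-limited shim solver: oracle equivalence, bounds, dynamic schedules."""

import numpy as np
import pytest

from mcshim import (
    SHBasisSpec,
    ShimBasis,
    ShimProblem,
    compose_method,
    current_steps,
    generate_head,
    masked_std,
    remove_sh,
    sh_fields,
    solve_dynamic,
    solve_static,
)
from mcshim.errors import SolverError
from mcshim.phantom import PhantomSpec
from mcshim.solver import SliceShimSchedule

from conftest import flat_fieldmap


def make_basis(matrix: np.ndarray, bound: float = 1.0) -> ShimBasis:
    n = matrix.shape[1]
    return ShimBasis(
        matrix=matrix,
        bounds=np.full(n, bound),
        labels=tuple(f"ch{i}" for i in range(n)),
    )


def grid_refinement_oracle(
    A: np.ndarray, target: np.ndarray, bound: float, n_pts: int = 9, n_iter: int = 40
) -> np.ndarray:
    """Independent bounded minimizer of std(target + A c) by iterated grid zoom.

    The objective is convex in the currents, so recentring a dense grid on the
    incumbent and shrinking converges to the global box-constrained optimum.
    """
    n_ch = A.shape[1]
    center = np.zeros(n_ch)
    half = np.full(n_ch, bound)
    best = center.copy()
    for _ in range(n_iter):
        axes = [
            np.linspace(center[i] - half[i], center[i] + half[i], n_pts)
            for i in range(n_ch)
        ]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n_ch)
        grid = np.clip(grid, -bound, bound)
        obj = np.std(target[None, :] + grid @ A.T, axis=1)
        best = grid[np.argmin(obj)]
        center = best
        half = half * (2.0 / (n_pts - 1)) * 1.5  # keep the +-1 cell neighborhood
        if np.all(half < 1e-5 * bound):
            break
    return best


class TestSolveStatic:
    def test_zero_target_gives_zero_currents(self):
        rng = np.random.default_rng(0)
        basis = make_basis(rng.normal(size=(30, 3)))
        sol = solve_static(ShimProblem(basis=basis, target=np.zeros(30)))
        assert np.max(np.abs(sol.currents)) < 1e-8
        assert sol.residual_std == pytest.approx(0.0, abs=1e-10)

    def test_single_column_cancellation(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=40)
        basis = make_basis(col[:, None], bound=2.5)
        target = 1.7 * col
        sol = solve_static(ShimProblem(basis=basis, target=target))
        assert sol.currents[0] == pytest.approx(-1.7, abs=1e-6)
        assert sol.residual_std < 1e-8 * np.std(target)

    def test_all_zero_basis_returns_input_std(self):
        basis = make_basis(np.zeros((20, 2)))
        target = np.arange(20.0)
        sol = solve_static(ShimProblem(basis=basis, target=target))
        assert np.all(sol.currents == 0)
        assert sol.residual_std == pytest.approx(np.std(target))

    def test_infeasible_bounds_rejected(self):
        basis = make_basis(np.ones((5, 1)), bound=-1.0)
        with pytest.raises(SolverError):
            solve_static(ShimProblem(basis=basis, target=np.ones(5)))

    @pytest.mark.parametrize("n_ch,seed", [(2, 0), (3, 1), (3, 2), (4, 3), (4, 4)])
    def test_matches_grid_refinement_oracle(self, n_ch, seed):
        """Bounded solutions on small random problems equal exhaustive search."""
        rng = np.random.default_rng(seed)
        n_vox = 50
        A = rng.normal(size=(n_vox, n_ch))
        # scale the target so at least one bound is typically active
        coeff = rng.uniform(0.5, 1.8, n_ch) * rng.choice([-1, 1], n_ch)
        target = A @ coeff + 0.3 * rng.normal(size=n_vox)
        bound = 1.0
        sol = solve_static(ShimProblem(basis=make_basis(A, bound), target=target))
        oracle = grid_refinement_oracle(A, target, bound)
        # agreement within 2e-3 of the bound range (2*bound)
        assert np.max(np.abs(sol.currents - oracle)) < 2e-3 * 2 * bound

    def test_bounds_respected(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(60, 5))
        target = 100 * rng.normal(size=60)
        sol = solve_static(ShimProblem(basis=make_basis(A, 0.5), target=target))
        assert np.max(np.abs(sol.currents)) <= 0.5 * (1 + 1e-6)

    def test_appending_channels_never_hurts(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(50, 3))
        target = rng.normal(size=50) * 10
        small = solve_static(ShimProblem(basis=make_basis(A), target=target))
        big = solve_static(
            ShimProblem(basis=make_basis(np.hstack([A, rng.normal(size=(50, 2))])),
                        target=target)
        )
        assert big.residual_std <= small.residual_std + 1e-6

    def test_scale_equivariance_unbounded(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(40, 3))
        target = rng.normal(size=40)
        basis = make_basis(A, bound=np.inf)
        s1 = solve_static(ShimProblem(basis=basis, target=target))
        s2 = solve_static(ShimProblem(basis=basis, target=7.0 * target))
        assert np.allclose(s2.currents, 7.0 * s1.currents, atol=1e-7)
        assert s2.residual_std == pytest.approx(7.0 * s1.residual_std, abs=1e-7)


@pytest.fixture(scope="module")
def dyn_head():
    return generate_head(PhantomSpec(shape=(24, 24, 10), voxel_mm=10.0, seed=21))


class TestSolveDynamic:
    def test_window_spanning_mask_equals_static(self, dyn_head):
        basis = sh_fields(SHBasisSpec(max_order=1, include_f0=True), dyn_head)
        static = solve_static(
            ShimProblem(basis=basis, target=dyn_head.values[dyn_head.mask])
        )
        schedule = solve_dynamic(dyn_head, basis, window=100)
        assert np.allclose(schedule.region_std, static.residual_std, atol=1e-9)
        assert schedule.global_std == pytest.approx(static.residual_std, abs=1e-9)

    def test_per_region_beats_static_on_region(self, dyn_head):
        """Slice solutions are at least as good as the static one per region."""
        basis = sh_fields(SHBasisSpec(max_order=1, include_f0=True), dyn_head)
        target = dyn_head.values[dyn_head.mask]
        static = solve_static(ShimProblem(basis=basis, target=target))
        idx = np.column_stack(dyn_head.mask_indices())[:, 2]
        schedule = solve_dynamic(dyn_head, basis, window=1)
        for row, s in enumerate(schedule.slice_indices):
            region = (idx >= s - 1) & (idx <= s + 1)
            static_region_std = np.std(static.residual[region])
            assert schedule.region_std[row] <= static_region_std + 1e-6

    def test_single_slice_plane_fit_closed_form(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 30, (12, 12, 1))
        fm = flat_fieldmap(values, voxel_mm=10.0)
        basis = sh_fields(SHBasisSpec(max_order=1, include_f0=True), fm)
        # drop the through-slice Z column, degenerate on one slice
        keep = [i for i, lab in enumerate(basis.labels) if lab != "Z"]
        basis = ShimBasis(
            matrix=basis.matrix[:, keep],
            bounds=basis.bounds[keep],
            labels=tuple(basis.labels[i] for i in keep),
        )
        schedule = solve_dynamic(fm, basis, window=0)
        # ordinary least squares plane fit on the slice
        pts = fm.mask_coords_mm()
        X = np.column_stack([np.ones(len(pts)), pts[:, 0], pts[:, 1]])
        y = values[fm.mask]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        expected = np.std(y - X @ beta)
        assert schedule.region_std[0] == pytest.approx(expected, abs=1e-8)

    def test_global_std_from_own_slices(self, dyn_head):
        basis = sh_fields(SHBasisSpec(max_order=1, include_f0=True), dyn_head)
        schedule = solve_dynamic(dyn_head, basis, window=1)
        assert schedule.assembled_residual is not None
        assert schedule.global_std == pytest.approx(
            float(np.std(schedule.assembled_residual))
        )


class TestCurrentSteps:
    def test_constant_schedule_zero_steps(self):
        sched = SliceShimSchedule(
            slice_indices=np.arange(3),
            currents=np.ones((3, 2)),
            labels=("a", "b"),
            slice_axis=2,
            window=1,
            region_std=np.zeros(3),
            own_slice_std=np.zeros(3),
            global_std=0.0,
        )
        steps = current_steps(sched)
        assert np.all(steps["max"] == 0) and np.all(steps["mean"] == 0)

    def test_sign_flip_counts_double(self):
        sched = SliceShimSchedule(
            slice_indices=np.arange(2),
            currents=np.array([[1.0], [-1.0]]),
            labels=("a",),
            slice_axis=2,
            window=1,
            region_std=np.zeros(2),
            own_slice_std=np.zeros(2),
            global_std=0.0,
        )
        assert current_steps(sched)["max"][0] == pytest.approx(2.0)

    def test_needs_two_slices(self):
        sched = SliceShimSchedule(
            slice_indices=np.arange(1),
            currents=np.ones((1, 1)),
            labels=("a",),
            slice_axis=2,
            window=1,
            region_std=np.zeros(1),
            own_slice_std=np.zeros(1),
            global_std=0.0,
        )
        with pytest.raises(SolverError):
            current_steps(sched)


class TestComposeMethod:
    def test_unknown_label_rejected_with_roster(self, dyn_head):
        with pytest.raises(SolverError, match="roster"):
            compose_method(dyn_head, "S9")

    def test_s2_is_second_order_removal(self, dyn_head):
        direct = remove_sh(dyn_head, SHBasisSpec(max_order=2))
        via = compose_method(dyn_head, "S2")
        assert via.residual_std == pytest.approx(masked_std(direct))

    def test_missing_array_rejected(self, dyn_head):
        with pytest.raises(SolverError, match="MC8"):
            compose_method(dyn_head, "S2+MC8", arrays={})

    def test_baseline_is_identity(self, dyn_head):
        res = compose_method(dyn_head, "baseline")
        assert res.residual_std == pytest.approx(masked_std(dyn_head))
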