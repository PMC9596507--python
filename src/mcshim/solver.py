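"""Current-limited least-squares shim solving.

The objective throughout is the population standard deviation of the shimmed
field over the region of interest.  An unbounded f0 (constant) column is
always part of the solve — the scanner center frequency can be updated freely
— so minimizing the sum of squares of ``target + basis @ currents + f0`` is
identical to minimizing the variance, and the problem reduces to
bound-constrained linear least squares (solved with scipy's ``lsq_linear``).

Sign convention: the shim field *adds* to the map, so the solver returns the
currents that flatten ``target + basis @ currents``; cancelling a field that
was generated by coefficients ``c`` yields currents ``-c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .coils import ShimBasis
from .errors import SolverError
from .fieldmap import FieldMap, masked_std
from .harmonics import SHBasisSpec, remove_sh, sh_fields

log = logging.getLogger(__name__)

SOLVER_TOL = 1e-10


@dataclass(frozen=True)
class ShimProblem:
    basis: ShimBasis
    target: np.ndarray  # Hz over mask voxels

    def __post_init__(self) -> None:
        t = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "target", t)
        if self.basis.matrix.shape[0] != t.shape[0]:
            raise SolverError(
                f"basis has {self.basis.matrix.shape[0]} rows but target has "
                f"{t.shape[0]} entries"
            )


@dataclass(frozen=True)
class ShimSolution:
    """Optimal channel drives, residual field over the region, and its std."""

    currents: np.ndarray
    labels: tuple[str, ...]
    residual: np.ndarray
    residual_std: float


@dataclass(frozen=True)
class SliceShimSchedule:
    """Per-slice shim settings from dynamic (slice-based) optimization."""

    slice_indices: np.ndarray  # mask-intersecting slice numbers
    currents: np.ndarray  # (n_slices, channels)
    labels: tuple[str, ...]
    slice_axis: int
    window: int
    region_std: np.ndarray  # std over each slice's optimization region
    own_slice_std: np.ndarray  # std over each slice's own voxels
    global_std: float  # std of the assembled per-slice residual, whole mask
    assembled_residual: np.ndarray | None = None  # per-mask-voxel residual, Hz


def _augment_f0(basis: ShimBasis) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Append an unbounded f0 column unless one is already present."""
    has_f0 = "f0" in basis.labels
    A = basis.matrix
    lo = -basis.bounds
    hi = basis.bounds.copy()
    if not has_f0:
        A = np.hstack([A, np.ones((A.shape[0], 1))])
        lo = np.concatenate([lo, [-np.inf]])
        hi = np.concatenate([hi, [np.inf]])
    return A, lo, hi, has_f0


def solve_static(problem: ShimProblem) -> ShimSolution:
    """Bound-constrained least-squares shim over one region.

    Returns the currents minimizing ``std(target + basis @ currents)`` under
    the per-channel box bounds, the residual (with the optimal f0 offset
    applied) and its population std in Hz.
    """
    basis, target = problem.basis, problem.target
    if target.shape[0] == 0:
        raise SolverError("cannot shim an empty region")
    if np.any(basis.bounds < 0):
        raise SolverError("negative current limit: infeasible bounds")
    A, lo, hi, has_f0 = _augment_f0(basis)
    if A.shape[1] == 0 or not np.any(np.abs(A) > 0):
        residual = target - target.mean()
        return ShimSolution(
            currents=np.zeros(basis.n_channels),
            labels=basis.labels,
            residual=residual,
            residual_std=float(np.std(target)),
        )
    res = lsq_linear(A, -target, bounds=(lo, hi), tol=SOLVER_TOL, method="bvls")
    x = res.x
    residual = target + A @ x
    currents = x if has_f0 else x[:-1]
    return ShimSolution(
        currents=currents,
        labels=basis.labels,
        residual=residual,
        residual_std=float(np.std(residual)),
    )


def solve_dynamic(
    fm: FieldMap,
    basis: ShimBasis,
    slice_axis: int = 2,
    window: int = 1,
) -> SliceShimSchedule:
    """Slice-based dynamic shim: each slice optimized with its neighbors.

    For every mask-intersecting slice ``s`` the static solve is run on the
    mask voxels of slices ``[s-window, s+window]``.  The global std assembles,
    for every slice, the residual of its own solution evaluated on that slice
    only, then takes the population std over the whole brain — the
    acquisition-faithful metric for a multi-slice scan.
    """
    if window < 0:
        raise SolverError("window must be >= 0")
    idx = np.column_stack(fm.mask_indices())
    if idx.shape[0] == 0:
        raise SolverError("empty mask")
    if basis.matrix.shape[0] != idx.shape[0]:
        raise SolverError("basis rows must match mask voxel count")
    slice_of_voxel = idx[:, slice_axis]
    slices = np.unique(slice_of_voxel)
    target = fm.values[fm.mask]

    currents = []
    region_stds = []
    own_stds = []
    assembled = np.empty_like(target)
    kept_slices = []
    for s in slices:
        region = (slice_of_voxel >= s - window) & (slice_of_voxel <= s + window)
        if not np.any(region):
            log.info("slice %d: empty optimization region, skipped", s)
            continue
        sub = ShimBasis(
            matrix=basis.matrix[region], bounds=basis.bounds, labels=basis.labels
        )
        sol = solve_static(ShimProblem(basis=sub, target=target[region]))
        own = slice_of_voxel == s
        own_in_region = slice_of_voxel[region] == s
        own_res = sol.residual[own_in_region]
        assembled[own] = own_res
        kept_slices.append(s)
        currents.append(sol.currents)
        region_stds.append(sol.residual_std)
        own_stds.append(float(np.std(own_res)) if own_res.size else 0.0)
    return SliceShimSchedule(
        slice_indices=np.array(kept_slices),
        currents=np.array(currents),
        labels=basis.labels,
        slice_axis=slice_axis,
        window=window,
        region_std=np.array(region_stds),
        own_slice_std=np.array(own_stds),
        global_std=float(np.std(assembled)),
        assembled_residual=assembled,
    )


def current_steps(schedule: SliceShimSchedule) -> dict[str, np.ndarray]:
    """Adjacent-slice current changes per channel (switching diagnostic)."""
    if schedule.currents.shape[0] < 2:
        raise SolverError("need at least 2 slices to compute current steps")
    steps = np.abs(np.diff(schedule.currents, axis=0))
    return {"max": steps.max(axis=0), "mean": steps.mean(axis=0)}


# --- method roster ----------------------------------------------------------

STATIC_SH = {"S1": 1, "S2": 2, "S3": 3}
DYNAMIC_SH = {"D1": 1, "D2": 2, "D3": 3}


@dataclass(frozen=True)
class MethodResult:
    """Residual map and summary for one entry of the comparison roster."""

    label: str
    residual: FieldMap
    residual_std: float
    schedule: SliceShimSchedule | None = None
    solution: ShimSolution | None = None


def _residual_map(fm: FieldMap, residual_in_mask: np.ndarray) -> FieldMap:
    values = fm.values.copy()
    values[fm.mask] = residual_in_mask
    return fm.with_values(values)


def compose_method(
    fm: FieldMap,
    label: str,
    arrays: dict[str, list] | None = None,
    current_limit: float = 2.5,
    window: int = 1,
    slice_axis: int = 2,
    n_segments: int = 64,
    remove_order: int = 2,
    s2_first: bool = True,
    precomputed_bases: dict[str, ShimBasis] | None = None,
) -> MethodResult:
    """Run one labelled shim method on a field map.

    Roster: ``baseline``; static ``S1/S2/S3`` (SH removal up to that order)
    optionally ``+MCx`` (static current-limited array shim on the S2
    residual); dynamic ``D1/D2/D3`` (slice-based SH including f0) optionally
    ``D1+MCx`` (dynamic f0+linear SH plus array).  Per the comparison
    protocol, everything beyond the baseline is applied after static removal
    of up to second-order fields (``s2_first``; set False to skip for the
    dynamic SH methods).

    ``arrays`` maps array names (e.g. "MC8") to loop lists; ``precomputed_bases``
    may cache their Biot-Savart bases (keyed by array name) to avoid
    recomputation across methods.
    """
    from .coils import basis_from_loops  # local import to avoid cycle

    arrays = arrays or {}
    label = label.strip()
    if label == "baseline":
        return MethodResult(label, fm, masked_std(fm), None, None)

    parts = [p.strip() for p in label.split("+")]
    head = parts[0]
    mc_name = parts[1] if len(parts) > 1 else None
    known = sorted(set(STATIC_SH) | set(DYNAMIC_SH) | {"baseline"})
    if head not in STATIC_SH and head not in DYNAMIC_SH:
        raise SolverError(
            f"unknown method label {label!r}; roster heads: {known} "
            f"optionally '+<array name>'"
        )
    if mc_name is not None and mc_name not in arrays and (
        precomputed_bases is None or mc_name not in precomputed_bases
    ):
        raise SolverError(
            f"method {label!r} needs array {mc_name!r}; available: {sorted(arrays)}"
        )

    def mc_basis(target_fm: FieldMap) -> ShimBasis:
        if precomputed_bases is not None and mc_name in precomputed_bases:
            return precomputed_bases[mc_name]
        b = basis_from_loops(
            arrays[mc_name], target_fm, current_limit=current_limit, n_segments=n_segments
        )
        if precomputed_bases is not None:
            precomputed_bases[mc_name] = b
        return b

    if head in STATIC_SH:
        order = STATIC_SH[head]
        residual_fm = remove_sh(fm, SHBasisSpec(max_order=order))
        if mc_name is None:
            return MethodResult(label, residual_fm, masked_std(residual_fm))
        basis = mc_basis(residual_fm)
        sol = solve_static(
            ShimProblem(basis=basis, target=residual_fm.values[residual_fm.mask])
        )
        res_fm = _residual_map(residual_fm, sol.residual)
        return MethodResult(label, res_fm, sol.residual_std, solution=sol)

    order = DYNAMIC_SH[head]
    stage1 = remove_sh(fm, SHBasisSpec(max_order=remove_order)) if s2_first else fm
    basis = sh_fields(SHBasisSpec(max_order=order, include_f0=True), stage1)
    if mc_name is not None:
        basis = basis.concat(mc_basis(stage1))
    schedule = solve_dynamic(stage1, basis, slice_axis=slice_axis, window=window)
    res_fm = _residual_map(stage1, schedule.assembled_residual)
    return MethodResult(label, res_fm, schedule.global_std, schedule=schedule)
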