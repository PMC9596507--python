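"""Nonlinear optimization of the center-plus-ring shim array geometry.

The design objective is the mean (over the supplied field maps) of the
current-limited static shim residual std achieved by the candidate geometry,
so design and deployment use the same solver and the same amplifier bounds.
The discrete outer-loop count is swept exhaustively; the four continuous
parameters (r1, r2, alpha, z_offset) are optimized by seeded multi-start
bounded local search (Powell), since the objective is non-convex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .coils import MCArrayGeometry, ShimBasis, build_mc_array, loops_bz_matrix
from .errors import GeometryError, SolverError
from .fieldmap import FieldMap
from .solver import ShimProblem, solve_static

log = logging.getLogger(__name__)


class _CachedMaps:
    """Mask coordinates and targets extracted once per optimization run.

    ``voxel_stride`` subsamples mask voxels (every k-th in C order) to
    cheapen the inner shim solves during geometry search; the final
    reported objective is always re-evaluated at stride 1.
    """

    def __init__(self, fms: list[FieldMap], voxel_stride: int = 1):
        if voxel_stride < 1:
            raise SolverError("voxel stride must be >= 1")
        self.points = []
        self.targets = []
        for fm in fms:
            pts = fm.mask_coords_mm()[::voxel_stride]
            self.points.append(pts)
            self.targets.append(fm.values[fm.mask][::voxel_stride])

    def objective(self, geom: MCArrayGeometry, current_limit: float, n_segments: int) -> float:
        try:
            loops = build_mc_array(geom)
        except GeometryError as exc:
            log.debug("geometry rejected: %s", exc)
            return float("inf")
        stds = []
        n_loops = len(loops)
        for pts, target in zip(self.points, self.targets):
            basis = ShimBasis(
                matrix=loops_bz_matrix(loops, pts, n_segments),
                bounds=np.full(n_loops, current_limit),
                labels=tuple(f"loop{i}" for i in range(n_loops)),
            )
            sol = solve_static(ShimProblem(basis=basis, target=target))
            stds.append(sol.residual_std)
        return float(np.mean(stds))


@dataclass(frozen=True)
class GeometrySearchSpace:
    """Bounds of the geometry search (mm / degrees)."""

    n_outer_candidates: tuple[int, ...] = (5, 6, 7, 8, 9)
    r1_bounds: tuple[float, float] = (10.0, 50.0)
    r2_bounds: tuple[float, float] = (10.0, 150.0)
    alpha_bounds: tuple[float, float] = (-45.0, 45.0)
    z_offset_bounds: tuple[float, float] = (-50.0, 50.0)
    former_diameter: float = 370.0
    turns: int = 50

    def __post_init__(self) -> None:
        if not self.n_outer_candidates:
            raise GeometryError("candidate set must be nonempty")
        for name in ("r1_bounds", "r2_bounds", "alpha_bounds", "z_offset_bounds"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise GeometryError(f"{name} out of order: {lo} > {hi}")

    @property
    def box(self) -> list[tuple[float, float]]:
        return [self.r1_bounds, self.r2_bounds, self.alpha_bounds, self.z_offset_bounds]


@dataclass
class DesignResult:
    best_geometry: MCArrayGeometry
    objective: float  # Hz
    trace: list[dict] = field(default_factory=list)  # per-start records
    per_map_objectives: np.ndarray | None = None


def design_objective(
    geom: MCArrayGeometry,
    fms: list[FieldMap],
    current_limit: float = 2.5,
    n_segments: int = 32,
) -> float:
    """Mean current-limited static shim residual std for a geometry, Hz.

    Invalid geometries (overlapping loops) score +inf so bounded searches
    need no explicit constraint handling.
    """
    if not fms:
        raise SolverError("need at least one field map")
    return _CachedMaps(fms).objective(geom, current_limit, n_segments)


def _objective_vec(
    x: np.ndarray,
    n_outer: int,
    space: GeometrySearchSpace,
    cached: _CachedMaps,
    current_limit: float,
    n_segments: int,
) -> float:
    try:
        geom = MCArrayGeometry(
            n_outer=n_outer,
            r1=float(x[0]),
            r2=float(x[1]),
            alpha=float(x[2]),
            z_offset=float(x[3]),
            former_diameter=space.former_diameter,
            turns=space.turns,
        )
    except GeometryError:
        return float("inf")
    return cached.objective(geom, current_limit, n_segments)


def _feasible_starts(
    n_outer: int, space: GeometrySearchSpace, n_starts: int, seed: int
) -> np.ndarray:
    """Latin-hypercube starts over the box, filtered to valid geometries."""
    box = np.asarray(space.box)
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts: list[np.ndarray] = []
    attempts = 0
    while len(starts) < n_starts and attempts < 50:
        raw = qmc.scale(sampler.random(n_starts), box[:, 0], box[:, 1])
        for x in raw:
            if len(starts) >= n_starts:
                break
            try:
                build_mc_array(
                    MCArrayGeometry(
                        n_outer=n_outer,
                        r1=float(x[0]),
                        r2=float(x[1]),
                        alpha=float(x[2]),
                        z_offset=float(x[3]),
                        former_diameter=space.former_diameter,
                        turns=space.turns,
                    )
                )
            except GeometryError:
                continue
            starts.append(x)
        attempts += 1
    return np.asarray(starts)


def optimize_geometry(
    space: GeometrySearchSpace,
    fms: list[FieldMap],
    n_starts: int = 8,
    seed: int = 0,
    current_limit: float = 2.5,
    n_segments: int = 32,
    maxfev: int = 600,
    voxel_stride: int = 1,
    extra_starts: list[np.ndarray] | None = None,
) -> DesignResult:
    """Sweep outer-loop counts; multi-start Powell over (r1, r2, alpha, z).

    Deterministic given (seed, n_starts, inputs).  ``extra_starts`` may seed
    additional start points (e.g. a known fixed design).  ``voxel_stride``
    subsamples mask voxels inside the search; the returned objective is
    re-evaluated on the full mask.
    """
    if not fms:
        raise SolverError("need at least one field map")
    cached = _CachedMaps(fms, voxel_stride)
    best: tuple[float, MCArrayGeometry] | None = None
    trace: list[dict] = []
    for n_outer in space.n_outer_candidates:
        starts = _feasible_starts(n_outer, space, n_starts, seed + 1000 * n_outer)
        if extra_starts:
            extra = [np.asarray(s, dtype=float) for s in extra_starts]
            starts = np.vstack([extra, starts]) if starts.size else np.asarray(extra)
        if starts.size == 0:
            log.info("n_outer=%d: no feasible start found, skipped", n_outer)
            continue
        for x0 in starts:
            res = minimize(
                _objective_vec,
                x0,
                args=(n_outer, space, cached, current_limit, n_segments),
                method="Powell",
                bounds=space.box,
                options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-8},
            )
            trace.append(
                {
                    "n_outer": n_outer,
                    "x0": x0.tolist(),
                    "x": res.x.tolist(),
                    "objective": float(res.fun),
                    "nfev": int(res.nfev),
                }
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
                geom = MCArrayGeometry(
                    n_outer=n_outer,
                    r1=float(res.x[0]),
                    r2=float(res.x[1]),
                    alpha=float(res.x[2]),
                    z_offset=float(res.x[3]),
                    former_diameter=space.former_diameter,
                    turns=space.turns,
                )
                best = (float(res.fun), geom)
    if best is None:
        raise SolverError("no feasible geometry found in the whole search space")
    per_map = np.array(
        [design_objective(best[1], [fm], current_limit, n_segments) for fm in fms]
    )
    return DesignResult(
        best_geometry=best[1],
        objective=float(per_map.mean()),  # re-evaluated on the full masks
        trace=trace,
        per_map_objectives=per_map,
    )


def per_subject_vs_fixed(
    fixed: MCArrayGeometry,
    fms: list[FieldMap],
    space: GeometrySearchSpace | None = None,
    n_starts: int = 4,
    seed: int = 0,
    current_limit: float = 2.5,
    n_segments: int = 32,
    maxfev: int = 600,
    voxel_stride: int = 1,
) -> np.ndarray:
    """Per-map gain (Hz) of a subject-specific design over a fixed design.

    Each per-map search is seeded at the fixed design, so the improvement is
    nonnegative up to local-solver tolerance.
    """
    if len(fms) < 2:
        raise SolverError("need at least two field maps for a cohort comparison")
    if space is None:
        space = GeometrySearchSpace(
            n_outer_candidates=(fixed.n_outer,),
            former_diameter=fixed.former_diameter,
            turns=fixed.turns,
        )
    x_fixed = np.array([fixed.r1, fixed.r2, fixed.alpha, fixed.z_offset])
    improvements = []
    for fm in fms:
        fixed_obj = design_objective(fixed, [fm], current_limit, n_segments)
        res = optimize_geometry(
            space,
            [fm],
            n_starts=n_starts,
            seed=seed,
            current_limit=current_limit,
            n_segments=n_segments,
            maxfev=maxfev,
            voxel_stride=voxel_stride,
            extra_starts=[x_fixed],
        )
        improvements.append(fixed_obj - res.objective)
    return np.asarray(improvements)
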