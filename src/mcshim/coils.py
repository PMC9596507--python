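"""Loop-coil geometry and discrete Biot-Savart field synthesis.

Shim elements are circular wire loops approximated by closed polygons; the
z-component of their magnetic field is evaluated with the exact field of each
straight segment and converted to Hz through the proton gyromagnetic ratio.
Loops are planar filaments tangent to the cylindrical former by default; an
optional conformal mode projects the polygon vertices onto the former surface
(the physical loops were bent onto the cylinder).  Multi-turn elements are a
single filament scaled by the turn count — the finite bundle extent only
matters for the circuit estimators in :mod:`mcshim.circuit`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_HZ_PER_T, MU0
from .errors import GeometryError, OverlapError
from .fieldmap import FieldMap

log = logging.getLogger(__name__)

DEFAULT_N_SEGMENTS = 64


@dataclass(frozen=True)
class LoopElement:
    """One circular shim loop: center/normal in scanner mm, radius mm."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float
    turns: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError(f"loop radius must be positive, got {self.radius}")
        if self.turns < 1:
            raise GeometryError(f"turns must be >= 1, got {self.turns}")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise GeometryError(f"loop normal must be a unit vector, got {self.normal}")


@dataclass(frozen=True)
class MCArrayGeometry:
    """Parametric center-plus-ring array on a cylindrical former.

    ``r1`` is the loop radius, ``r2`` the on-surface arc distance from the
    center element to each outer element, ``alpha`` tilts the outer normals
    from radial toward the cylinder (+z) axis, and ``z_offset`` shifts the
    whole array axially (negative = caudal).
    """

    n_outer: int = 7
    r1: float = 37.0
    r2: float = 95.0
    alpha: float = 0.0
    z_offset: float = -8.0
    former_diameter: float = 370.0
    turns: int = 50

    def __post_init__(self) -> None:
        if self.n_outer < 0:
            raise GeometryError("n_outer must be >= 0")
        if not (10.0 <= self.r1 <= 50.0):
            raise GeometryError(f"r1={self.r1} mm outside design bounds [10, 50] mm")
        if self.n_outer > 0 and not (10.0 <= self.r2 <= 150.0):
            raise GeometryError(f"r2={self.r2} mm outside design bounds [10, 150] mm")
        if self.former_diameter <= 0:
            raise GeometryError("former diameter must be positive")


@dataclass(frozen=True)
class ShimBasis:
    """Voxels-in-mask x channels matrix of field per unit drive (Hz/A)."""

    matrix: np.ndarray
    bounds: np.ndarray  # (channels,) absolute drive limit; inf = unconstrained
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        b = np.asarray(self.bounds, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "bounds", b)
        if not np.all(np.isfinite(m)):
            raise GeometryError("shim basis matrix contains non-finite entries")
        if m.shape[1] != b.shape[0] or m.shape[1] != len(self.labels):
            raise GeometryError(
                "basis columns, bounds and labels must have equal counts"
            )

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def concat(self, other: "ShimBasis") -> "ShimBasis":
        if self.matrix.shape[0] != other.matrix.shape[0]:
            raise GeometryError("cannot concatenate bases with different voxel counts")
        return ShimBasis(
            matrix=np.hstack([self.matrix, other.matrix]),
            bounds=np.concatenate([self.bounds, other.bounds]),
            labels=self.labels + other.labels,
        )


def loop_vertices(
    loop: LoopElement,
    n_segments: int = DEFAULT_N_SEGMENTS,
    conformal_radius: float | None = None,
) -> np.ndarray:
    """Closed polygon vertices (n_segments+1, 3) of a loop, in mm.

    With ``conformal_radius`` the planar vertices are radially projected onto
    the cylinder of that radius about the z axis (conformal winding).
    """
    if n_segments < 8:
        raise GeometryError("n_segments must be >= 8")
    n = np.asarray(loop.normal, dtype=float)
    # build an orthonormal in-plane frame
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    t = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    verts = (
        np.asarray(loop.center, dtype=float)
        + loop.radius * np.cos(t)[:, None] * u
        + loop.radius * np.sin(t)[:, None] * v
    )
    if conformal_radius is not None:
        rho = np.hypot(verts[:, 0], verts[:, 1])
        scale = conformal_radius / np.maximum(rho, 1e-12)
        verts[:, 0] *= scale
        verts[:, 1] *= scale
    return verts


def segment_bz(starts_mm: np.ndarray, ends_mm: np.ndarray, points_mm: np.ndarray) -> np.ndarray:
    """z-field (tesla per ampere) of straight segments at points.

    Uses the exact finite-segment Biot-Savart expression
    ``B = mu0 I/(4 pi) * (a x b)(|a|+|b|) / (|a||b|(|a||b| + a.b))``
    with ``a``, ``b`` the vectors from the field point to the endpoints.
    """
    return np.sum(_segment_bz_per_segment(starts_mm, ends_mm, points_mm), axis=1)


def loop_bz(
    loop: LoopElement,
    points_mm: np.ndarray,
    current: float = 1.0,
    n_segments: int = DEFAULT_N_SEGMENTS,
    conformal_radius: float | None = None,
) -> np.ndarray:
    """Off-resonance (Hz) produced by a loop at points, for a given current.

    The result includes the turn count and is linear in both current and
    turns.  Points must not lie on the wire path.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    verts = loop_vertices(loop, n_segments, conformal_radius)
    # chunk over points to bound the (P, S, 3) temporaries
    out = np.empty(points_mm.shape[0])
    chunk = max(1, int(2_000_000 / max(n_segments, 1)))
    for lo in range(0, points_mm.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        out[sl] = segment_bz(verts[:-1], verts[1:], points_mm[sl])
    return out * current * loop.turns * GAMMA_HZ_PER_T


def _check_overlap(loops: list[LoopElement], context: str) -> None:
    for i in range(len(loops)):
        for j in range(i + 1, len(loops)):
            d = np.linalg.norm(
                np.asarray(loops[i].center) - np.asarray(loops[j].center)
            )
            if d < loops[i].radius + loops[j].radius - 1e-9:
                raise OverlapError(
                    f"{context}: loops {i} and {j} overlap "
                    f"(center distance {d:.1f} mm < radii sum "
                    f"{loops[i].radius + loops[j].radius:.1f} mm)"
                )


def build_mc_array(geom: MCArrayGeometry) -> list[LoopElement]:
    """Construct the center-plus-ring loop list for a parametric array.

    The center element sits on the former at azimuth 0 and axial position
    ``z_offset``; the ``n_outer`` ring elements sit at on-surface arc distance
    ``r2``, equally spaced around the ring.  Normals are radial, tilted by
    ``alpha`` degrees toward the +z cylinder axis.
    """
    R = geom.former_diameter / 2.0
    alpha = np.deg2rad(geom.alpha)
    loops = [
        LoopElement(
            center=(R, 0.0, geom.z_offset),
            normal=(1.0, 0.0, 0.0),
            radius=geom.r1,
            turns=geom.turns,
        )
    ]
    for k in range(geom.n_outer):
        psi = 2.0 * np.pi * k / geom.n_outer
        phi = geom.r2 * np.cos(psi) / R  # azimuthal arc -> angle
        dz = geom.r2 * np.sin(psi)
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        normal = np.cos(alpha) * radial + np.sin(alpha) * np.array([0.0, 0.0, 1.0])
        normal /= np.linalg.norm(normal)
        loops.append(
            LoopElement(
                center=(R * np.cos(phi), R * np.sin(phi), geom.z_offset + dz),
                normal=tuple(normal),
                radius=geom.r1,
                turns=geom.turns,
            )
        )
    _check_overlap(loops, "MC array")
    return loops


def build_cylindrical_grid_array(
    n_rows: int,
    n_per_row: int,
    former_diameter: float,
    loop_radius: float,
    turns: int = 1,
    z_span: float = 300.0,
    z_center: float = 0.0,
    azimuth_offset_deg: float = 0.0,
) -> list[LoopElement]:
    """Generic rows-by-azimuth grid of radial loops on a cylinder.

    Stand-in generator for high-count shim arrays: rows equally spaced
    axially over ``z_span``, loops equally spaced in azimuth, normals radial.
    """
    R = former_diameter / 2.0
    pitch = z_span / n_rows
    z0 = z_center - z_span / 2.0 + pitch / 2.0
    loops = []
    for row in range(n_rows):
        for k in range(n_per_row):
            phi = 2.0 * np.pi * k / n_per_row + np.deg2rad(azimuth_offset_deg)
            loops.append(
                LoopElement(
                    center=(R * np.cos(phi), R * np.sin(phi), z0 + row * pitch),
                    normal=(np.cos(phi), np.sin(phi), 0.0),
                    radius=loop_radius,
                    turns=turns,
                )
            )
    _check_overlap(loops, "grid array")
    return loops


def loops_bz_matrix(
    loops: list[LoopElement],
    points_mm: np.ndarray,
    n_segments: int = DEFAULT_N_SEGMENTS,
    conformal_radius: float | None = None,
) -> np.ndarray:
    """(points, loops) matrix of Hz per ampere; one batched segment pass."""
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    n_loops = len(loops)
    out = np.empty((points_mm.shape[0], n_loops))
    if n_loops == 0:
        return out
    verts = [loop_vertices(loop, n_segments, conformal_radius) for loop in loops]
    starts = np.vstack([v[:-1] for v in verts])
    ends = np.vstack([v[1:] for v in verts])
    chunk = max(1, int(4_000_000 / max(starts.shape[0], 1)))
    turns = np.array([loop.turns for loop in loops], dtype=float)
    for lo in range(0, points_mm.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        per_seg = _segment_bz_per_segment(starts, ends, points_mm[sl])
        per_loop = per_seg.reshape(per_seg.shape[0], n_loops, n_segments).sum(axis=2)
        out[sl] = per_loop * turns[None, :]
    return out * GAMMA_HZ_PER_T


def _segment_bz_per_segment(
    starts_mm: np.ndarray, ends_mm: np.ndarray, points_mm: np.ndarray
) -> np.ndarray:
    """Per-segment z-field contributions (tesla/ampere), not yet summed."""
    a = (starts_mm[None, :, :] - points_mm[:, None, :]) * 1e-3
    b = (ends_mm[None, :, :] - points_mm[:, None, :]) * 1e-3
    cross_z = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    dot = np.einsum("psk,psk->ps", a, b)
    denom = na * nb * (na * nb + dot)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise GeometryError("field point lies on (or too close to) the conductor")
    return MU0 / (4.0 * np.pi) * cross_z * (na + nb) / denom


def basis_from_loops(
    loops: list[LoopElement],
    fm: FieldMap,
    current_limit: float = 2.5,
    n_segments: int = DEFAULT_N_SEGMENTS,
    conformal_radius: float | None = None,
    labels: tuple[str, ...] | None = None,
) -> ShimBasis:
    """Biot-Savart shim basis: one Hz/A column per loop at mask voxel centers."""
    pts = fm.mask_coords_mm()
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    for i, loop in enumerate(loops):
        c = np.asarray(loop.center)
        if np.all(c >= lo - loop.radius) and np.all(c <= hi + loop.radius):
            log.warning("loop %d center %s is inside/near the mask bounding box", i, c)
    matrix = loops_bz_matrix(loops, pts, n_segments, conformal_radius)
    if labels is None:
        labels = tuple(f"loop{i}" for i in range(len(loops)))
    return ShimBasis(
        matrix=matrix,
        bounds=np.full(len(loops), float(current_limit)),
        labels=labels,
    )


def loops_to_csv(loops: list[LoopElement], path, n_segments: int = DEFAULT_N_SEGMENTS) -> None:
    """Export loop polygon vertices as a CSV table (loop, vertex, x, y, z)."""
    rows = []
    for i, loop in enumerate(loops):
        for j, v in enumerate(loop_vertices(loop, n_segments)):
            rows.append((i, j, v[0], v[1], v[2]))
    arr = np.array(rows)
    np.savetxt(
        path, arr, delimiter=",", header="loop,vertex,x_mm,y_mm,z_mm", comments=""
    )
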