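"""Real solid spherical-harmonic shim fields and SH removal.

Whole-body shim coils generate fields shaped as real solid harmonics
``r^l Y_lm``; order 1 is the linear gradient set (x, y, z), order 2 adds the
five second-degree terms (z2, zx, zy, x2-y2, xy), and so on.  Columns are
scaled to unit RMS over a sphere of ``reference_radius`` so SH and loop
columns are numerically comparable inside the solver; SH channels are
unconstrained by default (hardware amp limits are not convertible to these
units without a vendor calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import scipy.linalg
from scipy.special import sph_harm_y

from .coils import ShimBasis
from .errors import BasisError, EmptyMaskError
from .fieldmap import FieldMap

_ORDER1_ALIASES = {(1, -1): "Y", (1, 0): "Z", (1, 1): "X"}
_ORDER2_ALIASES = {(2, -2): "XY", (2, -1): "ZY", (2, 0): "Z2", (2, 1): "ZX", (2, 2): "X2-Y2"}


@dataclass(frozen=True)
class SHBasisSpec:
    """Spherical-harmonic shim set up to ``max_order`` (1..4)."""

    max_order: int = 2
    include_f0: bool = True
    reference_radius: float = 90.0  # mm

    def __post_init__(self) -> None:
        if not (1 <= self.max_order <= 4):
            raise BasisError(f"SH order must be in 1..4, got {self.max_order}")
        if self.reference_radius <= 0:
            raise BasisError("reference radius must be positive")


def _real_solid_harmonic(l: int, m: int, points_mm: np.ndarray, r_ref: float) -> np.ndarray:
    """Real solid harmonic (r/r_ref)^l * Ylm_real * sqrt(4 pi); unit RMS at r_ref."""
    x, y, z = points_mm[:, 0], points_mm[:, 1], points_mm[:, 2]
    r = np.sqrt(x * x + y * y + z * z)
    cos_theta = np.divide(z, r, out=np.zeros_like(r), where=r > 0)
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    phi = np.arctan2(y, x)
    ylm = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        ang = ylm.real
    elif m > 0:
        ang = np.sqrt(2.0) * (-1.0) ** m * ylm.real
    else:
        ang = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
    return (r / r_ref) ** l * ang * np.sqrt(4.0 * np.pi)


def sh_labels(max_order: int, include_f0: bool) -> tuple[str, ...]:
    labels = ["f0"] if include_f0 else []
    for l in range(1, max_order + 1):
        for m in range(-l, l + 1):
            labels.append(
                _ORDER1_ALIASES.get((l, m))
                or _ORDER2_ALIASES.get((l, m))
                or f"SH({l},{m})"
            )
    return tuple(labels)


def sh_fields(spec: SHBasisSpec, fm: FieldMap) -> ShimBasis:
    """SH shim basis evaluated at mask voxel centers.

    Column counts excluding f0: order 1 -> 3, order 2 -> 8, order 3 -> 15.
    """
    if fm.n_mask == 0:
        raise EmptyMaskError("cannot build an SH basis on an empty mask")
    pts = fm.mask_coords_mm()
    cols = []
    if spec.include_f0:
        cols.append(np.ones(pts.shape[0]))
    for l in range(1, spec.max_order + 1):
        for m in range(-l, l + 1):
            cols.append(_real_solid_harmonic(l, m, pts, spec.reference_radius))
    matrix = np.column_stack(cols)
    return ShimBasis(
        matrix=matrix,
        bounds=np.full(matrix.shape[1], np.inf),
        labels=sh_labels(spec.max_order, spec.include_f0),
    )


def remove_sh(fm: FieldMap, spec: SHBasisSpec) -> FieldMap:
    """Residual after unconstrained least-squares SH removal over the mask.

    An f0 (constant) column is always included, so the masked std never
    increases.  The fitted low-order field is subtracted over the whole grid.
    """
    full_spec = SHBasisSpec(
        max_order=spec.max_order,
        include_f0=True,
        reference_radius=spec.reference_radius,
    )
    basis = sh_fields(full_spec, fm)
    A = basis.matrix
    if A.shape[0] <= A.shape[1]:
        raise BasisError(
            f"mask has {A.shape[0]} voxels but the basis has {A.shape[1]} columns"
        )
    # detect rank deficiency (e.g. single-slice mask vs through-slice terms)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        norms = np.linalg.norm(A, axis=0)
        _, _, piv = scipy.linalg.qr(
            A / np.maximum(norms, 1e-300), pivoting=True, mode="economic"
        )
        rank = int(np.sum(sv > 1e-10 * sv[0]))
        bad = [basis.labels[i] for i in sorted(piv[rank:])]
        raise BasisError(
            f"SH fit is rank-deficient on this mask; degenerate columns: {bad}"
        )
    target = fm.values[fm.mask]
    coeffs, *_ = np.linalg.lstsq(A, target, rcond=None)
    # evaluate the fitted field on the full grid for subtraction everywhere
    shape = fm.values.shape
    ijk = np.indices(shape).reshape(3, -1).T.astype(float)
    all_pts = nib.affines.apply_affine(fm.affine, ijk)
    cols = [np.ones(all_pts.shape[0])]
    for l in range(1, full_spec.max_order + 1):
        for m in range(-l, l + 1):
            cols.append(_real_solid_harmonic(l, m, all_pts, full_spec.reference_radius))
    fitted = (np.column_stack(cols) @ coeffs).reshape(shape)
    return fm.with_values(fm.values - fitted)
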