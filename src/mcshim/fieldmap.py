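"""B0 field-map data model, NIfTI I/O and masked statistics.

A :class:`FieldMap` holds an off-resonance volume in Hz on a regular 3D grid
together with its voxel-to-mm affine and a binary brain mask.  The standard
deviation of the field over the mask is the homogeneity metric every shim
method in this package minimizes; the population (divide-by-N) convention is
used throughout so that the std equals the RMS of the demeaned residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AcquisitionError, EmptyMaskError, ShapeMismatchError


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo gradient-echo timing, in milliseconds."""

    te1_ms: float = 2.0
    te2_ms: float = 3.0

    def __post_init__(self) -> None:
        if not (self.te2_ms > self.te1_ms > 0):
            raise AcquisitionError(
                f"echo times must satisfy TE2 > TE1 > 0, got "
                f"TE1={self.te1_ms} ms, TE2={self.te2_ms} ms"
            )

    @property
    def delta_te_s(self) -> float:
        return (self.te2_ms - self.te1_ms) * 1e-3

    @property
    def alias_range_hz(self) -> float:
        """Half-width of the alias-free frequency range, 1/(2*dTE)."""
        return 1.0 / (2.0 * self.delta_te_s)


@dataclass
class FieldMap:
    """Off-resonance volume (Hz) with affine and binary mask."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ShapeMismatchError(
                f"field map must be 3D, got shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ShapeMismatchError("affine must be a 4x4 matrix")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ShapeMismatchError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("field values inside the mask must be finite")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    def mask_indices(self) -> tuple[np.ndarray, ...]:
        """Voxel indices of mask voxels in C order (the basis row order)."""
        return np.nonzero(self.mask)

    def mask_coords_mm(self) -> np.ndarray:
        """(N, 3) scanner-frame mm coordinates of mask voxel centers."""
        ijk = np.column_stack(self.mask_indices()).astype(float)
        return nib.affines.apply_affine(self.affine, ijk)

    def with_values(self, values: np.ndarray) -> "FieldMap":
        return replace(self, values=np.asarray(values, dtype=float))


def fieldmap_from_phases(
    phase1: np.ndarray,
    phase2: np.ndarray,
    params: AcquisitionParams,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> FieldMap:
    """Compute an off-resonance map from two echo phases.

    The per-voxel phase difference is wrapped to (-pi, pi] and converted to
    frequency as ``wrap(phi2 - phi1) / (2*pi*dTE)``, giving values inside the
    alias-free range ``+-1/(2*dTE)``.  No spatial unwrapping is attempted.
    """
    phase1 = np.asarray(phase1, dtype=float)
    phase2 = np.asarray(phase2, dtype=float)
    if phase1.shape != phase2.shape:
        raise ShapeMismatchError(
            f"phase volumes differ in shape: {phase1.shape} vs {phase2.shape}"
        )
    dphi = np.angle(np.exp(1j * (phase2 - phase1)))
    values = dphi / (2.0 * np.pi * params.delta_te_s)
    if affine is None:
        affine = np.eye(4)
    return FieldMap(values=values, affine=affine, mask=mask)


def masked_std(fm: FieldMap) -> float:
    """Population standard deviation of the field over mask voxels, Hz."""
    if fm.n_mask == 0:
        raise EmptyMaskError("cannot compute statistics over an empty mask")
    return float(np.std(fm.values[fm.mask]))


def masked_mean(fm: FieldMap) -> float:
    if fm.n_mask == 0:
        raise EmptyMaskError("cannot compute statistics over an empty mask")
    return float(np.mean(fm.values[fm.mask]))


def _mask_path(path: Path) -> Path:
    suffixes = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    stem = path.name[: -len(suffixes)] if suffixes else path.name
    return path.with_name(stem + "_mask" + suffixes)


def write_fieldmap(fm: FieldMap, path: str | Path) -> None:
    """Write field values and mask as NIfTI; mask goes to a ``_mask`` companion."""
    path = Path(path)
    nib.save(nib.Nifti1Image(fm.values.astype(np.float64), fm.affine), str(path))
    nib.save(
        nib.Nifti1Image(fm.mask.astype(np.uint8), fm.affine), str(_mask_path(path))
    )


def read_fieldmap(path: str | Path, mask_path: str | Path | None = None) -> FieldMap:
    """Read a field map from NIfTI.

    The mask is read from ``mask_path`` if given, else from the ``_mask``
    companion file if present; otherwise all finite voxels are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such field map: {path}")
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata())
    if values.ndim != 3:
        raise ShapeMismatchError(
            f"expected a 3D volume, got {values.ndim}D in {path}"
        )
    mask = None
    candidate = Path(mask_path) if mask_path is not None else _mask_path(path)
    if candidate.exists():
        mask_img = nib.load(str(candidate))
        mask = np.asarray(mask_img.get_fdata()) > 0.5
    return FieldMap(values=values, affine=np.asarray(img.affine), mask=mask)
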