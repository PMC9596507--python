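"""Synthetic 7 T brain B0 field maps.

Real brain field maps at 7 T are dominated by a smooth low-order background
(imperfect magnet/system shim) plus strong localized dipole-shaped
perturbations from air/tissue susceptibility interfaces — frontal sinus,
nasal/sphenoid cavities and ear canals — that concentrate inhomogeneity in
inferior and frontal brain regions.  This module emulates exactly that
structure: an ellipsoidal brain mask, a random low-order solid-harmonic
background, external air spheres generating classic dipole fields, and white
noise.  The default spec is calibrated so the within-mask standard deviation
across subjects falls in :data:`CALIBRATION_BAND_HZ`, bracketing the
~144 Hz unshimmed average reported for 7 T brains.

The generator defines the study conditions for every simulation-based test
in this package; it is not an anatomical model (no tissue compartments, no
FFT susceptibility solver).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import GAMMA_HZ_PER_T
from .errors import GeometryError
from .fieldmap import FieldMap

#: Declared calibration band (Hz) for the cohort-mean unshimmed masked std.
CALIBRATION_BAND_HZ = (100.0, 190.0)


@dataclass(frozen=True)
class AirCavity:
    """Air sphere outside the brain: center (mm), radius (mm), dchi (ppm, SI)."""

    center: tuple[float, float, float]
    radius: float
    dchi_ppm: float = 9.4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head field map.

    Grid defaults to 64 x 64 x 31 voxels at 3.75 mm (240 mm transverse FOV,
    ~116 mm axial coverage), matching a typical low-resolution dual-echo
    field-map protocol.  Axes: x left-right, y posterior-anterior, z
    inferior-superior (the B0 axis).  ``background_rms_hz[l]`` is the RMS
    coefficient amplitude (Hz at the 90 mm reference radius) for solid
    harmonics of order l+1.
    """

    shape: tuple[int, int, int] = (64, 64, 31)
    voxel_mm: float = 3.75
    semi_axes_mm: tuple[float, float, float] = (65.0, 80.0, 55.0)
    cavities: tuple[AirCavity, ...] = (
        AirCavity(center=(0.0, 72.0, -48.0), radius=10.0),   # frontal sinus
        AirCavity(center=(0.0, 52.0, -56.0), radius=9.0),    # sphenoid/nasal
        AirCavity(center=(68.0, 0.0, -42.0), radius=7.0),    # ear canal R
        AirCavity(center=(-68.0, 0.0, -42.0), radius=7.0),   # ear canal L
    )
    background_rms_hz: tuple[float, ...] = (115.0, 80.0, 48.0)
    noise_std_hz: float = 3.0
    b0_tesla: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) <= 0:
            raise GeometryError("ellipsoid semi-axes must be positive")
        if self.noise_std_hz < 0:
            raise GeometryError("noise std must be >= 0")
        for cav in self.cavities:
            c = np.asarray(cav.center) / np.asarray(self.semi_axes_mm)
            if np.sum(c**2) <= 1.0:
                raise GeometryError(
                    f"air cavity at {cav.center} lies inside the brain ellipsoid"
                )


def sphere_dipole_field(
    center_mm: np.ndarray,
    radius_mm: float,
    dchi_ppm: float,
    b0_tesla: float,
    points_mm: np.ndarray,
) -> np.ndarray:
    """Off-resonance (Hz) of a susceptibility sphere, outside the sphere.

    ``df = (dchi/3) * f_larmor * (a^3/r^3) * (3 cos^2 theta - 1)`` with theta
    measured from the B0 (z) axis; the angular average over any concentric
    sphere is zero.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    d = points_mm - np.asarray(center_mm, dtype=float)
    r = np.linalg.norm(d, axis=1)
    if np.any(r <= radius_mm):
        raise GeometryError("dipole field requested inside the air sphere")
    cos2 = (d[:, 2] / r) ** 2
    f_larmor = GAMMA_HZ_PER_T * b0_tesla
    return (dchi_ppm * 1e-6 / 3.0) * f_larmor * (radius_mm / r) ** 3 * (3.0 * cos2 - 1.0)


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Affine (center of grid at isocenter) and (N, 3) voxel-center coords."""
    shape = np.asarray(spec.shape)
    affine = np.eye(4)
    affine[:3, :3] *= spec.voxel_mm
    affine[:3, 3] = -(shape - 1) / 2.0 * spec.voxel_mm
    ijk = np.indices(spec.shape).reshape(3, -1).T
    pts = ijk * spec.voxel_mm + affine[:3, 3]
    return affine, pts


def _solid_harmonic_background(
    spec: PhantomSpec, pts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    from .harmonics import _real_solid_harmonic

    out = np.zeros(pts.shape[0])
    for li, rms in enumerate(spec.background_rms_hz):
        l = li + 1
        coeffs = rng.normal(0.0, rms, size=2 * l + 1)
        for m, c in zip(range(-l, l + 1), coeffs):
            out += c * _real_solid_harmonic(l, m, pts, 90.0)
    return out


def generate_head(spec: PhantomSpec) -> FieldMap:
    """One synthetic head field map; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    affine, pts = _grid(spec)
    axes = np.asarray(spec.semi_axes_mm)
    mask = (np.sum((pts / axes) ** 2, axis=1) <= 1.0).reshape(spec.shape)
    if not mask.any():
        raise GeometryError("degenerate ellipsoid: empty mask")
    values = _solid_harmonic_background(spec, pts, rng)
    for cav in spec.cavities:
        # grid voxels inside the air sphere (always outside the brain mask)
        # carry no meaningful field; leave them at the background value
        outside = np.linalg.norm(pts - np.asarray(cav.center), axis=1) > cav.radius
        values[outside] += sphere_dipole_field(
            np.asarray(cav.center), cav.radius, cav.dchi_ppm, spec.b0_tesla, pts[outside]
        )
    values += rng.normal(0.0, spec.noise_std_hz, size=values.shape)
    return FieldMap(values=values.reshape(spec.shape), affine=affine, mask=mask)


def generate_cohort(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[FieldMap]:
    """n synthetic subjects with jittered anatomy; reproducible per seed.

    Jitter (fixed distributions): ellipsoid semi-axes scaled by U(0.93, 1.07)
    per axis, cavity centers displaced by N(0, 3 mm) per coordinate (pushed
    outward if the jitter would land inside the mask), cavity susceptibility
    scaled by U(0.8, 1.2).  Each subject gets an independent sub-seed, so the
    background draw differs across subjects too.
    """
    if n < 1:
        raise GeometryError("cohort size must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for k in range(n):
        jit = np.random.default_rng(sub_seeds[k])
        axes = np.asarray(base.semi_axes_mm) * jit.uniform(0.93, 1.07, size=3)
        cavities = []
        for cav in base.cavities:
            center = np.asarray(cav.center, dtype=float) + jit.normal(0.0, 3.0, size=3)
            # keep the cavity outside the (jittered) ellipsoid
            u = np.sum((center / axes) ** 2)
            if u <= 1.0 + 1e-9:
                center *= 1.05 / np.sqrt(max(u, 1e-9))
            cavities.append(
                AirCavity(
                    center=tuple(center),
                    radius=cav.radius,
                    dchi_ppm=cav.dchi_ppm * jit.uniform(0.8, 1.2),
                )
            )
        spec = replace(
            base,
            semi_axes_mm=tuple(axes),
            cavities=tuple(cavities),
            seed=int(sub_seeds[k]),
        )
        cohort.append(generate_head(spec))
    return cohort
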