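import numpy as np
import pytest

from mcshim import FieldMap, MCArrayGeometry, build_mc_array, generate_head, loop_bz
from mcshim.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse head phantom (same FOV, 7.5 mm voxels) for fast solver tests."""
    return PhantomSpec(shape=(32, 32, 16), voxel_mm=7.5, seed=11)


@pytest.fixture(scope="session")
def small_head(small_spec) -> FieldMap:
    return generate_head(small_spec)


@pytest.fixture(scope="session")
def loop_array_head() -> FieldMap:
    """Coarse phantom whose field is exactly a known 8-loop array's field + f0."""
    spec = PhantomSpec(
        shape=(32, 32, 16), voxel_mm=7.5, background_rms_hz=(0.0, 0.0, 0.0),
        noise_std_hz=0.0, cavities=(), seed=0,
    )
    fm = generate_head(spec)
    truth = MCArrayGeometry(n_outer=7, r1=37.0, r2=95.0, alpha=0.0, z_offset=-8.0)
    loops = build_mc_array(truth)
    currents = np.random.default_rng(7).uniform(-2.0, 2.0, size=len(loops))
    pts = fm.mask_coords_mm()
    field = sum(loop_bz(l, pts, c, 32) for l, c in zip(loops, currents)) + 30.0
    values = fm.values.copy()
    values[fm.mask] = field
    return fm.with_values(values)


@pytest.fixture(scope="session")
def default_cohort():
    """Ten synthetic subjects at the default field-map geometry (fixed seed)."""
    from mcshim import generate_cohort

    return generate_cohort(10, seed=1)


@pytest.fixture(scope="session")
def recovery_result(loop_array_head):
    """Geometry search on the known-array map, shared across recovery tests."""
    from mcshim import GeometrySearchSpace, optimize_geometry

    space = GeometrySearchSpace(n_outer_candidates=(7,))
    return optimize_geometry(
        space, [loop_array_head], n_starts=4, seed=0,
        n_segments=16, maxfev=400, voxel_stride=2,
    )


def flat_fieldmap(values: np.ndarray, voxel_mm: float = 1.0) -> FieldMap:
    """Helper: field map with identity-scaled affine centered at the origin."""
    values = np.asarray(values, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -(np.asarray(values.shape) - 1) / 2.0 * voxel_mm
    return FieldMap(values=values, affine=affine)
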