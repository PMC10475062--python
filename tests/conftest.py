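import numpy as np
import pytest

from maskvar.geometry import ContourPolygon, ContourSet, ImageGeometry
from maskvar.phantom import CohortConfig, generate_cohort


def axis_aligned_geometry(spacing=(1.0, 1.0, 1.0), dims=(5, 5, 1), origin=(0.0, 0.0, 0.0)):
    return ImageGeometry(
        origin=origin,
        row_dir=[1.0, 0.0, 0.0],
        col_dir=[0.0, 1.0, 0.0],
        slice_dir=[0.0, 0.0, 1.0],
        spacing=spacing,
        dims=dims,
    )


def square_contour(lo, hi, z=0.0, roi="square"):
    """Axis-aligned square polygon [lo, hi]^2 at patient z."""
    verts = np.array(
        [[lo, lo, z], [hi, lo, z], [hi, hi, z], [lo, hi, z]], dtype=float
    )
    return ContourSet(roi_name=roi, polygons=(ContourPolygon(verts),))


@pytest.fixture
def unit_grid():
    """5x5x1 grid, 1 mm spacing, voxel centres at integer mm."""
    return axis_aligned_geometry()


@pytest.fixture(scope="session")
def cohort42():
    """The default 20-patient synthetic cohort at seed 42."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-patient cohort for cheaper pipeline tests."""
    return generate_cohort(CohortConfig(n_patients=5, seed=7))
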