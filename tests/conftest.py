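import numpy as np
import pytest

import fabrifem as ff


@pytest.fixture(scope="session")
def card():
    return ff.MaterialCard()


@pytest.fixture(scope="session")
def all_tables():
    return ff.builtin_tables()


@pytest.fixture(scope="session")
def z_lattice():
    """Rod lattice with struts thickened along z (anisotropy ground truth)."""
    return ff.rod_lattice_volume((64, 64, 64), (90.0, 90.0, 200.0), 820.0, 82.0)


@pytest.fixture(scope="session")
def iso_lattice():
    """Rod lattice with equal struts on all axes (cubic symmetry)."""
    return ff.rod_lattice_volume((64, 64, 64), (120.0, 120.0, 120.0), 820.0, 82.0)


@pytest.fixture(scope="session")
def femur():
    return ff.femur_like_mesh()


def axis_mil_oracle(grid: np.ndarray) -> np.ndarray:
    """Brute-force MIL along the three axes by exhaustive voxel line-walks.

    For each axis, every voxel row is a test line; MIL = total line
    length / number of phase transitions along the rows.  Independent of
    the direction-sampled implementation under test.
    """
    grid = np.asarray(grid, dtype=bool)
    out = np.empty(3)
    for axis in range(3):
        swapped = np.moveaxis(grid, axis, -1)
        crossings = np.count_nonzero(np.diff(swapped, axis=-1))
        length = swapped.size  # voxel units: every row spans its full extent
        out[axis] = length / crossings if crossings else np.inf
    return out
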