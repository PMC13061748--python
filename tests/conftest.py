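import numpy as np
import pytest

from diebackmap import PointPattern, Window


@pytest.fixture
def window():
    return Window(1000.0, 1000.0)


def make_pattern(coords, species=None, status=None, crown=None, window=None):
    """Build a small pattern from literal coordinate pairs."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if window is None:
        window = Window(1000.0, 1000.0)
    if species is None:
        species = ["A. verus"] * n
    return PointPattern(
        window, coords[:, 0], coords[:, 1], species, status, crown
    )


@pytest.fixture
def marked_pattern():
    """Nine-plant pattern with species, status and crown marks."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(100, 900, size=(9, 2))
    species = ["A. verus"] * 5 + ["sp01"] * 2 + ["sp02"] * 2
    status = ["live", "live", "dead", "dead", "live"] + ["na"] * 4
    crown = rng.uniform(20, 70, 9)
    return make_pattern(coords, species, status, crown)
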