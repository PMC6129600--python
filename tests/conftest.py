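import numpy as np
import pytest

from archmorph import (
    BinaryFootprint,
    FootprintParams,
    extract_contour,
    generate_disk,
    generate_footprint,
    generate_rectangle,
)


@pytest.fixture(scope="session")
def disk50():
    return generate_disk(50)


@pytest.fixture(scope="session")
def disk50_contour(disk50):
    return extract_contour(disk50)


@pytest.fixture(scope="session")
def disk25():
    return generate_disk(25)


@pytest.fixture(scope="session")
def square3():
    return generate_rectangle(3, 3)


@pytest.fixture(scope="session")
def depth_sweep():
    """Noise-free synthetic prints at the three arch-depth strata."""
    return {d: generate_footprint(FootprintParams(arch_depth=d)) for d in (0.1, 0.5, 0.9)}


@pytest.fixture()
def plus_mask():
    m = np.zeros((5, 5), dtype=bool)
    m[2, 1:4] = True
    m[1:4, 2] = True
    return BinaryFootprint(mask=m)
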