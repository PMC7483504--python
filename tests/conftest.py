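import numpy as np
import pytest


def disk(shape, center, radius):
    """Boolean disk mask: pixels whose centers lie strictly inside."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2


@pytest.fixture
def disk_mask():
    return disk


@pytest.fixture(scope="session")
def exvivo_phantom():
    """One trephine-defect phantom (6 mm defect, 1.5 mm offset)."""
    from graftvol import build_model

    grid, truth, spec = build_model("BD6-1.5")
    return grid, truth, spec
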