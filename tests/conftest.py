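import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathclip import PlaneWidget, gen_mesh


@pytest.fixture
def z_plane():
    """Widget whose plane is z = 0 with the inside below (normal +z)."""
    return PlaneWidget(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def icosphere():
    return gen_mesh("SPHERE", {"radius": 1.0, "subdivisions": 3})


@pytest.fixture(scope="session")
def unit_tetrahedron():
    from pathclip import TriangleMesh

    return TriangleMesh(
        vertices=np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
        ),
        faces=np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]),
    )
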