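import numpy as np
import pytest
import trimesh

from condylometry.core import TriangleMesh
from condylometry.synth import PhantomSpec, make_condyle_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default condyle phantom (mesh, landmarks), shared read-only."""
    return make_condyle_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture()
def unit_cube():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


def icosphere(radius: float, subdivisions: int = 4) -> TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def sphere10():
    return icosphere(10.0, 4)
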