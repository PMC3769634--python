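import numpy as np
import pytest

from hippomorph import (PdmSurface, ShapeSpec, SphericalParamMesh,
                        icosphere_sampling, make_shape)


@pytest.fixture(scope="session")
def sampling():
    return icosphere_sampling()


@pytest.fixture(scope="session")
def sphere10(sampling):
    """Radius-10 sphere on the standard sampling, centered at the origin."""
    V, F, th, ph = sampling
    return PdmSurface(10.0 * V, np.array(F), np.array(th), np.array(ph))


@pytest.fixture(scope="session")
def sphere10_mesh(sphere10):
    return SphericalParamMesh(sphere10.vertices, sphere10.faces,
                              sphere10.theta, sphere10.phi)


@pytest.fixture(scope="session")
def tube():
    """Default hippocampus-like tube: (spec, model, surface)."""
    spec = ShapeSpec()
    model, surface = make_shape(spec)
    return spec, model, surface
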