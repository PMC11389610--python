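import numpy as np
import pytest

from neurocollin import ArcCurve, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def noise_free_arc_scene():
    """Elongated somata exactly along circle-arc normals; centerline on the arc."""
    spec = SceneSpec(curve=ArcCurve(center=(0.0, 0.0), radius=500.0,
                                    span_deg=(10.0, 170.0)),
                     n_neurons=120, kappa=None, seed=1)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def contaminated_scene():
    """Scene with planted glia, doublets and extracellular speckle."""
    spec = SceneSpec(curve=ArcCurve(center=(0.0, 0.0), radius=500.0,
                                    span_deg=(10.0, 170.0)),
                     n_neurons=100, kappa=8.0,
                     n_glia=12, n_doublets=6, n_speckle=10, seed=7)
    return generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
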