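import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_particles(xyz, classes=None, diameters=3.0, intensities=200.0):
    """Particle table from raw coordinates (test helper)."""
    xyz = np.atleast_2d(np.asarray(xyz, float))
    n = len(xyz)
    diameters = np.broadcast_to(np.asarray(diameters, float), n)
    intensities = np.broadcast_to(np.asarray(intensities, float), n)
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "x_nm": xyz[:, 0], "y_nm": xyz[:, 1], "z_nm": xyz[:, 2],
        "volume_nm3": np.pi / 6.0 * diameters ** 3,
        "diameter_nm": diameters,
        "peak_intensity": intensities,
        "voxel_count": np.full(n, 10),
        "class": classes if classes is not None else ["unclassified"] * n,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(0)
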