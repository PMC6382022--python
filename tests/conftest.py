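import numpy as np
import pytest

from lidarleaf.geometry import PointCloud
from lidarleaf.pipeline import PipelineConfig, run_all
from lidarleaf.synthetic import demo_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n, scale=10.0, with_reflectance=False):
    xyz = rng.uniform(-scale, scale, size=(n, 3))
    refl = rng.uniform(0, 60, size=n) if with_reflectance else None
    return PointCloud.from_xyz(xyz, refl)


@pytest.fixture(scope="session")
def noiseless_run():
    """Full pipeline on the standard 3-leaf scene, zero noise."""
    return run_all(demo_scene(), PipelineConfig())


@pytest.fixture(scope="session")
def stochastic_run():
    """Full pipeline under the stochastic study conditions: 0.2 cm range
    noise, 2% outlier returns, reflectance jitter."""
    cfg = PipelineConfig(range_sigma_cm=0.2, outlier_rate=0.02,
                         reflectance_sigma=1.0, seed=7)
    return run_all(demo_scene(), cfg)


def plant_summary(run):
    rep = run["report"]
    return rep[rep["section"] == "plant"].set_index("trait")
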