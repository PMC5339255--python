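import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def two_blob_run():
    """Fitted pipeline on the planted two-blob benchmark (seed 11)."""
    from voronet import VoronoiRiskModel, synthetic

    gvmap, labels = synthetic.make_mock_map(synthetic.two_blob_spec(seed=11))
    results = VoronoiRiskModel(gvmap).fit()
    return gvmap, labels, results


@pytest.fixture(scope="session")
def perturbed_grid():
    """7x7 jittered grid (seed 42) with one interior site displaced 30%
    of the spacing toward its neighbor; sites only."""
    xs = np.linspace(0.0, 1.0, 7)
    pts = np.array([(x, y) for y in xs for x in xs])
    rng = np.random.default_rng(42)
    pts = pts + rng.uniform(-1e-3, 1e-3, size=pts.shape)
    i_moved = 3 * 7 + 3          # (3, 3)
    i_target = 4 * 7 + 3         # (3, 4): one row up
    pts[i_moved] += 0.3 * (pts[i_target] - pts[i_moved])
    return pts


def random_sites(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=(n, 2))
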