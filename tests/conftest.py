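import numpy as np
import pytest

from palpinv import fem, nn
from palpinv.phantom import InclusionScenario


@pytest.fixture(scope="session")
def coarse_cfg() -> fem.FemConfig:
    """Coarse quarter-symmetric mesh: fast enough for per-test FEM solves."""
    return fem.FemConfig(fine_h=2.0)


@pytest.fixture(scope="session")
def default_cfg() -> fem.FemConfig:
    return fem.FemConfig()


@pytest.fixture(scope="session")
def reference_scenario() -> InclusionScenario:
    """The documented reference case: 8 mm inclusion, 5 mm deep, 120 kPa."""
    return InclusionScenario(d=8.0, h=5.0, E_inc=120.0)


def smooth_inverse_dataset(n: int, seed: int) -> nn.Dataset:
    """Synthetic learnable task shaped like the physical one.

    Three smooth monotone 'feature' channels of (d, h, E), used where a test
    needs a trainable dataset without paying for FEM solves.
    """
    rng = np.random.default_rng(seed)
    P = np.column_stack(
        [rng.uniform(2, 14, n), rng.uniform(3, 12, n), rng.uniform(20, 120, n)]
    )
    X = np.column_stack(
        [
            P[:, 0] * P[:, 2] / (P[:, 1] + 5.0),
            P[:, 0] ** 2 * np.sqrt(P[:, 2]) / (P[:, 1] + 2.0),
            P[:, 0] * P[:, 0] / (P[:, 1] + 1.0) + 0.01 * P[:, 2],
        ]
    )
    return nn.Dataset(X=X, Y=P, ids=np.arange(n))


@pytest.fixture(scope="session")
def smooth_dataset() -> nn.Dataset:
    return smooth_inverse_dataset(40, seed=7)
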