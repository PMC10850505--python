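import numpy as np
import pytest

from saxser.model_io import ConformerModel, ScatteringCurve
from saxser.synthetic import TwoDomainSpec, default_q_grid


@pytest.fixture(scope="session")
def small_spec_apo() -> TwoDomainSpec:
    """A scaled-down two-domain construct for fast unit tests."""
    return TwoDomainSpec(n1=20, n_link=5, n2=15, mode="apo", seed=123)


@pytest.fixture(scope="session")
def small_spec_bound() -> TwoDomainSpec:
    return TwoDomainSpec(n1=20, n_link=5, n2=15, mode="bound", seed=123)


@pytest.fixture(scope="session")
def coarse_q() -> np.ndarray:
    return default_q_grid(n=60)


@pytest.fixture()
def two_point_model() -> ConformerModel:
    return ConformerModel(id="pair", points=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]]))


def random_cloud(n: int, seed: int, scale: float = 10.0) -> ConformerModel:
    rng = np.random.default_rng(seed)
    return ConformerModel(id=f"cloud{seed}", points=rng.normal(size=(n, 3)) * scale)


def gaussian_curve(rg: float, i0: float = 100.0, n: int = 80, q_max: float = 0.2) -> ScatteringCurve:
    q = np.linspace(0.005, q_max, n)
    return ScatteringCurve(q=q, I=i0 * np.exp(-(q**2) * rg**2 / 3.0))
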