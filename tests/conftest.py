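import numpy as np
import pytest

from dcx.gridding import GridLayout
from dcx.simulate import ModuleSpec, SimConfig, generate_expression_dataset


@pytest.fixture(scope="session")
def small_layout() -> GridLayout:
    return GridLayout(rows=4, cols=4, pitch=16, spot_radius=3)


@pytest.fixture(scope="session")
def demo_layout() -> GridLayout:
    return GridLayout(rows=10, cols=10, pitch=16, spot_radius=3)


@pytest.fixture(scope="session")
def module_dataset():
    """200 genes with one planted module (size 30, rho 0.7 EA / 0 NEA)."""
    config = SimConfig(
        n_genes=200, modules=(ModuleSpec(30, 0.7, 0.0),), seed=7
    )
    return generate_expression_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """Fully null 300-gene dataset, 20 + 20 samples."""
    config = SimConfig(n_genes=300, de_fraction=0.0, seed=42)
    return generate_expression_dataset(config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
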