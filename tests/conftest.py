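import numpy as np
import pytest

from vesidist import ImageStack, SyntheticCellSpec, generate_cell


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_stack(rng):
    """Small random integer stack with a mix of sub- and supra-threshold pixels."""
    data = rng.integers(0, 200, size=(6, 16, 16), dtype=np.uint16)
    return ImageStack(data=data, cell_id="rand", group="test")


@pytest.fixture(scope="session")
def small_cell():
    """One synthetic cell at reduced size, shared across fast tests."""
    spec = SyntheticCellSpec(
        shape=(32, 96, 96), cell_radius=30.0, n_vesicles=80, seed=7,
        cell_id="small", group="WT",
    )
    stack, truth = generate_cell(spec)
    return spec, stack, truth
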