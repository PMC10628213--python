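import numpy as np
import pytest

from lipidxrr.stack_model import AIR, SILICON, LayerStack, Medium, Slab


@pytest.fixture
def bare_air_si():
    """Sharp bare air/Si interface (the textbook Fresnel case)."""
    return LayerStack(AIR, [], SILICON, 0.0)


@pytest.fixture
def q_grid():
    return np.geomspace(0.01, 0.7, 200)


def random_stack(rng, max_slabs=6):
    """Random physically plausible stack for property tests."""
    n = int(rng.integers(0, max_slabs + 1))
    slabs = [
        Slab(
            float(rng.uniform(3, 60)),
            float(rng.uniform(0, 0.8)),
            float(rng.uniform(0, 8)),
        )
        for _ in range(n)
    ]
    fronting = Medium("f", float(rng.uniform(0, 0.4)))
    backing = Medium("b", float(rng.uniform(0.3, 0.8)))
    return LayerStack(fronting, slabs, backing, float(rng.uniform(0, 8)))


@pytest.fixture(autouse=True)
def _quiet_smearing_warnings():
    """Random stacks legitimately trip the unphysical-smearing guard."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*smearing may be unphysical.*"
        )
        yield
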