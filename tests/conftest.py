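import logging
import warnings

import numpy as np
import pytest

from neurotess.coarse_mesh import build_coarse_mesh
from neurotess.morphology import SynthesisParams, generate_synthetic_morphology

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_tracing():
    """A compact branched neuron: 3 neurites, guaranteed bifurcations."""
    return generate_synthetic_morphology(
        SynthesisParams(n_neurites=3, seed=11, branch_probability=0.6, max_depth=3)
    )


@pytest.fixture(scope="session")
def small_coarse(small_tracing):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_coarse_mesh(small_tracing, soma_subdivision_level=1)


@pytest.fixture(scope="session")
def straight_tube_tracing():
    """Soma + one straight unbranched neurite along +x, constant radius."""
    from neurotess.morphology import parse_swc_text

    lines = ["1 1 0 0 0 5.0 -1"]
    x = 5.0
    for i in range(2, 8):
        lines.append(f"{i} 3 {x} 0 0 1.0 {i - 1}")
        x += 4.0
    return parse_swc_text("\n".join(lines))


@pytest.fixture(scope="session")
def straight_tube_coarse(straight_tube_tracing):
    return build_coarse_mesh(straight_tube_tracing, soma_subdivision_level=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
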