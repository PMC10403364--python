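import numpy as np
import pytest

from pherospace.spatial import build_hex_lattice
from pherospace.synthetic import (ForwardModelParams,
                                  default_toy_connectome_spec,
                                  generate_toy_connectome)

PATHWAY_LABELS = {
    "DA1_lPN": ("pn", "DA1"),
    "DL3_PN": ("pn", "DL3"),
    "MechanoSensory": ("sensory", "mechanosensory"),
    "OtherPN": ("other", None),
}


@pytest.fixture(scope="session")
def lattice():
    return build_hex_lattice()


@pytest.fixture(scope="session")
def noiseless_params():
    return ForwardModelParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def toy_connectome():
    return generate_toy_connectome(default_toy_connectome_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
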