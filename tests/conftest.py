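import numpy as np
import pytest

from gagir.spectra import BinningConfig, assemble_features
from gagir.synthetic_data import SynthConfig, default_composition, generate_library


@pytest.fixture(scope="session")
def full_library():
    """Default 23-sample synthetic library (16 di + 6 tetra + 1 hexa)."""
    return generate_library(SynthConfig(snr=10.0, seed=11))


@pytest.fixture(scope="session")
def di_library():
    """Disaccharide-only synthetic library (8 CS + 8 HS)."""
    comp = [m for m in default_composition() if m.oligomer_length == "di"]
    return generate_library(SynthConfig(composition=comp, snr=10.0, seed=11))


@pytest.fixture(scope="session")
def di_features(di_library):
    return assemble_features(di_library, BinningConfig())


@pytest.fixture(scope="session")
def separable_xy():
    """A tiny linearly separable problem: feature 0 carries the class."""
    rng = np.random.default_rng(42)
    n = 24
    y = np.arange(n) % 2 == 0
    X = rng.normal(0, 0.1, size=(n, 4))
    X[:, 0] += np.where(y, 1.0, 0.0)
    return X, y
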