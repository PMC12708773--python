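import numpy as np
import pytest

from xoscreen.dataset import stratified_split
from xoscreen.fingerprints import SCHEMES
from xoscreen.modeling import FingerprintClassifierModel, REDUCED_GRID
from xoscreen.structures import Molecule
from xoscreen.synthetic import SyntheticConfig, generate_library, generate_screening_set

NOISE0_CONFIG = SyntheticConfig(n_molecules=400, label_noise=0.0, seed=7)


@pytest.fixture(scope="session")
def noise0_library():
    """Noise-free synthetic library with the implanted activity rule (n=400)."""
    return generate_library(NOISE0_CONFIG)


@pytest.fixture(scope="session")
def noise0_split(noise0_library):
    return stratified_split(noise0_library, seed=1)


@pytest.fixture(scope="session")
def noise0_models(noise0_library, noise0_split):
    """Five constrained-grid-search models, one per fingerprint scheme."""
    return [
        FingerprintClassifierModel(noise0_library, noise0_split, scheme).fit(
            grid=REDUCED_GRID, seed=3
        )
        for scheme in SCHEMES
    ]


@pytest.fixture(scope="session")
def noise0_screening(noise0_library):
    return generate_screening_set(NOISE0_CONFIG, noise0_library)


def make_dummy_library(n, n_active, seed=0):
    """Label-only molecules for split arithmetic (no structure parsing)."""
    labels = ["active"] * n_active + ["inactive"] * (n - n_active)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return [
        Molecule(id=f"D{i:04d}", smiles="C", canonical_key=f"K{i:04d}", label=lab)
        for i, lab in enumerate(labels)
    ]
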