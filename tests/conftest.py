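import numpy as np
import pytest

from drugsig import LibraryConfig, build_matrix, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A reduced synthetic study world shared by read-only tests."""
    cfg = LibraryConfig(
        n_approved=30,
        n_experimental=40,
        n_proteins=25,
        n_indications=5,
        drugs_per_indication=(2, 4),
        seed=7,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_world):
    return build_matrix(small_world.compounds, small_world.site_models)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
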