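import numpy as np
import pandas as pd
import pytest

from macrofacets import SyntheticScenario, make_dataset

TINY_LIFE_FORMS = {
    "submerged": 8,
    "floating-leaved": 6,
    "free-floating": 6,
    "emergent": 20,
}


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small validated synthetic dataset (25 sites x 40 species)."""
    scenario = SyntheticScenario(
        n_sites=25,
        n_species=40,
        life_form_counts=dict(TINY_LIFE_FORMS),
        seed=7,
    )
    dataset, truth, report = make_dataset(scenario)
    return dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def toy_taxonomy(n_species: int = 10, seed: int = 0) -> pd.DataFrame:
    """Small nesting-consistent taxonomy spanning two phyla."""
    rng = np.random.default_rng(seed)
    genera = rng.integers(0, 5, size=n_species)
    g2f = rng.integers(0, 3, size=5)
    f2o = rng.integers(0, 2, size=3)
    o2s = np.array([0, 1])
    s2c = np.array([0, 1])
    c2p = np.array([0, 1])
    fam = g2f[genera]
    order = f2o[fam]
    sub = o2s[order]
    cls = s2c[sub]
    phy = c2p[cls]
    return pd.DataFrame(
        {
            "genus": [f"g{v}" for v in genera],
            "family": [f"f{v}" for v in fam],
            "order": [f"o{v}" for v in order],
            "subclass": [f"sc{v}" for v in sub],
            "class": [f"c{v}" for v in cls],
            "phylum": [f"p{v}" for v in phy],
        },
        index=[f"sp{i}" for i in range(n_species)],
    )
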