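import pytest

from m6avote.gkm import GkmParams
from m6avote.model import TrainingRecipe
from m6avote.psednc import PseDncConfig, builtin_property_table, standardize_properties
from m6avote.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def std_table():
    return standardize_properties(builtin_property_table())


@pytest.fixture(scope="session")
def light_recipe():
    """Small grids for fast unit tests; the search logic is unchanged."""
    return TrainingRecipe(
        psednc=PseDncConfig(lam=4),
        gkm=GkmParams(l=6, k=4),
        c_grid=(1.0, 100.0, 10000.0),
        gamma_grid=(0.1, 10.0, 1000.0),
        inner_cv=3,
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable toy, separable in every view: positives carry the
    motif verbatim at a fixed offset AND a GC-shifted background composition;
    negatives are uniform noise screened to never contain the motif."""
    pos = generate_dataset(
        SyntheticConfig(
            n_pos=10, n_neg=0, background=(0.1, 0.4, 0.4, 0.1),
            plant_prob=1.0, jitter=0, seed=7,
        )
    )
    neg = generate_dataset(
        SyntheticConfig(n_pos=0, n_neg=10, strict_negatives=True, seed=8)
    )
    return pos + neg
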