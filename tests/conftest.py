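import numpy as np
import pytest

from ahrseq.simulate import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic bundle shared across test modules."""
    return generate_dataset(
        ScenarioConfig(
            n_genes=250, n_dependent=40, n_independent=15, n_unspecific=8,
            effect_size=2.0, n_decoy_sets=4, seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
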