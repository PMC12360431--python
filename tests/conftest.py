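import numpy as np
import pandas as pd
import pytest

from orthodev.containers import CountMatrix, make_design
from orthodev.syndata import SynthConfig, generate


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        seed=11,
        n_orthogroups=300,
        n_paralog_pairs_per_species=(60, 60),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def study_bundle():
    """Default-condition dataset (study-scale emulation) shared by tests."""
    return generate(SynthConfig(seed=101))


def nb_counts(rng, mu, dispersion, shape):
    """Direct NB draws for handmade fixtures (mean/dispersion form)."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def flat_count_matrix(rng):
    """50 genes x 9 samples, no stage effect, NB dispersion 0.1."""
    design = make_design("sp")
    mu = np.exp(rng.normal(4.0, 1.0, size=50))
    counts = nb_counts(rng, mu[:, None], 0.1, (50, 9))
    return CountMatrix(
        counts=pd.DataFrame(
            counts, index=[f"sp|g{i}" for i in range(50)], columns=design.index
        ),
        design=design,
    )
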