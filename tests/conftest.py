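import numpy as np
import pytest

from antagogrid import matrices, strains


@pytest.fixture(scope="session")
def strain_table():
    return strains.load_strain_table()


@pytest.fixture(scope="session")
def exp_matrix(strain_table):
    """One experimental-like matrix at the generator's default settings."""
    spec = matrices.spec_from_strain_table(strain_table)
    return matrices.gen_experimental_like_matrix(
        spec, np.random.default_rng(1234)
    ).matrix


@pytest.fixture(scope="session")
def random_matrix_450():
    spec = matrices.MatrixGenSpec(n_strains=78, n_links=440)
    return matrices.gen_random_matrix(spec, np.random.default_rng(1234))
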