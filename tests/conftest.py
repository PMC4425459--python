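import numpy as np
import pytest

from emcdock.fixtures import default_forcefield, make_random_ligand


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_ligand():
    return make_random_ligand(n_atoms=5, seed=11)


@pytest.fixture(scope="session")
def small_receptor():
    return make_random_ligand(n_atoms=20, seed=12)


def random_population(rng, n, t_scale=4.0):
    """Uniform random pose population for kernel tests."""
    from emcdock.kernel import PosePopulation

    cols = [rng.uniform(-t_scale, t_scale, n) for _ in range(3)]
    cols += [rng.uniform(-np.pi, np.pi, n) for _ in range(3)]
    return PosePopulation(*cols)
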