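import numpy as np
import pytest

from estkit import coding, simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_params():
    return sim.GeneratorParams(n_families=25, seed=11)


@pytest.fixture(scope="session")
def family_data(small_params):
    return sim.generate_families(small_params)


def shuffled(seqs, rng):
    out = []
    for s in seqs:
        arr = np.array(list(s))
        rng.shuffle(arr)
        out.append("".join(arr))
    return out


@pytest.fixture(scope="session")
def coding_model(family_data, small_params):
    rng = np.random.default_rng(7)
    cds = [family_data.genes[small_params.ref_plant][g]
           for g in sorted(family_data.genes[small_params.ref_plant])]
    return coding.train_hexamer_model(cds, shuffled(cds, rng))


@pytest.fixture(scope="session")
def small_dataset():
    """A complete synthetic study at desk scale, with reads."""
    params = sim.GeneratorParams(n_families=30, seed=7)
    return sim.generate_dataset(params, depth_454=2.0, depth_sanger=0.6)
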