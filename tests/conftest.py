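import numpy as np
import pytest

import molfuse as mf
from molfuse.experiments import TINY_ARCH, tiny_train_config
from molfuse.fusion import prepare_molecule


@pytest.fixture(scope="session")
def tok_spec():
    return mf.default_tokenizer_spec()


@pytest.fixture(scope="session")
def regression_task():
    return mf.TaskSpec(name="synthetic", task_type="regression")


@pytest.fixture(scope="session")
def classification_task():
    return mf.TaskSpec(name="synthetic-clf", task_type="classification")


@pytest.fixture(scope="session")
def generator_smiles():
    """200 seeded generator SMILES used by fuzz-style properties."""
    cfg = mf.GeneratorConfig(n_molecules=200, seed=42,
                             scaffold_diversity="all_unique")
    return mf.generate_molecules(cfg)


@pytest.fixture(scope="session")
def small_fixture_frame():
    return mf.synergy_fixture(n=60, seed=7)


@pytest.fixture(scope="session")
def prepared_records(small_fixture_frame):
    return [prepare_molecule(s, label=float(l))
            for s, l in zip(small_fixture_frame.smiles,
                            small_fixture_frame.label)]


@pytest.fixture(scope="session")
def tiny_arch():
    return TINY_ARCH


@pytest.fixture()
def tiny_config():
    return tiny_train_config(seed=0, epochs=5)
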