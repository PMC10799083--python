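import pytest
from rdkit import RDLogger

from hpas.blocklib import load_default_library
from hpas.enumerator import GenerationConfig, generate_dataset

# InChI generation on boron-rich aromatics is chatty; keep test output readable
RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def dataset200():
    """A 200-molecule seeded default-configuration generation run.

    Shared across modules: bulk structural invariants, annotation, the
    mock-calculator pipeline and serialization all exercise the same run.
    """
    return generate_dataset(GenerationConfig(target_count=200, seed=7))
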