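import pytest

from coagkg.fixtures import load_paper_mini
from coagkg.synthetic_data import SimConfig, generate_all


@pytest.fixture(scope="session")
def paper_mini():
    return load_paper_mini()


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by read-only tests."""
    cfg = SimConfig(
        n_proteins=15,
        n_statements=80,
        n_pathways=4,
        pathway_size=(6, 12),
        seed=11,
    )
    return generate_all(cfg)
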