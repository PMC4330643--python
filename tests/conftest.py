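import warnings

import pytest

from capclade import anchor, simulate

warnings.filterwarnings("ignore", message=".*Kimura distance.*")


@pytest.fixture(scope="session")
def dataset():
    """One synthetic family shared by the read-only tests."""
    return simulate.simulate_family(simulate.SimConfig(seed=11))


@pytest.fixture(scope="session")
def core_alignment(dataset):
    trimmed = [
        anchor.trim_core(anchor.align_to_reference(r)) for r in dataset.sequences
    ]
    return anchor.stack_alignment(trimmed)
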