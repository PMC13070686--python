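import numpy as np
import pytest

from dualbind import MockEmbeddingProvider, SyntheticSpec, generate
from dualbind.sequences import ProteinSequence


@pytest.fixture(scope="session")
def provider():
    return MockEmbeddingProvider(dim=16)


@pytest.fixture(scope="session")
def small_records():
    """A small deterministic synthetic dataset (short chains for speed)."""
    spec = SyntheticSpec(
        n_pairs=24, ab_length_range=(18, 22), ag_length_range=(24, 30),
        paratope_span=(4, 9), epitope_span=(6, 12), seed=7,
    )
    records, components = generate(spec)
    return spec, records, components


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def antibody_seq():
    return ProteinSequence(
        id="ab1", residues="QVQLVESGGGLVQAGGSLRLSCAAS", chain_role="antibody",
        cdr_spans=((5, 10), (15, 20)),
    )
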