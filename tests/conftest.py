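import pytest

from radmut.synthetic import SyntheticGenomeSpec, generate_reference


@pytest.fixture(scope="session")
def toy_reference():
    """Small deterministic genome shared by tests that need sequences."""
    spec = SyntheticGenomeSpec(
        n_chromosomes=2, chromosome_length=60_000, n_genes=8,
        gene_length=1_500, seed=42,
    )
    return generate_reference(spec)
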