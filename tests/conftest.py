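import pytest

from cbdist import generate_pool, sample_community


@pytest.fixture(scope="session")
def pool_a():
    return generate_pool(n_templates=50, length=250, divergence=0.10, seed=1)


@pytest.fixture(scope="session")
def pool_b():
    return generate_pool(n_templates=50, length=250, divergence=0.10, seed=2)


@pytest.fixture(scope="session")
def community_a(pool_a):
    return sample_community(pool_a, depth=1500, error_rate=0.005, seed=3,
                            label="a1")


@pytest.fixture(scope="session")
def community_a2(pool_a):
    return sample_community(pool_a, depth=1500, error_rate=0.005, seed=4,
                            label="a2")


@pytest.fixture(scope="session")
def community_b(pool_b):
    return sample_community(pool_b, depth=1500, error_rate=0.005, seed=5,
                            label="b1")


@pytest.fixture
def fasta_file(tmp_path):
    """A small wrapped FASTA file with two records."""
    path = tmp_path / "sample1.fasta"
    path.write_text(
        ">read1 some description\n"
        "ACGTACGTAC\n"
        "GTACGTACGT\n"
        "ACGT\n"
        ">read2\n"
        "acgtacgtnn\n"
    )
    return path
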