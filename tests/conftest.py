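import numpy as np
import pandas as pd
import pytest

from bgcoex import CountMatrix, SimConfig, generate, write_bundle


def make_count_matrix(counts, lengths, gene_ids=None, sample_ids=None) -> CountMatrix:
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(n_samples)]
    idx = pd.Index(gene_ids, name="gene_id")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=sample_ids),
        lengths=pd.Series(np.asarray(lengths, dtype=float), index=idx, name="length"),
    )


def random_count_matrix(rng, n_genes, n_samples, max_count=2000):
    counts = rng.integers(0, max_count, size=(n_genes, n_samples))
    lengths = rng.integers(300, 5001, size=n_genes)
    return make_count_matrix(counts, lengths)


@pytest.fixture(scope="session")
def default_bundle():
    """One dataset at the default study conditions, shared across tests."""
    return generate(SimConfig())


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(default_bundle, out)
    return out


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate(
        SimConfig(
            n_genes=120,
            n_experiments=2,
            replicates=3,
            n_concordant=4,
            n_discordant=4,
            n_housekeeping=10,
            seed=7,
        )
    )
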