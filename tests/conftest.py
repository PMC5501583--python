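import numpy as np
import pytest

from virsign.pipeline import run_benchmark
from virsign.sequence_data import split_genome
from virsign.synthetic import make_two_class_corpus
from virsign.training import train_single_model


@pytest.fixture(scope="session")
def small_corpus():
    """A quick separable two-class corpus for unit tests."""
    return make_two_class_corpus(n_virus=30, n_host=30, divergence=0.3, genome_length=5000, seed=11)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A cheap trained 500 bp model (coarse lambda grid, 5 folds)."""
    virus, host = small_corpus
    return train_single_model(
        virus, host, L=500, k=4, seed=7, folds=5, n_lambda=8, lambda_min_ratio=1e-2, tol=1e-4
    )


@pytest.fixture(scope="session")
def small_fragments(small_corpus):
    virus, host = small_corpus
    vf = [f for g in virus for f in split_genome(g, 500)]
    hf = [f for g in host for f in split_genome(g, 500)]
    return vf, hf


@pytest.fixture(scope="session")
def benchmark_result():
    """The full-protocol benchmark: 200+200 genomes, L=500, k=4.

    Session-scoped because several robustness checks share the same
    trained model and held-out scores.
    """
    return run_benchmark(n_virus=200, n_host=200, divergence=0.3, L=500, k=4, seed=1)


def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    alphabet = "ACGTN" if with_n > 0 else "ACGT"
    if with_n > 0:
        p = [(1 - with_n) / 4] * 4 + [with_n]
    else:
        p = None
    return "".join(rng.choice(list(alphabet), size=n, p=p))
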