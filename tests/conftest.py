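"""Shared fixtures: synthetic corpora and their descriptor/PCA artifacts.

The heavier artifacts (descriptor matrices, PCA fits) are session-scoped
so the embedding and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pfasmap.descriptors import assemble_and_prune, compute_descriptor_vector
from pfasmap.embed import fit_pca
from pfasmap.synthetic import generate_corpus, generate_embedding_benchmark


@pytest.fixture(scope="session")
def corpus():
    return generate_corpus(seed=0)


@pytest.fixture(scope="session")
def bench_records():
    return generate_embedding_benchmark()


@pytest.fixture(scope="session")
def bench_matrix(bench_records):
    vectors = [compute_descriptor_vector(r.smiles) for r in bench_records]
    return assemble_and_prune(vectors, invalid_fraction_threshold=0.1)


@pytest.fixture(scope="session")
def bench_pca(bench_matrix):
    model, scores = fit_pca(bench_matrix, variance_target=0.70)
    return model, scores


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
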