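import numpy as np
import pytest

from mgcorr import center_distance_matrix, pairwise_distances, rank_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_pair(rng, n, p=2, q=1):
    """Random unrelated Gaussian samples and their Euclidean distances."""
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    return X, Y, pairwise_distances(X), pairwise_distances(Y)


def centered_with_ranks(Dx, Dy, scheme="unbiased"):
    A = center_distance_matrix(Dx, scheme)
    B = center_distance_matrix(Dy, scheme)
    ra = rank_matrix(Dx, axis="column")
    rb = rank_matrix(Dy, axis="row")
    return A, B, ra, rb
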