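import numpy as np
import pytest

from perturbnet.model import DataBundle, SCGGMLayer, compute_suffstats


def random_spd(q, rng, scale=0.3):
    """Random sparse-ish symmetric positive-definite precision."""
    A = rng.normal(size=(q, q)) * (rng.random((q, q)) < 0.4)
    A = 0.5 * (A + A.T) * scale
    np.fill_diagonal(A, 0.0)
    lam_min = np.linalg.eigvalsh(A)[0]
    np.fill_diagonal(A, 0.5 - lam_min)
    return A


def random_layer(p, q, rng, sparsity=0.3, lam_L=0.1, lam_T=0.1):
    Theta = rng.normal(size=(p, q)) * (rng.random((p, q)) < sparsity)
    return SCGGMLayer(
        Lambda=random_spd(q, rng),
        Theta=Theta,
        lambda_Lambda=lam_L,
        lambda_Theta=lam_T,
    )


def random_stats(p, q, n, rng):
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, q))
    d = DataBundle(X=X, Y=Y, Z=rng.normal(size=(n, 2)))
    s = compute_suffstats(d)
    return s.S_xx, s.S_xy, s.S_yy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_chain(rng):
    """A small random chain model with shared gene ids."""
    from perturbnet.model import ChainModel

    p, q, r = 6, 5, 3
    layer_xy = random_layer(p, q, rng)
    layer_yz = random_layer(q, r, rng)
    layer_yz.input_ids = layer_xy.output_ids
    return ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
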