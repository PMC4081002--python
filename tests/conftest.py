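import numpy as np
import pytest

from spikebm.models import (
    IndependentModel,
    IsingModel,
    IsingParams,
    RBMModel,
    RBMParams,
    SpikeRaster,
    SRBMModel,
    SRBMParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_ising(d, rng, coupling_scale=0.5, bias_loc=-1.0):
    R = rng.normal(0.0, coupling_scale, size=(d, d))
    J = np.triu(R, 1) + np.triu(R, 1).T
    return IsingModel(IsingParams(J, rng.normal(bias_loc, 0.5, d)))


def random_rbm(d, h, rng, scale=0.7):
    return RBMModel(
        RBMParams(
            rng.normal(0.0, scale, (h, d)),
            rng.normal(-0.5, 0.5, h),
            rng.normal(-1.0, 0.5, d),
        )
    )


def random_srbm(d, h, rng, scale=0.7):
    R = rng.normal(0.0, 0.3, size=(d, d))
    J = np.triu(R, 1) + np.triu(R, 1).T
    return SRBMModel(
        SRBMParams(
            IsingParams(J, rng.normal(-1.0, 0.5, d)),
            RBMParams(rng.normal(0.0, scale, (h, d)), rng.normal(-0.5, 0.5, h),
                      np.zeros(d)),
        )
    )


def random_model(kind, d, h, rng):
    if kind == "independent":
        return IndependentModel(rng.normal(-1.0, 0.5, d))
    if kind == "ising":
        return random_ising(d, rng)
    if kind == "rbm":
        return random_rbm(d, h, rng)
    if kind == "srbm":
        return random_srbm(d, h, rng)
    raise ValueError(kind)


@pytest.fixture
def sparse_raster(rng):
    """A small sparse binary raster (8 cells x 400 bins, ~5% active)."""
    return SpikeRaster((rng.random((8, 400)) < 0.05).astype(int), 20.0)
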