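import numpy as np
import pytest

from bmpinfer import CellContext, ModelParameters, ModelShape


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def shape_111():
    return ModelShape(nA=1, nB=1, nL=1)


@pytest.fixture
def unit_params_111():
    """1x1x1 system with K = 1, eps = 1."""
    return ModelParameters(K=np.ones((1, 1, 1)), eps=np.ones((1, 1, 1)))


@pytest.fixture
def unit_context_111():
    return CellContext(A0=[1.0], B0=[1.0], L0=[1.0])


def random_instance(rng, shape: ModelShape):
    """Random parameters/context with K on the prior box and totals over 4 decades."""
    K = 10.0 ** rng.uniform(-4, 2, shape.array_shape)
    eps = 10.0 ** rng.uniform(-2, 1, shape.array_shape)
    params = ModelParameters(K=K, eps=eps)
    context = CellContext(
        A0=10.0 ** rng.uniform(-2, 2, shape.nA),
        B0=10.0 ** rng.uniform(-2, 2, shape.nB),
        L0=10.0 ** rng.uniform(-2, 2, shape.nL),
    )
    return params, context
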