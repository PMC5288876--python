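import numpy as np
import pytest

from cmstab import PRESETS, ModelParams


@pytest.fixture(scope="session")
def fig2():
    """The canonical oscillation preset (simulation-code parameter set)."""
    return PRESETS["fig2_code"]


@pytest.fixture(scope="session")
def text_2017():
    return PRESETS["text_2017"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20170202)


def random_params(rng, n, with_feedback=True) -> list[ModelParams]:
    """Random valid lumped parameter sets spanning several decades."""
    out = []
    for _ in range(n):
        scale = 10.0 ** rng.uniform(-2, 1)
        out.append(ModelParams(
            D1=scale * rng.uniform(0.01, 1.0),
            D2=scale * rng.uniform(0.001, 0.5),
            a=rng.uniform(0.0, 200.0) if with_feedback else 0.0,
            b=rng.uniform(0.0, 200.0) if with_feedback else 0.0,
            c=rng.uniform(0.0, 1.0) if with_feedback else 0.0,
            d=rng.uniform(0.0, 1.0) if with_feedback else 0.0,
            k=scale * rng.uniform(1e-4, 0.1),
            p=scale * rng.uniform(1e-4, 0.1),
            M=rng.uniform(0.01, 1.0),
            W=rng.uniform(0.1, 10.0),
        ))
    return out
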