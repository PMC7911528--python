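import numpy as np
import pytest

from hsvr import pipeline, simulate


@pytest.fixture(scope="session")
def small_study():
    """One fitted HSVR study on a compact synthetic dataset, shared across
    tests that only need *a* fitted model."""
    cset, desc, truth = simulate.generate(simulate.SimConfig(n=160, seed=7))
    y = cset.response()
    result = pipeline.fit_hsvr(desc, y, seed=7, k_folds_cv=5)
    return {"cset": cset, "desc": desc, "y": y, "truth": truth, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pairs(rng, n=20):
    """Random observed/predicted vectors with assorted scales and offsets."""
    y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), n)
    yhat = y * rng.uniform(0.5, 1.5) + rng.normal(0, rng.uniform(0.05, 1), n) + rng.uniform(-1, 1)
    return y, yhat
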