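import numpy as np
import pytest

from motifpoim.wdsvm import TrainedModel


def random_sparse_model(
    rng: np.random.Generator, L: int, degmax: int = 3, per_length: int = 5
) -> TrainedModel:
    """Random model with unique (code, position) features per length."""
    weights = {}
    for l in range(1, degmax + 1):
        ncols = L - l + 1
        total = (4**l) * ncols
        m = int(rng.integers(1, min(per_length, total) + 1))
        flat = rng.choice(total, size=m, replace=False)
        codes = (flat // ncols).astype(np.int64)
        pos = (flat % ncols + 1).astype(np.int64)
        weights[l] = (codes, pos, rng.normal(size=m))
    return TrainedModel(
        weights=weights, bias=float(rng.normal()), degree=degmax, C=1.0, L=L
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
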