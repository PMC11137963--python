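import numpy as np
import pandas as pd
import pytest

from guidenet import IntensityMatrix, MarkerMap, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """8 samples x 5 features with two groups."""
    values = pd.DataFrame(
        rng.normal(size=(8, 5)),
        index=[f"S{i}" for i in range(8)],
        columns=[f"f{j}" for j in range(5)],
    )
    group = pd.Series(["A"] * 4 + ["B"] * 4, index=values.index)
    return OmicsMatrix(values, group=group)


@pytest.fixture
def chain_network():
    """3-node chain with both weights 0.5."""
    w = pd.DataFrame(
        [[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]],
        index=list("abc"),
        columns=list("abc"),
        dtype=float,
    )
    return IntensityMatrix(w)


@pytest.fixture
def simple_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3"],
                "chromosome": ["1", "1", "1"],
                "position": [0.0, 10.0, 20.0],
            }
        )
    )


def random_network(rng, k=6, density=0.4, labels=None) -> IntensityMatrix:
    w = np.abs(rng.normal(size=(k, k)))
    w = (w + w.T) / 2
    mask = rng.random((k, k)) < density
    mask = np.triu(mask, 1)
    w = w * (mask + mask.T)
    np.fill_diagonal(w, 0.0)
    labels = labels or [f"n{i}" for i in range(k)]
    return IntensityMatrix(pd.DataFrame(w, index=labels, columns=labels))
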