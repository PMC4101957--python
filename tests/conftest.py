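import numpy as np
import pytest

from permgsa import ExpressionDataset, GeneSetCollection, Phenotype


@pytest.fixture
def two_group_dataset():
    """12 samples in 2 balanced groups, 20 genes; genes 0-4 shifted +2 in group 1."""
    rng = np.random.default_rng(101)
    values = rng.normal(size=(20, 12))
    values[:5, :6] += 2.0
    ph = Phenotype("categorical", np.array(["1"] * 6 + ["2"] * 6))
    return ExpressionDataset(
        values, [f"g{i}" for i in range(20)], [f"s{i}" for i in range(12)], ph
    )


@pytest.fixture
def three_group_dataset():
    """12 samples in 3 groups, 15 genes; genes 0-4 shifted in group 3."""
    rng = np.random.default_rng(202)
    values = rng.normal(size=(15, 12))
    values[:5, 8:] += 3.0
    ph = Phenotype("categorical", np.array(["1"] * 4 + ["2"] * 4 + ["3"] * 4))
    return ExpressionDataset(
        values, [f"g{i}" for i in range(15)], [f"s{i}" for i in range(12)], ph
    )


@pytest.fixture
def toy_sets():
    """Three sets over a 20-gene universe: signal genes, nulls, mixed."""
    memb = np.zeros((20, 3), dtype=int)
    memb[:5, 0] = 1
    memb[5:12, 1] = 1
    memb[10:16, 2] = 1
    return GeneSetCollection(["signal", "null", "mixed"], memb)


def make_dataset(values, labels, kind="categorical"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionDataset(
        values,
        [f"g{i}" for i in range(m)],
        [f"s{i}" for i in range(n)],
        Phenotype(kind, np.asarray(labels)),
    )
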