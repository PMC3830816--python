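import numpy as np
import pytest

from ctgsvm import FEATURE_NAMES, Dataset, SwarmConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def separable_2d(rng):
    """20 well-separated 2-D points with +-1 labels (margin >> 0)."""
    pos = rng.normal(loc=(2.5, 2.5), scale=0.4, size=(10, 2))
    neg = rng.normal(loc=(-2.5, -2.5), scale=0.4, size=(10, 2))
    X = np.vstack([pos, neg])
    y = np.array([1.0] * 10 + [-1.0] * 10)
    return X, y

@pytest.fixture
def three_class_dataset(rng):
    """Small, clearly separated 3-class dataset (real class names)."""
    centers = {"normal": (0.0, 0.0), "suspect": (6.0, 0.0),
               "pathologic": (0.0, 6.0)}
    X, y = [], []
    for name, c in centers.items():
        X.append(rng.normal(loc=c, scale=0.5, size=(25, 2)))
        y.extend([name] * 25)
    return Dataset(X=np.vstack(X), y=np.array(y, dtype=object),
                   feature_names=("f1", "f2"))


@pytest.fixture
def tiny_swarm():
    """Small PSO budget for fast pipeline tests."""
    return SwarmConfig(n_particles=3, max_iterations=3, seed=0)


def make_ctg_csv(path, rows, label_header="NSP", delimiter=","):
    """Write a CTG-style CSV; rows are (feature_values, nsp_code)."""
    header = delimiter.join([*FEATURE_NAMES, label_header])
    lines = [header]
    for values, code in rows:
        lines.append(delimiter.join([*(str(v) for v in values), str(code)]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def ctg_csv_factory():
    return make_ctg_csv
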