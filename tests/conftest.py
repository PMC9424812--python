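import numpy as np
import pytest

from imrmr import FeatureTable


def random_table(seed: int, n: int = 40, m: int = 8, k: int = 2,
                 n_informative: int | None = None, shift: float = 1.5) -> FeatureTable:
    """Small random table: half the columns class-shifted, half pure noise."""
    rng = np.random.default_rng(seed)
    if n_informative is None:
        n_informative = m // 2
    codes = rng.integers(0, k, size=n)
    # every class present at least twice (splits and CV need it)
    codes[: 2 * k] = np.repeat(np.arange(k), 2)
    X = rng.standard_normal((n, m))
    X[:, :n_informative] += shift * codes[:, None]
    labels = tuple(f"c{i}" for i in range(k))
    return FeatureTable(
        X=X,
        y=np.array([labels[c] for c in codes], dtype=object),
        feature_names=tuple(f"f{j}" for j in range(m)),
        class_labels=labels,
    )


@pytest.fixture
def small_table() -> FeatureTable:
    return random_table(seed=7, n=60, m=10, k=2)


@pytest.fixture
def multiclass_table() -> FeatureTable:
    return random_table(seed=11, n=90, m=12, k=3)


@pytest.fixture
def tiny_csv(tmp_path):
    p = tmp_path / "tiny.csv"
    p.write_text("f1,f2,class\n1.0,2.0,a\n2.0,1.0,b\n3.0,4.0,a\n")
    return p


@pytest.fixture
def tiny_arff(tmp_path):
    p = tmp_path / "tiny.arff"
    p.write_text(
        "@relation tiny\n"
        "@attribute f1 numeric\n"
        "@attribute f2 numeric\n"
        "@attribute class {a,b}\n"
        "@data\n"
        "1.0,2.0,a\n"
        "2.0,1.0,b\n"
        "3.0,4.0,a\n"
        "4.0,3.0,b\n"
    )
    return p
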