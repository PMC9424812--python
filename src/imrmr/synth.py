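"""Synthetic labeled feature tables with planted ground truth.

Every stage of the pipeline is testable without external downloads: the
generator plants three kinds of columns with known roles —

* ``relevant``  : class-conditional Gaussians, unit within-class variance,
  class means spaced ``class_separation`` apart (class k has mean
  k · separation), so relevance is controlled in closed form;
* ``redundant`` : a noisy copy of a relevant column (cycling through them)
  plus N(0, redundancy_noise_sd²) noise — duplicates that a redundancy
  term should push behind their originals;
* ``noise``     : class-independent standard Gaussians.

Defaults (300 samples, 2 classes, 5 relevant + 5 redundant + 40 noise,
separation 2, copy noise sd 0.1) give a table where signal features are
clearly separable from noise by any sensible relevance score while the
duplicates exercise the redundancy machinery. ``make_table1_like`` only
reproduces the N×M×K shapes of seven published benchmark tables with
synthetic content — none of their actual distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .datasets import FeatureTable


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-signal table; M = relevant + redundant + noise."""

    n_samples: int = 300
    n_classes: int = 2
    n_relevant: int = 5
    n_redundant: int = 5
    n_noise: int = 40
    class_separation: float = 2.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_relevant < 1:
            raise ValueError("need at least one relevant feature")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need K >= 2 classes")
        if self.n_samples < 10 * self.n_classes:
            raise ValueError(
                f"need n_samples >= 10·n_classes, got {self.n_samples} for K={self.n_classes}"
            )
        if self.class_separation < 0 or self.redundancy_noise_sd < 0:
            raise ValueError("separation and noise sd must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_relevant + self.n_redundant + self.n_noise

    def to_dict(self) -> dict:
        return asdict(self)


def make_table(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Generate the table and its ground truth. Deterministic per seed.

    Returns ``(table, roles)`` where ``roles`` maps each role name to the
    list of column indices and ``roles['by_column']`` gives the role of
    every column in order (redundant entries also record their source).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_classes
    # near-balanced classes, order shuffled
    counts = [n // k + (1 if i < n % k else 0) for i in range(k)]
    codes = rng.permutation(np.repeat(np.arange(k), counts))

    cols: list[np.ndarray] = []
    names: list[str] = []
    by_column: list[dict] = []
    for j in range(spec.n_relevant):
        col = codes * spec.class_separation + rng.standard_normal(n)
        cols.append(col)
        names.append(f"rel_{j}")
        by_column.append({"role": "relevant"})
    for j in range(spec.n_redundant):
        src = j % spec.n_relevant
        col = cols[src] + spec.redundancy_noise_sd * rng.standard_normal(n)
        cols.append(col)
        names.append(f"red_{j}")
        by_column.append({"role": "redundant", "source": src})
    for j in range(spec.n_noise):
        cols.append(rng.standard_normal(n))
        names.append(f"noise_{j}")
        by_column.append({"role": "noise"})

    labels = tuple(f"c{i}" for i in range(k))
    table = FeatureTable(
        X=np.column_stack(cols),
        y=np.array([labels[c] for c in codes], dtype=object),
        feature_names=tuple(names),
        class_labels=labels,
    )
    roles = {
        "relevant": list(range(spec.n_relevant)),
        "redundant": list(range(spec.n_relevant, spec.n_relevant + spec.n_redundant)),
        "noise": list(range(spec.n_relevant + spec.n_redundant, spec.n_features)),
        "by_column": by_column,
        "spec": spec.to_dict(),
    }
    return table, roles


# (N, M, K) shapes of the seven benchmark tables (train + test recombined)
_TABLE1_SHAPES = {
    "musk": (476, 166, 2),
    "urban": (675, 147, 9),
    "ionosphere": (351, 34, 2),
    "glass": (214, 9, 6),
    "movement": (360, 90, 15),
    "pu": (2700, 103, 9),
    "crane": (343, 75, 7),
}


def make_table1_like(name: str, seed: int = 0) -> SyntheticSpec:
    """A spec matching a benchmark table's N×M×K shape (synthetic content).

    Roughly a fifth of the columns are relevant, a fifth redundant, the
    rest noise — enough planted structure for a selector to act on at the
    real problem size.
    """
    key = name.lower()
    if key not in _TABLE1_SHAPES:
        raise ValueError(f"unknown dataset name {name!r}; known: {sorted(_TABLE1_SHAPES)}")
    n, m, k = _TABLE1_SHAPES[key]
    n_rel = max(1, round(m / 5))
    n_red = min(round(m / 5), m - n_rel)
    return SyntheticSpec(
        n_samples=n,
        n_classes=k,
        n_relevant=n_rel,
        n_redundant=n_red,
        n_noise=m - n_rel - n_red,
        seed=seed,
    )
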