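"""Labeled feature tables: the universal input of the selection pipeline.

A :class:`FeatureTable` is an N×M numeric matrix plus a categorical class
vector. Tables are read from CSV (header row, RFC-4180-style) or ARFF
(WEKA attribute-relation format, numeric attributes + one nominal class).
Class labels are kept as strings; integer encoding happens only where an
operation needs numeric labels (``class_codes``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff


class DataError(ValueError):
    """Invalid data content (NaN cells, bad labels, impossible splits)."""


class SchemaError(DataError):
    """Structural problem: missing class column, duplicate feature names."""


class FormatError(DataError):
    """The file does not parse in the named dialect."""


@dataclass(frozen=True)
class FeatureTable:
    """N samples × M numeric features with a categorical class vector.

    Parameters
    ----------
    X : ndarray of shape (N, M)
        Feature matrix, float.
    y : ndarray of shape (N,)
        Class label per sample, strings drawn from ``class_labels``.
    feature_names : tuple of str
        Unique names, one per column of ``X``.
    class_labels : tuple of str
        The K ≥ 2 distinct labels in their declared order (ARFF header
        order, or first-appearance order for CSV). This order defines the
        integer encoding used wherever a numeric class is needed.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=object)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(str(n) for n in self.feature_names))
        object.__setattr__(self, "class_labels", tuple(str(l) for l in self.class_labels))
        if X.ndim != 2:
            raise SchemaError(f"X must be 2-D, got shape {X.shape}")
        n, m = X.shape
        if n < 2 or m < 1:
            raise SchemaError(f"need N >= 2 samples and M >= 1 features, got N={n}, M={m}")
        if len(self.feature_names) != m:
            raise SchemaError(f"{len(self.feature_names)} feature names for M={m} columns")
        if len(set(self.feature_names)) != m:
            raise SchemaError("feature names must be unique")
        if y.shape != (n,):
            raise SchemaError(f"class vector length {y.shape} does not match N={n}")
        if len(self.class_labels) < 2:
            raise SchemaError("need K >= 2 class labels")
        known = set(self.class_labels)
        bad = sorted({str(v) for v in y} - known)
        if bad:
            raise DataError(f"class values {bad} not in class_labels {self.class_labels}")
        if np.isnan(X).any():
            i, j = map(int, np.argwhere(np.isnan(X))[0])
            raise DataError(
                f"NaN at sample {i}, feature {self.feature_names[j]!r}; missing values are rejected"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def class_codes(self) -> np.ndarray:
        """Integer code of each sample's label in declared-label order."""
        lut = {l: k for k, l in enumerate(self.class_labels)}
        return np.array([lut[str(v)] for v in self.y], dtype=np.int64)

    def select_features(self, indices: Sequence[int]) -> "FeatureTable":
        """Restrict to the given feature columns (order preserved)."""
        idx = list(indices)
        return FeatureTable(
            X=self.X[:, idx],
            y=self.y,
            feature_names=tuple(self.feature_names[i] for i in idx),
            class_labels=self.class_labels,
        )

    def select_samples(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            X=self.X[idx, :],
            y=self.y[idx],
            feature_names=self.feature_names,
            class_labels=self.class_labels,
        )

    def to_frame(self, class_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df[class_column] = [str(v) for v in self.y]
        return df


@dataclass(frozen=True)
class SplitPair:
    """A train/test partition of one table (feature names shared)."""

    train: FeatureTable
    test: FeatureTable
    seed: int
    train_fraction: float

    def __post_init__(self):
        if self.train.feature_names != self.test.feature_names:
            raise SchemaError("train and test must share feature names")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def read_table(
    path: str | Path,
    format: str | None = None,
    class_column: str | int = "class",
    encode_non_numeric: bool = False,
) -> FeatureTable:
    """Read a labeled feature table from CSV or ARFF.

    ``format`` defaults to the file suffix. Non-numeric feature columns are
    rejected unless ``encode_non_numeric`` is set, in which case they are
    label-encoded in sorted-value order. Missing values are always rejected.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path, class_column, encode_non_numeric)
    if fmt == "arff":
        return _read_arff(path, class_column, encode_non_numeric)
    raise FormatError(f"unknown format {fmt!r} (expected csv or arff)")


def _read_csv(path: Path, class_column, encode_non_numeric: bool) -> FeatureTable:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: CSV parse failure: {exc}") from exc
    if isinstance(class_column, int):
        if not (0 <= class_column < df.shape[1]):
            raise SchemaError(f"{path}: class column index {class_column} out of range")
        class_column = df.columns[class_column]
    if class_column not in df.columns:
        raise SchemaError(f"{path}: class column {class_column!r} not found")
    return _frame_to_table(df, str(class_column), encode_non_numeric, class_labels=None)


def _read_arff(path: Path, class_column, encode_non_numeric: bool) -> FeatureTable:
    try:
        data, meta = scipy_arff.loadarff(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: ARFF parse failure: {exc}") from exc
    df = pd.DataFrame(data)
    # scipy returns nominal attributes as bytes
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].map(lambda v: v.decode() if isinstance(v, bytes) else v)
    if isinstance(class_column, int):
        class_column = df.columns[class_column]
    if class_column not in df.columns:
        raise SchemaError(f"{path}: class attribute {class_column!r} not found")
    # nominal class: the @attribute declaration fixes the label order
    labels = None
    attr = meta[str(class_column)]
    if attr[0] == "nominal":
        labels = tuple(attr[1])
    return _frame_to_table(df, str(class_column), encode_non_numeric, class_labels=labels)


def _frame_to_table(
    df: pd.DataFrame,
    class_column: str,
    encode_non_numeric: bool,
    class_labels: tuple[str, ...] | None,
) -> FeatureTable:
    y_raw = df[class_column]
    if y_raw.isna().any():
        i = int(y_raw.isna().idxmax())
        raise DataError(f"missing class value at sample {i}")
    y = np.array([str(v) for v in y_raw], dtype=object)
    feats = df.drop(columns=[class_column])
    cols = []
    for name in feats.columns:
        col = feats[name]
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise DataError(f"missing value at sample {i}, feature {name!r}")
        if not pd.api.types.is_numeric_dtype(col):
            coerced = pd.to_numeric(col, errors="coerce")
            if coerced.isna().any():
                if not encode_non_numeric:
                    raise DataError(
                        f"feature {name!r} is non-numeric; pass encode_non_numeric=True to label-encode"
                    )
                col = pd.Series(pd.Categorical(col.astype(str)).codes, index=col.index)
            else:
                col = coerced
        cols.append(np.asarray(col, dtype=float))
    if class_labels is None:
        seen: dict[str, None] = {}
        for v in y:
            seen.setdefault(str(v), None)
        class_labels = tuple(seen)
    X = np.column_stack(cols) if cols else np.empty((len(y), 0))
    return FeatureTable(X=X, y=y, feature_names=tuple(str(c) for c in feats.columns), class_labels=class_labels)


def write_table(table: FeatureTable, path: str | Path, class_column: str = "class") -> None:
    """Write a table as CSV; round-trips bit-exactly through read_table."""
    # 17 significant digits reproduce any float64 exactly on re-parse
    table.to_frame(class_column).to_csv(path, index=False, float_format="%.17g")


def stratified_split(
    table: FeatureTable,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> SplitPair:
    """Random train/test partition, stratified by class by default.

    The total training size is round(train_fraction · N) (half away from
    zero), apportioned across classes by largest remainder so per-class
    proportions match the global fraction to within rounding. Each class
    keeps at least one sample on each side. Deterministic given ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = table.n_samples
    n_train = _round_half_away(train_fraction * n)
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)

    if not stratify:
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        labels = [str(v) for v in table.y]
        per_class: dict[str, list[int]] = {l: [] for l in table.class_labels}
        for i, l in enumerate(labels):
            per_class[l].append(i)
        per_class = {l: idx for l, idx in per_class.items() if idx}
        for l, idx in per_class.items():
            if len(idx) < 2:
                raise DataError(
                    f"class {l!r} has {len(idx)} sample(s); stratified split needs >= 2 per class"
                )
        # largest-remainder apportionment of n_train across classes,
        # capped so every class keeps >= 1 test sample
        quotas = {l: train_fraction * len(idx) for l, idx in per_class.items()}
        take = {l: min(int(np.floor(q)), len(per_class[l]) - 1) for l, q in quotas.items()}
        take = {l: max(t, 1) for l, t in take.items()}
        remainders = sorted(
            per_class, key=lambda l: (-(quotas[l] - np.floor(quotas[l])), list(per_class).index(l))
        )
        deficit = n_train - sum(take.values())
        for l in list(remainders) * 2:  # two passes suffice; caps may skip classes
            if deficit <= 0:
                break
            if take[l] < len(per_class[l]) - 1:
                take[l] += 1
                deficit -= 1
        for l in reversed(remainders):
            if deficit >= 0:
                break
            if take[l] > 1:
                take[l] -= 1
                deficit += 1
        train_idx_l: list[int] = []
        test_idx_l: list[int] = []
        for l, idx in per_class.items():
            shuffled = rng.permutation(idx)
            train_idx_l.extend(int(i) for i in shuffled[: take[l]])
            test_idx_l.extend(int(i) for i in shuffled[take[l] :])
        train_idx, test_idx = np.array(sorted(train_idx_l)), np.array(sorted(test_idx_l))

    return SplitPair(
        train=table.select_samples(train_idx),
        test=table.select_samples(test_idx),
        seed=seed,
        train_fraction=train_fraction,
    )
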