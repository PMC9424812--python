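"""Feature–class relevance: mutual information, Pearson correlation, and
their α-weighted combination Ic.

Mutual information is the plug-in (histogram) estimate in bits, computed on
the empirical joint distribution after discretization — the standard choice
in the mRMR family, where the continuous densities of the defining integral
are unobservable. Equal-frequency binning with 10 bins is the default; a
feature that already has no more distinct values than bins is passed through
unchanged. The log base only rescales MI uniformly, so rankings that use MI
alone do not depend on it.

The combined per-feature relevance is

    Ic(f; c) = α · I(f; c) + (1 − α) · |corr(f; c)|,   α ∈ [0.1, 1]

with the absolute value taken by default: a strongly anti-correlated feature
is as relevant as a correlated one, and a signed term could cancel genuine
MI relevance. Pearson correlation against a multiclass label uses the
integer code of the class labels in their declared order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import FeatureTable

logger = logging.getLogger(__name__)

ALPHA_MIN, ALPHA_MAX = 0.1, 1.0


@dataclass
class DiscretizationScheme:
    """How continuous features are binned before MI estimation.

    method : 'equal_frequency' (quantile bins) or 'equal_width'
    n_bins : number of bins, >= 2
    edges_ : per-feature interior bin edges, filled by :func:`discretize`
        (``None`` for passthrough columns)
    """

    method: str = "equal_frequency"
    n_bins: int = 10
    edges_: list | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.method not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")


def _discretize_column(col: np.ndarray, scheme: DiscretizationScheme):
    """Return (codes, interior_edges_or_None) for one feature column."""
    distinct = np.unique(col)
    if distinct.size <= scheme.n_bins:
        # already discrete enough: keep the value structure, just recode
        if distinct.size == 1:
            logger.debug("constant feature: single-bin passthrough")
        codes = np.searchsorted(distinct, col)
        return codes.astype(np.int64), None
    if scheme.method == "equal_frequency":
        qs = np.quantile(col, np.linspace(0, 1, scheme.n_bins + 1)[1:-1])
        edges = np.unique(qs)
    else:
        lo, hi = float(col.min()), float(col.max())
        edges = np.linspace(lo, hi, scheme.n_bins + 1)[1:-1]
    codes = np.searchsorted(edges, col, side="right")
    return codes.astype(np.int64), edges


def discretize(X: np.ndarray | FeatureTable, scheme: DiscretizationScheme) -> np.ndarray:
    """Discretize every feature column; returns an integer-code matrix.

    Fitted interior edges are stored on ``scheme.edges_`` (``None`` entries
    for columns passed through unchanged).
    """
    if isinstance(X, FeatureTable):
        X = X.X
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape, dtype=np.int64)
    edges = []
    for j in range(X.shape[1]):
        out[:, j], e = _discretize_column(X[:, j], scheme)
        edges.append(e)
    scheme.edges_ = edges
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    Symmetric, non-negative; I(x; x) is the empirical entropy of x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1-D vectors, got {x.shape} and {y.shape}")
    n = x.size
    if n == 0:
        raise ValueError("empty vectors")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px * py)[nz])))
    return max(mi, 0.0)  # clip the tiny negative round-off


def entropy(x: np.ndarray) -> float:
    """Empirical entropy in bits (plug-in)."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 by convention when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError(f"need equal-length 1-D vectors of length >= 2, got {x.shape}, {y.shape}")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        logger.debug("constant vector in pearson: returning 0 by convention")
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return min(1.0, max(-1.0, r))


def combined_relevance(I: float, corr: float, alpha: float, absolute: bool = True) -> float:
    """α-weighted combination of MI and (absolute) Pearson correlation."""
    if not (ALPHA_MIN <= alpha <= ALPHA_MAX):
        raise ValueError(f"alpha must be in [{ALPHA_MIN}, {ALPHA_MAX}], got {alpha}")
    c = abs(corr) if absolute else corr
    return alpha * I + (1.0 - alpha) * c


@dataclass(frozen=True)
class RelevanceProfile:
    """Per-feature relevance scores at one α, with the induced ranking.

    ``ranking`` sorts features by non-increasing Ic, ties broken by the
    original (lower) index — a stable descending sort.
    """

    alpha: float
    mi: np.ndarray
    corr: np.ndarray
    ic: np.ndarray
    ranking: np.ndarray

    @property
    def n_features(self) -> int:
        return self.ic.size


def relevance_profile(
    table: FeatureTable,
    alpha: float,
    scheme: DiscretizationScheme | None = None,
    absolute_corr: bool = True,
    normalize: bool = False,
    codes: np.ndarray | None = None,
) -> RelevanceProfile:
    """Score every feature against the class and rank by descending Ic.

    ``normalize`` min–max rescales the MI and |corr| vectors across
    features before weighting (off by default: the two scales are combined
    as-is, matching the criterion's definition).
    """
    if not (ALPHA_MIN <= alpha <= ALPHA_MAX):
        raise ValueError(f"alpha must be in [{ALPHA_MIN}, {ALPHA_MAX}], got {alpha}")
    scheme = scheme or DiscretizationScheme()
    if codes is None:
        codes = discretize(table.X, scheme)
    y = table.class_codes
    m = table.n_features
    mi = np.array([mutual_information(codes[:, j], y) for j in range(m)])
    corr = np.array([pearson(table.X[:, j], y.astype(float)) for j in range(m)])
    mag = np.abs(corr) if absolute_corr else corr
    mi_w, mag_w = mi, mag
    if normalize:
        mi_w = _minmax(mi)
        mag_w = _minmax(mag)
    ic = alpha * mi_w + (1.0 - alpha) * mag_w
    ranking = np.argsort(-ic, kind="stable")
    return RelevanceProfile(alpha=alpha, mi=mi, corr=corr, ic=ic, ranking=ranking)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
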