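"""Independent brute-force oracles for the search and estimator routines.

These deliberately avoid the package's own code paths: mutual information
comes from an explicit double sum over the observed joint support (or from
sklearn's contingency-based estimator, converted to bits), correlations
from numpy, and the greedy searches are re-derived step by step from the
written criteria. They share only the discretized codes with the
implementation, since discretization is not what they check.
"""

from collections import Counter
from math import log2

import numpy as np
from sklearn.metrics import mutual_info_score

# Two float routes to the same mathematical score can disagree at ~1e-16,
# so an exact tie must be recognized with a tolerance before the
# lowest-index tie-break is applied.
TIE_ATOL = 1e-9


def argmax_lowest_index(items, score) -> object:
    """The lowest-indexed item whose score is within TIE_ATOL of the max."""
    scored = [(it, score(it)) for it in items]
    best = max(v for _, v in scored)
    return min((it for it, v in scored if v >= best - TIE_ATOL), key=lambda it: _key(it))


def _key(item):
    return item[0] if isinstance(item, tuple) else item


def mi_brute(x, y) -> float:
    """Plug-in MI in bits by explicit summation over the joint support."""
    x, y = list(x), list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pxy = c / n
        total += pxy * log2(pxy / ((px[a] / n) * (py[b] / n)))
    return max(total, 0.0)


def mi_sklearn_bits(x, y) -> float:
    """sklearn's contingency MI (natural log) converted to bits."""
    return float(mutual_info_score(np.asarray(x), np.asarray(y)) / np.log(2))


def entropy_brute(x) -> float:
    n = len(list(x))
    return -sum((c / n) * log2(c / n) for c in Counter(x).values())


def corr_mag_matrix(X) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
    return np.abs(np.nan_to_num(np.atleast_2d(c), nan=0.0))


def corr_mag_to_class(X, y_codes) -> np.ndarray:
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.std() == 0 or np.std(y_codes) == 0:
            out.append(0.0)
        else:
            out.append(abs(float(np.corrcoef(col, y_codes)[0, 1])))
    return np.array(out)


def mrmr_oracle(codes, y_codes) -> list[int]:
    """Step-wise exhaustive classic mRMR: first feature by max I(f;c), then
    argmax of I(f;c) − mean MI with the already-selected features."""
    m = codes.shape[1]
    class_mi = np.array([mi_sklearn_bits(codes[:, j], y_codes) for j in range(m)])
    pair_mi = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            pair_mi[i, j] = pair_mi[j, i] = mi_sklearn_bits(codes[:, i], codes[:, j])
    remaining = list(range(m))
    order = [argmax_lowest_index(remaining, lambda j: class_mi[j])]
    remaining.remove(order[0])
    while remaining:
        best = argmax_lowest_index(remaining, lambda j: class_mi[j] - pair_mi[j, order].mean())
        order.append(best)
        remaining.remove(best)
    return order


def subset_rank_oracle(subsets, codes, X, y_codes, alpha, beta) -> list[int]:
    """Step-wise exhaustive subset ordering per the incremental criterion.

    ``subsets`` is a list of (index, members) pairs. Returns the subset
    indices in selection order. First pick maximizes the accumulated
    per-feature alpha-weighted relevance; later picks maximize D − R where
    D sums beta-weighted MI/|corr| to the class over members and R averages
    the beta-weighted pairwise sums against each selected subset.
    """
    m = codes.shape[1]
    class_mi = np.array([mi_sklearn_bits(codes[:, j], y_codes) for j in range(m)])
    class_corr = corr_mag_to_class(X, y_codes)
    pair_mi = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            pair_mi[i, j] = pair_mi[j, i] = mi_sklearn_bits(codes[:, i], codes[:, j])
    pair_corr = corr_mag_matrix(X)

    def contribution(members):
        return sum(alpha * class_mi[f] + (1 - alpha) * class_corr[f] for f in members)

    def D(members):
        return beta * class_mi[list(members)].sum() + (1 - beta) * class_corr[list(members)].sum()

    def R(members, selected):
        acc = 0.0
        for _, fy in selected:
            s_mi = sum(pair_mi[i, j] for i in members for j in fy if i != j)
            s_co = sum(pair_corr[i, j] for i in members for j in fy if i != j)
            acc += beta * s_mi + (1 - beta) * s_co
        return acc / len(selected)

    pool = list(subsets)
    first = argmax_lowest_index(pool, lambda s: contribution(s[1]))
    order = [first[0]]
    selected = [first]
    pool.remove(first)
    while pool:
        best = argmax_lowest_index(pool, lambda s: D(s[1]) - R(s[1], selected))
        order.append(best[0])
        selected.append(best)
        pool.remove(best)
    return order
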