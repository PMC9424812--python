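"""Subset-level relevance/redundancy scoring and the greedy subset search;
also the classic single-feature mRMR baseline.

A candidate subset Fx is scored against the class by

    D(Fx; c) = β · Σ_i I(f_i; c) + (1 − β) · Σ_i |corr(f_i; c)|

(sums over members, not means) and against the already-selected subsets by

    R(Fx; S) = (1/|S|) · Σ_{Fy in S} [ β · Σ_{i,j} I(f_i; f_j)
                                       + (1 − β) · Σ_{i,j} |corr(f_i; f_j)| ]

with pairs (i, j) over members of Fx × members of Fy (i = j pairs are
excluded defensively; EGM partitions never produce them). The search is
incremental: the first pick maximizes the accumulated per-feature Ic
contribution, every later pick greedily maximizes D − R. Ties break to the
lower group index. Pairwise MI and |corr| are cached in M×M matrices once
per table, which changes complexity, not results.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from .datasets import FeatureTable
from .grouping import CandidateSubset, GroupingPlan
from .relevance import (
    DiscretizationScheme,
    RelevanceProfile,
    discretize,
    mutual_information,
    pearson,
    relevance_profile,
)

BETA_MIN, BETA_MAX = 0.1, 1.0


class PairwiseStats:
    """Per-table cache of feature–class and feature–feature MI / |corr|."""

    def __init__(
        self,
        table: FeatureTable,
        scheme: DiscretizationScheme | None = None,
        absolute_corr: bool = True,
    ):
        self.table = table
        self.scheme = scheme or DiscretizationScheme()
        self.absolute_corr = absolute_corr
        self.codes = discretize(table.X, self.scheme)
        y = table.class_codes
        m = table.n_features
        self.class_mi = np.array([mutual_information(self.codes[:, j], y) for j in range(m)])
        corr = np.array([pearson(table.X[:, j], y.astype(float)) for j in range(m)])
        self.class_corr_mag = np.abs(corr) if absolute_corr else corr

    @cached_property
    def feature_mi(self) -> np.ndarray:
        """Symmetric M×M plug-in MI matrix (diagonal = entropies)."""
        m = self.codes.shape[1]
        out = np.zeros((m, m))
        for i in range(m):
            for j in range(i, m):
                v = mutual_information(self.codes[:, i], self.codes[:, j])
                out[i, j] = out[j, i] = v
        return out

    @cached_property
    def feature_corr_mag(self) -> np.ndarray:
        """M×M Pearson matrix (absolute by default; constants give 0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(self.table.X, rowvar=False)
        c = np.atleast_2d(np.nan_to_num(c, nan=0.0))
        c = np.clip(c, -1.0, 1.0)
        return np.abs(c) if self.absolute_corr else c


def _check_beta(beta: float) -> None:
    if not (BETA_MIN <= beta <= BETA_MAX):
        raise ValueError(f"beta must be in [{BETA_MIN}, {BETA_MAX}], got {beta}")


# Mathematically equal scores can differ by ~1e-16 depending on summation
# order, so the lowest-index tie-break recognizes ties with a tolerance;
# otherwise "determinism" would hinge on float round-off.
TIE_ATOL = 1e-9


def _argmax_low_index(items, score, index):
    """Highest score wins; scores within TIE_ATOL of the max tie, and the
    tied item with the smallest index wins."""
    scored = [(it, score(it)) for it in items]
    best = max(v for _, v in scored)
    return min((it for it, v in scored if v >= best - TIE_ATOL), key=index)


def subset_contribution(subset: CandidateSubset, profile: RelevanceProfile) -> float:
    """Accumulated per-feature Ic over the subset's members."""
    members = np.asarray(subset.members)
    if members.size and members.max() >= profile.n_features:
        raise ValueError(
            f"subset member {members.max()} not in profile of {profile.n_features} features"
        )
    return float(profile.ic[members].sum())


def subset_relevance(subset: CandidateSubset, stats: PairwiseStats, beta: float,
                     normalize: bool = False) -> float:
    """β-weighted class relevance D of a subset (sums over members)."""
    _check_beta(beta)
    members = list(subset.members)
    d = beta * float(stats.class_mi[members].sum()) + (1.0 - beta) * float(
        stats.class_corr_mag[members].sum()
    )
    return d / len(members) if normalize else d


def subset_redundancy(
    subset: CandidateSubset,
    selected: Sequence[CandidateSubset],
    stats: PairwiseStats,
    beta: float,
    normalize: bool = False,
) -> float:
    """Mean β-weighted pairwise redundancy of a subset against the selected
    subsets; the first pick never calls this (``selected`` must be non-empty)."""
    _check_beta(beta)
    if not selected:
        raise ValueError("selected subsets must be non-empty (the first pick has no redundancy)")
    fx = np.asarray(subset.members)
    total = 0.0
    for fy_subset in selected:
        fy = np.asarray(fy_subset.members)
        mi_block = stats.feature_mi[np.ix_(fx, fy)]
        corr_block = stats.feature_corr_mag[np.ix_(fx, fy)]
        # exclude self-pairs if overlapping subsets are supplied
        same = fx[:, None] == fy[None, :]
        n_pairs = same.size - int(same.sum())
        if same.any():
            mi_block = np.where(same, 0.0, mi_block)
            corr_block = np.where(same, 0.0, corr_block)
        term = beta * float(mi_block.sum()) + (1.0 - beta) * float(corr_block.sum())
        if normalize and n_pairs:
            term /= n_pairs
        total += term
    return total / len(selected)


@dataclass(frozen=True)
class SubsetScore:
    """One step of the subset search: D, R and the criterion D − R.

    The first pick is chosen by contribution, so its R and criterion are
    ``None``.
    """

    subset: CandidateSubset
    D: float
    R: float | None
    criterion: float | None
    contribution: float


@dataclass(frozen=True)
class SubsetSequence:
    """Ordered candidate subsets produced by the greedy incremental search."""

    ordered: tuple[SubsetScore, ...]
    alpha: float
    beta: float

    def __len__(self) -> int:
        return len(self.ordered)

    @property
    def subsets(self) -> tuple[CandidateSubset, ...]:
        return tuple(s.subset for s in self.ordered)

    def trace_rows(self) -> list[dict]:
        rows = []
        for step, s in enumerate(self.ordered, start=1):
            rows.append(
                {
                    "step": step,
                    "subset_index": s.subset.index,
                    "size": len(s.subset),
                    "D": s.D,
                    "R": s.R,
                    "criterion": s.criterion,
                    "contribution": s.contribution,
                }
            )
        return rows


def rank_subsets(
    plan: GroupingPlan,
    table: FeatureTable,
    alpha: float,
    beta: float,
    scheme: DiscretizationScheme | None = None,
    stats: PairwiseStats | None = None,
    profile: RelevanceProfile | None = None,
    normalize_subset_sums: bool = False,
) -> SubsetSequence:
    """Order all candidate subsets by the incremental subset criterion.

    Step 1 picks the subset with the largest accumulated Ic contribution;
    every subsequent step picks the remaining subset maximizing D − R
    against the already-selected ones. Ties break to the lower group index.
    Every subset of the plan appears exactly once.
    """
    _check_beta(beta)
    stats = stats or PairwiseStats(table, scheme)
    if profile is None:
        profile = relevance_profile(table, alpha, stats.scheme, codes=stats.codes)
    pool = list(plan.subsets)
    contribs = {s.index: subset_contribution(s, profile) for s in pool}
    d_scores = {s.index: subset_relevance(s, stats, beta, normalize_subset_sums) for s in pool}

    first = _argmax_low_index(pool, lambda s: contribs[s.index], lambda s: s.index)
    ordered = [
        SubsetScore(subset=first, D=d_scores[first.index], R=None, criterion=None,
                    contribution=contribs[first.index])
    ]
    pool.remove(first)
    selected = [first]
    while pool:
        redundancy = {
            s.index: subset_redundancy(s, selected, stats, beta, normalize_subset_sums)
            for s in pool
        }
        best = _argmax_low_index(
            pool, lambda s: d_scores[s.index] - redundancy[s.index], lambda s: s.index
        )
        ordered.append(
            SubsetScore(
                subset=best,
                D=d_scores[best.index],
                R=redundancy[best.index],
                criterion=d_scores[best.index] - redundancy[best.index],
                contribution=contribs[best.index],
            )
        )
        pool.remove(best)
        selected.append(best)
    return SubsetSequence(ordered=tuple(ordered), alpha=alpha, beta=beta)


def classic_mrmr_rank(
    table: FeatureTable,
    scheme: DiscretizationScheme | None = None,
    stats: PairwiseStats | None = None,
) -> np.ndarray:
    """Classic single-feature mRMR ranking (MI only).

    The first feature maximizes I(f; c); each next feature f_j maximizes
    I(f_j; c) − mean over selected f_i of I(f_j; f_i). Ties break to the
    lower feature index; the full permutation is returned.
    """
    stats = stats or PairwiseStats(table, scheme)
    m = table.n_features
    remaining = list(range(m))
    first = _argmax_low_index(remaining, lambda j: stats.class_mi[j], lambda j: j)
    order = [first]
    remaining.remove(first)
    while remaining:
        sel = np.asarray(order)
        best = _argmax_low_index(
            remaining,
            lambda j: stats.class_mi[j] - float(stats.feature_mi[j, sel].mean()),
            lambda j: j,
        )
        order.append(best)
        remaining.remove(best)
    return np.asarray(order)
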