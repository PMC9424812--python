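"""Candidate-subset generation by the equal grouping method (EGM).

Relevance-ranked features are dealt into r near-equal groups with a
serpentine walk: the first pass fills groups 1→r with the top-r features,
the next pass runs r→1, and the direction keeps alternating until every
feature is assigned. The subset size Fc = round(log2 M) mirrors the feature
count a random-forest base tree considers, and r = round(M / Fc). Rounding
is half-away-from-zero. When r·Fc ≠ M the walk simply stops (or keeps
cycling) when features run out, so group sizes never differ by more than
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CandidateSubset:
    """One candidate group: 1-based group index + ordered member features."""

    index: int
    members: tuple[int, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("subset must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in subset")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GroupingPlan:
    """A partition of the M features into r candidate subsets."""

    fc: int
    r: int
    subsets: tuple[CandidateSubset, ...]
    strategy: str = "egm"

    def __post_init__(self):
        all_members = [f for s in self.subsets for f in s.members]
        if len(all_members) != len(set(all_members)):
            raise ValueError("subsets overlap: not a partition")
        sizes = [len(s) for s in self.subsets]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"group sizes {sizes} differ by more than 1")

    @property
    def n_features(self) -> int:
        return sum(len(s) for s in self.subsets)


def subset_size(M: int) -> int:
    """Features per candidate subset: Fc = round(log2 M), at least 1."""
    if M < 2:
        raise ValueError(f"need M >= 2 features, got {M}")
    return max(1, _round_half_away(math.log2(M)))


def subset_count(M: int, fc: int) -> int:
    """Number of candidate subsets: r = round(M / Fc), at least 1."""
    if fc < 1:
        raise ValueError(f"need Fc >= 1, got {fc}")
    if fc > M:
        raise ValueError(f"Fc={fc} exceeds M={M}")
    return max(1, _round_half_away(M / fc))


def egm_partition(ranking: Sequence[int], r: int) -> GroupingPlan:
    """Serpentine-deal the ranked features into r groups.

    ``ranking`` is a permutation of feature indices, best first. Group
    indices along the ranked order follow 1..r, r..1, 1..r, … so adjacent
    ranks land in different groups and each group mixes strong and weak
    features. Deterministic; within a group, members keep assignment order.
    """
    ranking = list(int(f) for f in ranking)
    m = len(ranking)
    if r < 1:
        raise ValueError(f"need r >= 1, got {r}")
    if sorted(ranking) != sorted(set(ranking)):
        raise ValueError("ranking contains duplicates")
    pattern = list(range(r)) + list(range(r - 1, -1, -1))
    groups: list[list[int]] = [[] for _ in range(r)]
    for pos, feat in enumerate(ranking):
        groups[pattern[pos % (2 * r)]].append(feat)
    subsets = tuple(
        CandidateSubset(index=g + 1, members=tuple(members))
        for g, members in enumerate(groups)
        if members
    )
    fc = max(1, _round_half_away(m / r))
    return GroupingPlan(fc=fc, r=len(subsets), subsets=subsets, strategy="egm")


def random_partition(ranking: Sequence[int], r: int, seed: int = 0) -> GroupingPlan:
    """Random near-equal partition (the grouping ablation): shuffle the
    features, then deal them into r groups round-robin. Deterministic per
    seed; same partition invariants as EGM minus the serpentine pattern."""
    ranking = list(int(f) for f in ranking)
    m = len(ranking)
    if r < 1:
        raise ValueError(f"need r >= 1, got {r}")
    rng = np.random.default_rng(seed)
    shuffled = [ranking[i] for i in rng.permutation(m)]
    groups: list[list[int]] = [[] for _ in range(r)]
    for pos, feat in enumerate(shuffled):
        groups[pos % r].append(feat)
    subsets = tuple(
        CandidateSubset(index=g + 1, members=tuple(members))
        for g, members in enumerate(groups)
        if members
    )
    fc = max(1, _round_half_away(m / r))
    return GroupingPlan(fc=fc, r=len(subsets), subsets=subsets, strategy="random")


def make_plan(ranking: Sequence[int], strategy: str = "egm", seed: int = 0) -> GroupingPlan:
    """Compute Fc and r from M and build the partition in one step."""
    m = len(ranking)
    fc = subset_size(m) if m >= 2 else 1
    r = subset_count(m, fc)
    if strategy == "egm":
        return egm_partition(ranking, r)
    if strategy == "random":
        return random_partition(ranking, r, seed=seed)
    raise ValueError(f"unknown grouping strategy {strategy!r}")
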