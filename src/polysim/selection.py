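"""Reaction-selection structures for the exact SSA.

Three interchangeable stores hold the per-channel propensities ``a_j`` and
select the next channel with probability ``a_j / total``:

* :class:`DirectStore` — linear cumulative scan, O(R) per selection;
* :class:`TreeStore` — binary tree of partial sums, O(log R);
* :class:`CRStore` — composition–rejection: channels grouped by the
  power-of-two bracket ``a_j ∈ [2^g, 2^(g+1))``; a group is chosen by
  composition over group sums, the channel inside by rejection, giving O(1)
  cost with respect to the number of channels.

Ties at the selection threshold resolve to the first channel whose
cumulative sum reaches ``u*total`` (the ``>=`` rule), identically in all
three stores.  Stored totals drift by floating-point summation error over
long runs; ``refresh()`` recomputes them exactly and the solver calls it
periodically.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

from .errors import NoReactionError, ValidationError

STRATEGIES = ("direct", "tree", "cr")


def waiting_time_sample(total: float, u: float) -> float:
    """Exponential waiting time τ = −ln(u)/total for u ∈ (0,1)."""
    if total <= 0.0:
        raise NoReactionError("total propensity is zero")
    if not (0.0 < u < 1.0):
        raise ValidationError("u must lie strictly in (0, 1)")
    return -math.log(u) / total


def select_direct(entries, u: float, total: Optional[float] = None):
    """Smallest index whose cumulative propensity reaches u*total."""
    if total is None:
        total = math.fsum(entries)
    if total <= 0.0:
        return None
    threshold = u * total
    cum = 0.0
    last_positive = None
    for i, a in enumerate(entries):
        if a > 0.0:
            cum += a
            last_positive = i
            if cum >= threshold:
                return i
    return last_positive  # only reachable through rounding drift


class DirectStore:
    strategy = "direct"

    def __init__(self, n: int):
        self.entries: List[float] = [0.0] * n
        self.total = 0.0

    def set(self, index: int, propensity: float) -> None:
        if propensity < 0.0:
            raise ValidationError("negative propensity")
        self.total += propensity - self.entries[index]
        self.entries[index] = propensity

    def get(self, index: int) -> float:
        return self.entries[index]

    def select(self, rng):
        return select_direct(self.entries, rng.random(), self.total)

    def refresh(self) -> None:
        self.total = math.fsum(self.entries)


class TreeStore:
    """Complete binary tree over the channel array; internal nodes store
    children sums, so updates walk one root path and selection descends by
    comparing the threshold with left-subtree sums."""

    strategy = "tree"

    def __init__(self, n: int):
        m = 1
        while m < max(n, 1):
            m *= 2
        self._m = m
        self._n = n
        self._tree = [0.0] * (2 * m)

    @property
    def total(self) -> float:
        return self._tree[1]

    @property
    def entries(self) -> List[float]:
        return self._tree[self._m:self._m + self._n]

    def set(self, index: int, propensity: float) -> None:
        if propensity < 0.0:
            raise ValidationError("negative propensity")
        tree = self._tree
        i = index + self._m
        tree[i] = propensity
        i >>= 1
        while i:
            tree[i] = tree[2 * i] + tree[2 * i + 1]
            i >>= 1

    def get(self, index: int) -> float:
        return self._tree[index + self._m]

    def select_with(self, u: float):
        tree = self._tree
        total = tree[1]
        if total <= 0.0:
            return None
        threshold = u * total
        i = 1
        m = self._m
        while i < m:
            left = tree[2 * i]
            if left >= threshold and left > 0.0:
                i = 2 * i
            else:
                threshold -= left
                i = 2 * i + 1
        index = i - m
        if tree[i] <= 0.0:  # rounding drift pushed us onto a dead leaf
            return select_direct(self.entries, u, total)
        return index

    def select(self, rng):
        return self.select_with(rng.random())

    def refresh(self) -> None:
        tree = self._tree
        for i in range(self._m - 1, 0, -1):
            tree[i] = tree[2 * i] + tree[2 * i + 1]


def select_tree(tree: TreeStore, u: float):
    """Tree descent; identical distribution to :func:`select_direct`."""
    return tree.select_with(u)


def cr_group_exponent(propensity: float) -> int:
    """g with propensity ∈ [2^g, 2^(g+1)); negative exponents allowed."""
    if propensity <= 0.0:
        raise ValidationError("exponent undefined for non-positive propensity")
    return math.frexp(propensity)[1] - 1


class CRGroup:
    __slots__ = ("g", "cap", "members", "where", "group_sum")

    def __init__(self, g: int):
        self.g = g
        self.cap = math.ldexp(1.0, g + 1)  # 2^(g+1)
        self.members: List[int] = []
        self.where: Dict[int, int] = {}
        self.group_sum = 0.0

    def add(self, index: int, propensity: float) -> None:
        self.where[index] = len(self.members)
        self.members.append(index)
        self.group_sum += propensity

    def remove(self, index: int, propensity: float) -> None:
        pos = self.where.pop(index)
        last = self.members.pop()
        if last != index:
            self.members[pos] = last
            self.where[last] = pos
        self.group_sum -= propensity


class CRStore:
    """Composition–rejection store.  The group list is scanned linearly for
    the composition step; its length is bounded by log2 of the propensity
    dynamic range, so the per-event cost does not grow with the number of
    channels.  Expected rejections per draw are below 2 because every
    member propensity is at least half the group cap."""

    strategy = "cr"

    def __init__(self, n: int):
        self.entries: List[float] = [0.0] * n
        self.groups: Dict[int, CRGroup] = {}
        self._g: List[Optional[int]] = [None] * n
        self.total = 0.0

    def set(self, index: int, propensity: float) -> None:
        if propensity < 0.0:
            raise ValidationError("negative propensity")
        old = self.entries[index]
        self.entries[index] = propensity
        self.total += propensity - old
        g_old = self._g[index]
        g_new = cr_group_exponent(propensity) if propensity > 0.0 else None
        if g_new == g_old:
            if g_new is not None:
                self.groups[g_new].group_sum += propensity - old
            return
        if g_old is not None:
            grp = self.groups[g_old]
            grp.remove(index, old)
            if not grp.members:
                del self.groups[g_old]
        if g_new is not None:
            grp = self.groups.get(g_new)
            if grp is None:
                grp = self.groups[g_new] = CRGroup(g_new)
            grp.add(index, propensity)
        self._g[index] = g_new

    def get(self, index: int) -> float:
        return self.entries[index]

    def select(self, rng):
        if self.total <= 0.0 or not self.groups:
            return None
        r = rng.random() * self.total
        chosen = None
        cum = 0.0
        for g in sorted(self.groups):
            grp = self.groups[g]
            cum += grp.group_sum
            chosen = grp
            if cum >= r:
                break
        members = chosen.members
        cap = chosen.cap
        entries = self.entries
        n = len(members)
        for _ in range(10000):
            j = members[int(rng.random() * n)]
            if rng.random() * cap < entries[j]:
                return j
        return j  # unreachable for consistent groups; appeases drift

    def refresh(self) -> None:
        self.total = math.fsum(self.entries)
        for grp in self.groups.values():
            grp.group_sum = math.fsum(self.entries[j] for j in grp.members)


def select_composition_rejection(groups: CRStore, rng):
    """Composition over group sums, rejection within the group; marginal
    selection probability of channel j is a_j/total."""
    return groups.select(rng)


def make_store(strategy: str, n: int):
    if strategy == "direct":
        return DirectStore(n)
    if strategy == "tree":
        return TreeStore(n)
    if strategy == "cr":
        return CRStore(n)
    raise ValidationError(f"unknown solver strategy {strategy!r}; "
                          f"choose one of {STRATEGIES}")


def update_channel(store, channel: int, new_propensity: float) -> None:
    """Write one channel's propensity into any store."""
    store.set(channel, new_propensity)
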