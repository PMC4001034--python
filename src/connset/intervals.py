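"""Ordered sets of non-negative integers stored as disjoint closed intervals.

Index sets and GID ranges are overwhelmingly contiguous in practice, so the
canonical representation is a sorted list of closed intervals ``(lo, hi)``
with gaps between them.  The empty set is permitted (a rank may own no
targets); consumers that require non-empty populations enforce that
themselves.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["IntervalSet", "interval_set_from_ids"]


class IntervalSet:
    """An ordered set of non-negative integers as disjoint closed intervals.

    Invariants: intervals are sorted ascending, pairwise disjoint and
    non-adjacent (``hi_k + 1 < lo_{k+1}``), with ``0 <= lo <= hi``.
    Construction normalises arbitrary interval input into this canonical
    form; building from explicit member ids goes through
    :func:`interval_set_from_ids`.
    """

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Iterable[tuple[int, int]] = ()):
        ivs: list[tuple[int, int]] = []
        for lo, hi in intervals:
            lo, hi = int(lo), int(hi)
            if lo < 0:
                raise ValueError(f"negative interval bound: ({lo}, {hi})")
            if hi < lo:
                raise ValueError(f"empty interval ({lo}, {hi}): need lo <= hi")
            ivs.append((lo, hi))
        ivs.sort()
        merged: list[tuple[int, int]] = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        self._ivs = tuple(merged)

    @classmethod
    def range(cls, lo: int, hi_exclusive: int) -> "IntervalSet":
        """Half-open integer range [lo, hi_exclusive) as an interval set."""
        if hi_exclusive <= lo:
            return cls()
        return cls([(lo, hi_exclusive - 1)])

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        return self._ivs

    def __len__(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self._ivs)

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __contains__(self, i: int) -> bool:
        for lo, hi in self._ivs:
            if i < lo:
                return False
            if i <= hi:
                return True
        return False

    def __iter__(self) -> Iterator[int]:
        for lo, hi in self._ivs:
            yield from range(lo, hi + 1)

    def members(self) -> np.ndarray:
        """All members, ascending, as an int64 array."""
        if not self._ivs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(
            [np.arange(lo, hi + 1, dtype=np.int64) for lo, hi in self._ivs]
        )

    def contains_many(self, idx: np.ndarray) -> np.ndarray:
        """Vectorised membership test for an array of indices."""
        idx = np.asarray(idx, dtype=np.int64)
        out = np.zeros(idx.shape, dtype=bool)
        for lo, hi in self._ivs:
            out |= (idx >= lo) & (idx <= hi)
        return out

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: list[tuple[int, int]] = []
        a, b = self._ivs, other._ivs
        ia = ib = 0
        while ia < len(a) and ib < len(b):
            lo = max(a[ia][0], b[ib][0])
            hi = min(a[ia][1], b[ib][1])
            if lo <= hi:
                out.append((lo, hi))
            if a[ia][1] < b[ib][1]:
                ia += 1
            else:
                ib += 1
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self._ivs + other._ivs)

    def min(self) -> int:
        if not self._ivs:
            raise ValueError("empty IntervalSet has no minimum")
        return self._ivs[0][0]

    def max(self) -> int:
        if not self._ivs:
            raise ValueError("empty IntervalSet has no maximum")
        return self._ivs[-1][1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __hash__(self) -> int:
        return hash(self._ivs)

    def __repr__(self) -> str:
        body = ", ".join(f"({lo}, {hi})" for lo, hi in self._ivs)
        return f"IntervalSet([{body}])"


def interval_set_from_ids(ids: Sequence[int]) -> IntervalSet:
    """Compress a list of distinct non-negative ids into closed intervals.

    Maximal contiguous runs of the sorted ids are merged into single
    intervals; the result covers exactly the input ids.  Duplicates and
    negative ids are rejected.
    """
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    arr = np.asarray(sorted(int(x) for x in ids), dtype=np.int64)
    if arr[0] < 0:
        raise ValueError(f"negative id: {arr[0]}")
    dup = arr[1:][arr[1:] == arr[:-1]]
    if dup.size:
        raise ValueError(f"duplicate id: {int(dup[0])}")
    breaks = np.nonzero(arr[1:] != arr[:-1] + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [arr.size - 1]])
    return IntervalSet([(int(arr[s]), int(arr[e])) for s, e in zip(starts, ends)])
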