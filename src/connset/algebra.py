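"""The CSA expression language: elementary masks, set operators, cset.

Elementary masks:

* ``full()`` — every pair; the identity of intersection.
* ``delta()`` — the one-to-one mask δ: (i, j) iff i == j.  Self-connections
  when source and target populations coincide.
* ``random_mask(p, seed)`` — the Erdős–Rényi mask ρ(p): an infinite matrix
  of independent Bernoulli(p) realizations, fixed once realized.  Membership
  is a pure function of (seed, i, j) via a counter-based hash, so every
  rank, window and iteration order sees the same mask.
* ``cross(sources, targets)`` — the Cartesian product of two index sets;
  intersecting with it cuts an infinite mask down to a concrete connection
  matrix.
* ``explicit(pairs)`` — exactly the listed pairs.

Operators (:func:`combine`) are lazy pointwise Boolean combinations —
intersection, union, difference — restricted to arity-0 operands; value
sets attach at the top level via :func:`cset`.  ``rho(p) - delta()`` is the
canonical "random connectivity without self-connections".
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from ._hash import uniform01
from .core import ConnectionSet, Mask, MaskSpec, as_connection_set
from .intervals import IntervalSet

__all__ = [
    "Full",
    "OneToOne",
    "RandomMask",
    "CartesianProduct",
    "ExplicitMask",
    "OperatorNode",
    "full",
    "delta",
    "random_mask",
    "cross",
    "explicit",
    "combine",
    "cset",
]


class Full(Mask):
    """Every pair (i, j): the Cartesian product of two unbounded index
    sets, and the identity element of intersection."""

    def contains_many(self, i, j):
        shape = np.broadcast(np.asarray(i), np.asarray(j)).shape
        return np.ones(shape, dtype=bool)

    def row(self, j, sources):
        return sources

    def exact_size(self, window: MaskSpec) -> int | None:
        return len(window.sources) * len(window.targets)

    def __repr__(self):
        return "full()"


class OneToOne(Mask):
    """The one-to-one mask δ: contains (i, j) iff i == j."""

    def contains_many(self, i, j):
        return np.asarray(i) == np.asarray(j)

    def row(self, j, sources):
        return sources[sources == j]

    def exact_size(self, window: MaskSpec) -> int | None:
        return len(window.sources.intersection(window.targets))

    def __repr__(self):
        return "delta()"


class RandomMask(Mask):
    """The random mask ρ(p): independent Bernoulli(p) per pair.

    The realization is a fixed infinite mask: (i, j) is a member iff the
    counter-based uniform draw keyed by (seed, i, j) falls below p.  Two
    expressions with equal (p, seed) denote the identical mask.
    """

    def __init__(self, p: float, seed: int = 0):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability p must be in [0, 1], got {p}")
        self.p = float(p)
        self.seed = int(seed)

    def contains_many(self, i, j):
        return uniform01(self.seed, i, j) < self.p

    def __repr__(self):
        return f"random_mask(p={self.p}, seed={self.seed})"


class CartesianProduct(Mask):
    """The finite mask I_s × I_t: all pairs of two finite index sets."""

    def __init__(self, sources: IntervalSet, targets: IntervalSet):
        self.sources = sources
        self.targets = targets

    def contains_many(self, i, j):
        return self.sources.contains_many(np.asarray(i)) & self.targets.contains_many(
            np.asarray(j)
        )

    def row(self, j, sources):
        if j not in self.targets:
            return sources[:0]
        return sources[self.sources.contains_many(sources)]

    def exact_size(self, window: MaskSpec) -> int | None:
        ns = len(self.sources.intersection(window.sources))
        nt = len(self.targets.intersection(window.targets))
        return ns * nt

    def __repr__(self):
        return f"cross({self.sources!r}, {self.targets!r})"


class ExplicitMask(Mask):
    """Exactly the listed (source, target) pairs."""

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        pset = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i < 0 or j < 0:
                raise ValueError(f"negative index in pair ({i}, {j})")
            pset.add((i, j))
        self.pairs = frozenset(pset)
        self._by_target: dict[int, np.ndarray] = {}
        for i, j in sorted(pset, key=lambda ij: (ij[1], ij[0])):
            self._by_target.setdefault(j, []).append(i)  # type: ignore[arg-type]
        self._by_target = {
            j: np.asarray(ii, dtype=np.int64) for j, ii in self._by_target.items()
        }

    def contains_many(self, i, j):
        bi = np.broadcast(np.asarray(i), np.asarray(j))
        out = np.fromiter(
            ((int(a), int(b)) in self.pairs for a, b in bi), dtype=bool, count=bi.size
        )
        return out.reshape(bi.shape) if bi.shape else out[0]

    def row(self, j, sources):
        ii = self._by_target.get(int(j))
        if ii is None:
            return sources[:0]
        return ii[np.isin(ii, sources)]

    def exact_size(self, window: MaskSpec) -> int | None:
        return sum(
            1
            for i, j in self.pairs
            if i in window.sources and j in window.targets
        )

    def __repr__(self):
        return f"explicit({sorted(self.pairs, key=lambda ij: (ij[1], ij[0]))!r})"


_OPS = ("intersection", "union", "difference")


class OperatorNode(Mask):
    """Lazy pointwise Boolean combination of two mask expressions."""

    def __init__(self, op: str, left: Mask, right: Mask):
        if op not in _OPS:
            raise ValueError(f"unknown operator {op!r}; expected one of {_OPS}")
        self.op = op
        self.left = left
        self.right = right

    def contains_many(self, i, j):
        a = self.left.contains_many(i, j)
        if self.op == "intersection":
            return a & self.right.contains_many(i, j)
        if self.op == "union":
            return a | self.right.contains_many(i, j)
        return a & ~self.right.contains_many(i, j)

    def row(self, j, sources):
        # Evaluate the left row first, then refine with the right operand on
        # the (usually much smaller) candidate set.
        a = self.left.row(j, sources)
        if self.op == "intersection":
            if a.size == 0:
                return a
            return a[self.right.contains_many(a, np.int64(j))]
        if self.op == "difference":
            if a.size == 0:
                return a
            return a[~self.right.contains_many(a, np.int64(j))]
        b = self.right.row(j, sources)
        return np.union1d(a, b)

    def exact_size(self, window: MaskSpec) -> int | None:
        # Intersecting with a Cartesian product narrows the window; the
        # other operand may then know its exact count.
        if self.op == "intersection":
            for a, b in ((self.left, self.right), (self.right, self.left)):
                if isinstance(a, CartesianProduct):
                    narrowed = MaskSpec(
                        window.sources.intersection(a.sources),
                        window.targets.intersection(a.targets),
                    )
                    return b.exact_size(narrowed)
        return None

    def __repr__(self):
        return f"{self.op}({self.left!r}, {self.right!r})"


def full() -> Mask:
    return Full()


def delta() -> Mask:
    return OneToOne()


def random_mask(p: float, seed: int = 0) -> Mask:
    return RandomMask(p, seed)


def cross(sources: IntervalSet | Iterable[int], targets: IntervalSet | Iterable[int]) -> Mask:
    """Cartesian product mask; accepts IntervalSets or iterables of ids."""
    from .intervals import interval_set_from_ids

    if not isinstance(sources, IntervalSet):
        sources = interval_set_from_ids(list(sources))
    if not isinstance(targets, IntervalSet):
        targets = interval_set_from_ids(list(targets))
    return CartesianProduct(sources, targets)


def explicit(pairs: Iterable[tuple[int, int]]) -> Mask:
    return ExplicitMask(pairs)


def combine(op: str, left, right) -> Mask:
    """Pointwise Boolean combination of two arity-0 expressions.

    Operators act on masks only; value sets attach at top level via
    :func:`cset`.
    """
    for operand in (left, right):
        cs = as_connection_set(operand)
        if cs.arity != 0:
            raise ValueError(
                "operators act on masks; attach value sets at top level "
                f"(operand has arity {cs.arity})"
            )
    lm = as_connection_set(left).mask
    rm = as_connection_set(right).mask
    return OperatorNode(op, lm, rm)


def cset(mask, *value_sets) -> ConnectionSet:
    """Attach value sets to a mask: C = (M, V0, V1, ...).

    With no value sets the mask itself already is the arity-0
    connection-set; this still returns the wrapped form for uniformity.
    """
    cs = as_connection_set(mask)
    if cs.arity != 0:
        raise ValueError("cset expects a bare mask; it already has value sets")
    return ConnectionSet(cs.mask, tuple(value_sets))
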