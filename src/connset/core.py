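"""Core containers: masks, connection-sets, iteration windows, GID maps.

A *mask* is a connection-set of arity 0: a Boolean indicator over pairs
``(i, j)`` of non-negative source/target indices, possibly with infinite
support (the one-to-one mask, the Bernoulli random mask).  A
*connection-set* is a mask plus zero or more value sets; its *arity* is the
number of value sets, i.e. the number of per-connection parameters (weight,
delay, ...).  A bare mask and an arity-0 connection-set are interchangeable
everywhere.

Populations in a simulator are identified by global ids (GIDs); the algebra
works on 0-based consecutive indices.  :class:`GidIndexMap` is the bijection
between the two, in user-supplied list order.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .intervals import IntervalSet

__all__ = [
    "Mask",
    "MaskSpec",
    "Connection",
    "ConnectionSet",
    "GidIndexMap",
    "gid_index_map",
    "mask_contains",
    "as_connection_set",
]


class Mask(abc.ABC):
    """Abstract indicator over (source, target) index pairs.

    Subclasses implement :meth:`contains_many`; everything else (scalar
    membership, per-target row extraction, operator sugar) derives from it.
    Support may be infinite — a mask is only ever *enumerated* after being
    cut to a finite window by a generator.
    """

    arity = 0

    @abc.abstractmethod
    def contains_many(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Vectorised membership: boolean array, broadcasting over i and j."""

    def contains(self, i: int, j: int) -> bool:
        if i < 0 or j < 0:
            raise ValueError(f"indices must be non-negative, got ({i}, {j})")
        return bool(self.contains_many(np.int64(i), np.int64(j)))

    def row(self, j: int, sources: np.ndarray) -> np.ndarray:
        """The sources among `sources` connected to target `j` (ascending)."""
        keep = self.contains_many(sources, np.int64(j))
        return sources[keep]

    def exact_size(self, window: "MaskSpec") -> int | None:
        """Connection count inside `window` when computable without
        iteration; None when unknown a priori."""
        return None

    # Operator sugar; semantics live in algebra.combine.
    def __and__(self, other: "Mask") -> "Mask":
        from .algebra import combine

        return combine("intersection", self, other)

    def __or__(self, other: "Mask") -> "Mask":
        from .algebra import combine

        return combine("union", self, other)

    def __sub__(self, other: "Mask") -> "Mask":
        from .algebra import combine

        return combine("difference", self, other)


@dataclass(frozen=True)
class MaskSpec:
    """A finite iteration window: the source and target indices available
    to one consumer (one rank, in a parallel simulator)."""

    sources: IntervalSet
    targets: IntervalSet


@dataclass(frozen=True)
class Connection:
    """One connection: source index, target index, and the per-connection
    values (length = arity of the generating connection-set)."""

    source: int
    target: int
    values: tuple[float, ...] = ()


@dataclass(frozen=True)
class ConnectionSet:
    """A mask together with its value sets: C = (M, V0, V1, ...)."""

    mask: Mask
    value_sets: tuple = ()

    @property
    def arity(self) -> int:
        return len(self.value_sets)


MaskLike = Union[Mask, ConnectionSet]


def as_connection_set(expr: MaskLike) -> ConnectionSet:
    """Coerce a bare mask to an arity-0 connection-set (the two are
    interchangeable)."""
    if isinstance(expr, ConnectionSet):
        return expr
    if isinstance(expr, Mask):
        return ConnectionSet(expr, ())
    raise TypeError(f"expected Mask or ConnectionSet, got {type(expr).__name__}")


def mask_contains(expr: MaskLike, i: int, j: int) -> bool:
    """Membership query on an arity-0 expression: true iff (i, j) is a
    connection.  Pure; out-of-support queries return False."""
    cs = as_connection_set(expr)
    if cs.arity != 0:
        raise ValueError(f"mask_contains needs an arity-0 expression, got arity {cs.arity}")
    return cs.mask.contains(i, j)


class GidIndexMap:
    """Bijection between 0-based population indices and simulator GIDs.

    Index ``k`` maps to the k-th GID of the user-supplied list; GIDs need
    not be sorted or contiguous.
    """

    __slots__ = ("_gids", "_inv")

    def __init__(self, gids: Sequence[int]):
        gids = [int(g) for g in gids]
        if not gids:
            raise ValueError("gids must be non-empty")
        inv: dict[int, int] = {}
        for k, g in enumerate(gids):
            if g in inv:
                raise ValueError(f"duplicate GID: {g}")
            inv[g] = k
        self._gids = tuple(gids)
        self._inv = inv

    def __len__(self) -> int:
        return len(self._gids)

    def to_gid(self, index: int) -> int:
        return self._gids[index]

    def to_index(self, gid: int) -> int:
        try:
            return self._inv[gid]
        except KeyError:
            raise KeyError(f"GID {gid} is not in this population") from None

    @property
    def gids(self) -> tuple[int, ...]:
        return self._gids

    def index_set(self) -> IntervalSet:
        return IntervalSet.range(0, len(self._gids))


def gid_index_map(gids: Sequence[int]) -> GidIndexMap:
    """Build the index↔GID bijection for a population given as a GID list."""
    return GidIndexMap(gids)
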