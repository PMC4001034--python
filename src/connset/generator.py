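"""The connection-generator protocol: streaming iteration over a
connection-set cut to finite windows, with per-rank partitioning.

A consumer (a simulator kernel) drives the protocol:

1. ``set_mask(window)`` or ``set_masks(windows, local)`` declares which
   source and target indices are available — per rank in the parallel case,
   where target sets are typically disjoint across ranks and every rank is
   handed all masks so a generator may skip non-local work without
   communicating.
2. ``start()`` begins an iteration.
3. ``next()`` yields :class:`~connset.core.Connection` objects in ascending
   (target, source) order — all sources iterated per target — restricted to
   the local window, then returns None forever once exhausted.

``arity()`` is the number of per-connection values; ``size()`` returns the
exact connection count when it is computable without iteration and the
sentinel -1 ("unknown") otherwise.
"""

from __future__ import annotations

import abc
import warnings
from typing import Iterator, Sequence

import numpy as np

from .core import Connection, ConnectionSet, Mask, MaskSpec, as_connection_set

__all__ = ["ConnectionGenerator", "CSAGenerator", "connection_generator"]

#: size() return value meaning "count unknown without iterating".
SIZE_UNKNOWN = -1


class ConnectionGenerator(abc.ABC):
    """Abstract generator protocol any connectivity library can implement;
    consumers depend only on this interface."""

    @abc.abstractmethod
    def arity(self) -> int: ...

    @abc.abstractmethod
    def size(self) -> int: ...

    @abc.abstractmethod
    def set_mask(self, mask: MaskSpec) -> None: ...

    @abc.abstractmethod
    def set_masks(self, masks: Sequence[MaskSpec], local: int) -> None: ...

    @abc.abstractmethod
    def start(self) -> None: ...

    @abc.abstractmethod
    def next(self) -> Connection | None: ...

    def __iter__(self) -> Iterator[Connection]:
        self.start()
        while (c := self.next()) is not None:
            yield c


class CSAGenerator(ConnectionGenerator):
    """Generator over a CSA expression (a mask or connection-set)."""

    def __init__(self, expression: Mask | ConnectionSet):
        self._cs = as_connection_set(expression)
        self._masks: list[MaskSpec] | None = None
        self._local = 0
        self._iter: Iterator[Connection] | None = None
        self._exhausted = False
        self._started = False

    @property
    def expression(self) -> ConnectionSet:
        return self._cs

    def arity(self) -> int:
        return self._cs.arity

    def _require_masks(self) -> MaskSpec:
        if self._masks is None:
            raise RuntimeError("set_mask()/set_masks() must be called first")
        return self._masks[self._local]

    def size(self) -> int:
        window = self._require_masks()
        n = self._cs.mask.exact_size(window)
        return SIZE_UNKNOWN if n is None else n

    def _check_not_mid_iteration(self) -> None:
        if self._started and not self._exhausted:
            raise RuntimeError("cannot change masks mid-iteration")

    def set_mask(self, mask: MaskSpec) -> None:
        self.set_masks([mask], 0)

    def set_masks(self, masks: Sequence[MaskSpec], local: int) -> None:
        self._check_not_mid_iteration()
        masks = list(masks)
        if not masks:
            raise ValueError("need at least one mask")
        if not 0 <= local < len(masks):
            raise ValueError(f"local rank {local} out of range for {len(masks)} masks")
        for a in range(len(masks)):
            for b in range(a + 1, len(masks)):
                if masks[a].targets.intersection(masks[b].targets):
                    warnings.warn(
                        f"target masks of ranks {a} and {b} overlap; "
                        "per-rank streams will not be disjoint",
                        stacklevel=2,
                    )
                    break
            else:
                continue
            break
        self._masks = masks
        self._local = local
        self._iter = None
        self._started = False
        self._exhausted = False

    def _stream(self) -> Iterator[Connection]:
        window = self._masks[self._local]  # type: ignore[index]
        mask = self._cs.mask
        vsets = self._cs.value_sets
        sources = window.sources.members()
        if sources.size == 0:
            return
        for j in window.targets:
            row = mask.row(j, sources)
            for i in row:
                i = int(i)
                vals = tuple(float(v(i, j)) for v in vsets)
                yield Connection(i, int(j), vals)

    def start(self) -> None:
        self._require_masks()
        self._iter = self._stream()
        self._started = True
        self._exhausted = False

    def next(self) -> Connection | None:
        if not self._started:
            raise RuntimeError("start() must be called before next()")
        assert self._iter is not None
        try:
            return next(self._iter)
        except StopIteration:
            self._exhausted = True
            return None


def connection_generator(expression: Mask | ConnectionSet) -> CSAGenerator:
    """Wrap a CSA expression in the generator protocol (masks unset)."""
    return CSAGenerator(expression)
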