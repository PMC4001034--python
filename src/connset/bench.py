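"""Connection-count benchmarks: population-size scaling and strong scaling.

The number of connections produced by an expression fixes the asymptotic
work of any consumer, so these benchmarks measure counts (exact, assertable)
and report wall-clock times as information only.  The random mask at fixed p
creates O(n^2) connections for n neurons — expected log-log slope 2; the
one-to-one mask creates O(n) — expected slope 1.  Following the figure
convention of scaling studies, the slope is the ratio of logarithms of the
last and first data points:

    slope = log(C_last / C_first) / log(x_last / x_first)

Strong scaling partitions the targets of a fixed-size problem over R
emulated ranks; the per-rank counts must always sum to the serial count.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .algebra import delta, random_mask
from .core import Mask
from .intervals import IntervalSet

__all__ = [
    "BenchmarkResult",
    "count_connections",
    "bench_population_scaling",
    "bench_strong_scaling",
    "rank_targets",
]


@dataclass
class BenchmarkResult:
    """A series of (x, connection count, elapsed seconds) plus metadata."""

    label: str
    xs: list[float]
    counts: list[int]
    seconds: list[float]
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        """log(C_last/C_first) / log(x_last/x_first)."""
        return math.log(self.counts[-1] / self.counts[0]) / math.log(
            self.xs[-1] / self.xs[0]
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "x": self.xs,
            "count": self.counts,
            "seconds": self.seconds,
            "slope": self.slope if self.counts[0] > 0 and len(self.xs) > 1 else None,
            **self.extra,
        }


def _source_array(sources) -> np.ndarray:
    if isinstance(sources, IntervalSet):
        return sources.members()
    return np.asarray(sources, dtype=np.int64)


def count_connections(mask: Mask, sources, targets: Iterable[int]) -> int:
    """Count mask members in sources × targets without materializing pairs.

    Counting goes row by row (all sources per target) through the same
    membership functions the generator iterates, so counts always agree
    with the streamed connections.
    """
    src = _source_array(sources)
    if src.size == 0:
        return 0
    return sum(int(mask.row(int(j), src).size) for j in targets)


def bench_population_scaling(
    mask_kind: str, n_values: Sequence[int], seed: int = 0, p: float = 0.1
) -> BenchmarkResult:
    """Count connections over square n × n windows for growing n.

    ``mask_kind`` is "random" (Bernoulli mask with probability p) or
    "one_to_one".
    """
    if len(n_values) < 2 or list(n_values) != sorted(n_values):
        raise ValueError("n_values must be ascending with at least two entries")
    if mask_kind == "random":
        mask = random_mask(p, seed)
        label = f"random(p={p})"
    elif mask_kind == "one_to_one":
        mask = delta()
        label = "one_to_one"
    else:
        raise ValueError(f"unknown mask_kind {mask_kind!r}")

    xs, counts, secs = [], [], []
    for n in n_values:
        idx = np.arange(n, dtype=np.int64)
        t0 = time.perf_counter()
        c = count_connections(mask, idx, range(n))
        secs.append(time.perf_counter() - t0)
        xs.append(float(n))
        counts.append(c)
    return BenchmarkResult(label, xs, counts, secs, seed=seed)


def rank_targets(n: int, n_ranks: int, rank: int) -> np.ndarray:
    """Round-robin partition: the targets j < n with j mod n_ranks == rank."""
    return np.arange(rank, n, n_ranks, dtype=np.int64)


def bench_strong_scaling(
    n: int, p: float, ranks_list: Sequence[int], seed: int = 0
) -> BenchmarkResult:
    """Partition a fixed n-neuron random-mask problem over emulated ranks.

    For every R the per-rank counts are checked to sum exactly to the
    serial count; the result records total counts, per-rank balance and
    per-R elapsed time.
    """
    if list(ranks_list) != sorted(ranks_list) or not ranks_list:
        raise ValueError("ranks_list must be ascending and non-empty")
    mask = random_mask(p, seed)
    src = np.arange(n, dtype=np.int64)
    serial = count_connections(mask, src, range(n))

    xs, counts, secs = [], [], []
    per_rank_all: dict[int, list[int]] = {}
    for R in ranks_list:
        t0 = time.perf_counter()
        per_rank = [
            count_connections(mask, src, rank_targets(n, R, r)) for r in range(R)
        ]
        secs.append(time.perf_counter() - t0)
        total = sum(per_rank)
        if total != serial:
            raise AssertionError(
                f"partition lost connections: R={R} total {total} != serial {serial}"
            )
        per_rank_all[R] = per_rank
        xs.append(float(R))
        counts.append(total)
    return BenchmarkResult(
        f"strong(n={n}, p={p})", xs, counts, secs, seed=seed,
        extra={"serial_count": serial, "per_rank": per_rank_all},
    )
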