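"""Shared test utilities: brute-force oracles and random expression trees.

The brute-force oracle enumerates every pair of a finite window and tests
scalar membership; it is independent of the row-based iteration path that
the generator uses and therefore pins the iteration semantics.
"""

from __future__ import annotations

import numpy as np

from connset import (
    CSAGenerator,
    IntervalSet,
    MaskSpec,
    combine,
    cross,
    cset,
    delta,
    explicit,
    full,
    interval_set_from_ids,
    random_mask,
)
from connset.values import (
    clipped_normal_noise,
    constant,
    distance_delay,
    positions_from_array,
    uniform_random,
)

# The worked-example mask shown as a 5x5 connection matrix.
FIG2A_PAIRS = [(0, 1), (1, 1), (1, 2), (3, 2), (2, 3), (0, 4)]


def window(n: int, m: int | None = None) -> MaskSpec:
    """Square (or n x m) window over indices starting at 0."""
    m = n if m is None else m
    return MaskSpec(IntervalSet.range(0, n), IntervalSet.range(0, m))


def brute_force_pairs(mask, sources, targets) -> list[tuple[int, int]]:
    """Oracle: scalar-membership scan of every pair, in (target, source)
    target-major ascending order."""
    return [(i, j) for j in targets for i in sources if mask.contains(i, j)]


def stream_pairs(expr, win: MaskSpec) -> list[tuple[int, int]]:
    g = CSAGenerator(expr)
    g.set_mask(win)
    return [(c.source, c.target) for c in g]


def stream_connections(expr, win: MaskSpec):
    g = CSAGenerator(expr)
    g.set_mask(win)
    return [(c.source, c.target, c.values) for c in g]


def random_interval_set(rng: np.random.Generator, hi: int = 20) -> IntervalSet:
    k = int(rng.integers(1, 8))
    ids = sorted(rng.choice(hi, size=min(k, hi), replace=False).tolist())
    return interval_set_from_ids(ids)


def random_leaf(rng: np.random.Generator):
    kind = int(rng.integers(5))
    if kind == 0:
        return delta()
    if kind == 1:
        return random_mask(float(rng.uniform()), int(rng.integers(10_000)))
    if kind == 2:
        return cross(random_interval_set(rng), random_interval_set(rng))
    if kind == 3:
        npairs = int(rng.integers(1, 10))
        pairs = {(int(rng.integers(20)), int(rng.integers(20))) for _ in range(npairs)}
        return explicit(pairs)
    return full()


def random_expression(rng: np.random.Generator, depth: int):
    """Random mask expression tree with at most 2**depth - 1 operators."""
    if depth == 0 or rng.uniform() < 0.3:
        return random_leaf(rng)
    op = ["intersection", "union", "difference"][int(rng.integers(3))]
    return combine(op, random_expression(rng, depth - 1), random_expression(rng, depth - 1))


def random_value_sets(rng: np.random.Generator, max_n: int = 2, hi: int = 20):
    """Serializable value sets for round-trip tests."""
    out = []
    for _ in range(int(rng.integers(0, max_n + 1))):
        kind = int(rng.integers(4))
        if kind == 0:
            out.append(constant(float(rng.normal())))
        elif kind == 1:
            lo = float(rng.uniform(-1, 0))
            out.append(uniform_random(lo, lo + float(rng.uniform(0.1, 2)), int(rng.integers(1000))))
        elif kind == 2:
            out.append(clipped_normal_noise(1.0, 0.3, -0.5, 0.5, int(rng.integers(1000))))
        else:
            coords = rng.uniform(0, 10, size=(hi, 2))
            pos = positions_from_array(range(hi), coords)
            out.append(distance_delay(pos, pos, velocity=2.0, base=0.1,
                                      sigma=0.2, lo=-0.05, hi=0.05,
                                      seed=int(rng.integers(1000))))
    return out


def random_serializable(rng: np.random.Generator, depth: int = 3):
    mask = random_expression(rng, depth)
    values = random_value_sets(rng)
    return cset(mask, *values) if values else mask
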