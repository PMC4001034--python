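"""Value sets: pure functions V(i, j) -> real attached to connections.

A value set parameterizes connections — typically a synaptic weight or an
axonal delay.  Random kinds are deterministic given (seed, i, j) through the
same counter-based hash as the random mask, so re-iterating an expression
reproduces the identical values on any rank.

``DistanceDelay`` models distance-dependent conduction delays with additive
noise drawn from a clipped normal distribution:

    V(i, j) = base + ||pos_s(i) - pos_t(j)|| / velocity
              + clip(Normal(0, sigma), lo, hi)

Positions come from a callable index -> coordinates; :func:`load_positions`
reads the TSV convention (columns id, x, y[, z]; ids are 0-based population
indices).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtri

from ._hash import uniform01_scalar

__all__ = [
    "ValueSet",
    "Constant",
    "UniformRandom",
    "ClippedNormalNoise",
    "DistanceDelay",
    "CustomValue",
    "constant",
    "uniform_random",
    "clipped_normal_noise",
    "distance_delay",
    "custom_value",
    "load_positions",
    "positions_from_array",
]


class ValueSet:
    """Base class: a pure evaluator V(i, j) -> float."""

    kind = "custom"

    def __call__(self, i: int, j: int) -> float:
        raise NotImplementedError


class Constant(ValueSet):
    kind = "constant"

    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, i, j):
        return self.value


class UniformRandom(ValueSet):
    """Uniform draw in [low, high), pure in (seed, i, j)."""

    kind = "uniform_random"

    def __init__(self, low: float, high: float, seed: int = 0):
        if high < low:
            raise ValueError(f"need low <= high, got [{low}, {high}]")
        self.low, self.high, self.seed = float(low), float(high), int(seed)

    def __call__(self, i, j):
        u = uniform01_scalar(self.seed, i, j)
        return self.low + (self.high - self.low) * u


def _clipped_normal(seed: int, i: int, j: int, sigma: float, lo: float, hi: float) -> float:
    if sigma == 0.0:
        return min(max(0.0, lo), hi)
    u = uniform01_scalar(seed, i, j)
    # Inverse-CDF transform; guard the open endpoint u = 0.
    z = float(ndtri(max(u, 1e-300))) * sigma
    return min(max(z, lo), hi)


class ClippedNormalNoise(ValueSet):
    """mean + Normal(0, sigma) clipped to [lo, hi], pure in (seed, i, j)."""

    kind = "clipped_normal_noise"

    def __init__(self, mean: float, sigma: float, lo: float, hi: float, seed: int = 0):
        if hi < lo:
            raise ValueError(f"need lo <= hi, got [{lo}, {hi}]")
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        self.mean, self.sigma = float(mean), float(sigma)
        self.lo, self.hi, self.seed = float(lo), float(hi), int(seed)

    def __call__(self, i, j):
        return self.mean + _clipped_normal(self.seed, i, j, self.sigma, self.lo, self.hi)


PositionFn = Callable[[int], np.ndarray]


class DistanceDelay(ValueSet):
    """Distance-dependent delay with clipped-normal noise."""

    kind = "distance_delay"

    def __init__(
        self,
        pos_source: PositionFn,
        pos_target: PositionFn,
        velocity: float,
        base: float = 0.0,
        sigma: float = 0.0,
        lo: float = 0.0,
        hi: float = 0.0,
        seed: int = 0,
    ):
        if velocity <= 0:
            raise ValueError(f"velocity must be > 0, got {velocity}")
        if base < 0:
            raise ValueError(f"base must be >= 0, got {base}")
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        if hi < lo:
            raise ValueError(f"need lo <= hi, got [{lo}, {hi}]")
        self.pos_source, self.pos_target = pos_source, pos_target
        self.velocity, self.base = float(velocity), float(base)
        self.sigma, self.lo, self.hi = float(sigma), float(lo), float(hi)
        self.seed = int(seed)

    def __call__(self, i, j):
        ps = np.asarray(self.pos_source(i), dtype=float)
        pt = np.asarray(self.pos_target(j), dtype=float)
        d = float(np.linalg.norm(ps - pt))
        noise = _clipped_normal(self.seed, i, j, self.sigma, self.lo, self.hi)
        return self.base + d / self.velocity + noise


class CustomValue(ValueSet):
    """Arbitrary user evaluator; not serializable to XML."""

    kind = "custom"

    def __init__(self, fn: Callable[[int, int], float]):
        self.fn = fn

    def __call__(self, i, j):
        return float(self.fn(i, j))


def constant(value: float) -> Constant:
    return Constant(value)


def uniform_random(low: float, high: float, seed: int = 0) -> UniformRandom:
    return UniformRandom(low, high, seed)


def clipped_normal_noise(
    mean: float, sigma: float, lo: float, hi: float, seed: int = 0
) -> ClippedNormalNoise:
    return ClippedNormalNoise(mean, sigma, lo, hi, seed)


def distance_delay(
    pos_source: PositionFn,
    pos_target: PositionFn,
    velocity: float,
    base: float = 0.0,
    sigma: float = 0.0,
    lo: float = 0.0,
    hi: float = 0.0,
    seed: int = 0,
) -> DistanceDelay:
    return DistanceDelay(pos_source, pos_target, velocity, base, sigma, lo, hi, seed)


def custom_value(fn: Callable[[int, int], float]) -> CustomValue:
    return CustomValue(fn)


class _TablePositions:
    """index -> coordinate vector backed by a dense table; raises a
    descriptive KeyError for indices without a position."""

    def __init__(self, table: dict[int, np.ndarray]):
        self.table = table

    def __call__(self, index: int) -> np.ndarray:
        try:
            return self.table[int(index)]
        except KeyError:
            raise KeyError(f"no position for index {index}") from None

    def items(self):
        return sorted(self.table.items())


def positions_from_array(ids: Sequence[int], coords: np.ndarray) -> _TablePositions:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return _TablePositions({int(k): coords[n] for n, k in enumerate(ids)})


def load_positions(path: str | Path) -> _TablePositions:
    """Read a position table: TSV with header, columns id, x, y[, z]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if "id" not in df.columns or len(cols) < 2:
        raise ValueError(f"{path}: expected columns id, x, y[, z]; got {list(df.columns)}")
    return positions_from_array(df["id"].to_numpy(), df[cols].to_numpy())
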