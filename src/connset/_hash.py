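"""Counter-based uniform random numbers keyed by (seed, i, j).

The random mask rho(p) is defined as a fixed (infinite) realization of
independent Bernoulli variables, one per index pair.  Membership must be a
pure function of the seed and the pair, identical no matter which process,
rank, window or iteration order queries it.  A stateful stream generator
cannot provide that, so we hash the counter (seed, i, j) through a 64-bit
avalanche mix (the splitmix64 finalizer applied three times, folding in the
seed, the source index and the target index) and map the result to [0, 1).

All functions are vectorised over numpy uint64 arrays; integer overflow is
the intended modular arithmetic.
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U53 = np.uint64(11)
_INV53 = 1.0 / float(1 << 53)


def _mix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """splitmix64 finalizer: a full-avalanche bijection on 64-bit words."""
    x = (x ^ (x >> np.uint64(30))) * _MIX1
    x = (x ^ (x >> np.uint64(27))) * _MIX2
    return x ^ (x >> np.uint64(31))


def uniform01(seed: int, i, j):
    """Uniform variates in [0, 1), pure in (seed, i, j).

    `i` and `j` may be scalars or broadcastable integer arrays; the result
    follows numpy broadcasting.  Distinct (seed, i, j) triples give
    independent-looking draws; equal triples always give the same draw.
    """
    with np.errstate(over="ignore"):
        si = np.asarray(i, dtype=np.uint64)
        sj = np.asarray(j, dtype=np.uint64)
        h = _mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) + _GOLDEN)
        h = _mix64(h ^ (si + _GOLDEN))
        h = _mix64(h ^ (sj + _GOLDEN))
        out = (h >> _U53) * _INV53
    return out


def uniform01_scalar(seed: int, i: int, j: int) -> float:
    return float(uniform01(seed, i, j))
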