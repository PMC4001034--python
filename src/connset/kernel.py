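"""A mock simulator kernel exercising the connect path of the generator
protocol: populations of GIDs, a connection table, and an in-process
multi-rank driver.

``cg_connect`` mirrors how a parallel point-neuron simulator consumes a
connection generator: every neuron carries a global id (GID); GIDs are
mapped to contiguous 0-based indices for the algebra; targets are
partitioned over ranks (round-robin by default); each rank receives all
rank masks plus its own rank number, iterates only its local targets, and
stores each yielded (i, j, values) as (source GID, target GID, named
parameters).  Because the random mask's realization is a pure function of
(seed, i, j), the union of the per-rank tables is independent of how many
ranks participated.

No neuron dynamics, devices or synapse models exist here — only the
connection-building path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import GidIndexMap, MaskSpec, gid_index_map
from .generator import ConnectionGenerator
from .intervals import IntervalSet, interval_set_from_ids

__all__ = [
    "Population",
    "StoredConnection",
    "Network",
    "cg_connect",
    "rank_of_target",
    "network_stats",
]


@dataclass(frozen=True)
class Population:
    """An ordered set of unique positive GIDs; order defines the index map."""

    gids: tuple[int, ...]

    def __init__(self, gids: Sequence[int]):
        gids = tuple(int(g) for g in gids)
        if not gids:
            raise ValueError("population must be non-empty")
        if any(g <= 0 for g in gids):
            raise ValueError("GIDs must be positive integers")
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate GIDs in population")
        object.__setattr__(self, "gids", gids)

    def __len__(self) -> int:
        return len(self.gids)

    def index_map(self) -> GidIndexMap:
        return gid_index_map(self.gids)


@dataclass(frozen=True)
class StoredConnection:
    source_gid: int
    target_gid: int
    params: tuple[tuple[str, float], ...] = ()

    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


def rank_of_target(j: int, n_ranks: int) -> int:
    """Round-robin target-to-rank assignment: j mod n_ranks."""
    if n_ranks < 1:
        raise ValueError(f"n_ranks must be >= 1, got {n_ranks}")
    return j % n_ranks


RankAssign = Callable[[int, int], int]


class Network:
    """The kernel's store: populations plus the connection table."""

    def __init__(self, strict_arity: bool = False):
        #: reproduce the historical restriction that only arities 0 and 2
        #: (bare mask, or weight+delay) are accepted.
        self.strict_arity = strict_arity
        self.connections: list[StoredConnection] = []
        self.populations: list[Population] = []

    def add_population(self, gids: Sequence[int]) -> Population:
        pop = Population(gids)
        self.populations.append(pop)
        return pop

    def connect(self, source_gid: int, target_gid: int, params: Mapping[str, float]) -> None:
        self.connections.append(
            StoredConnection(int(source_gid), int(target_gid), tuple(sorted(params.items())))
        )

    # -- export -----------------------------------------------------------

    def to_table(self):
        """Connection table as a pandas DataFrame: source_gid, target_gid,
        then one column per named parameter."""
        import pandas as pd

        names = sorted({k for c in self.connections for k, _ in c.params})
        rows = [
            {"source_gid": c.source_gid, "target_gid": c.target_gid, **c.param_dict()}
            for c in self.connections
        ]
        return pd.DataFrame(rows, columns=["source_gid", "target_gid", *names])

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def adjacency(self):
        """0/1 adjacency over GIDs as scipy COO (multi-edges collapse)."""
        import scipy.sparse as sp

        if not self.connections:
            return sp.coo_matrix((0, 0))
        src = np.array([c.source_gid for c in self.connections])
        tgt = np.array([c.target_gid for c in self.connections])
        n = int(max(src.max(), tgt.max())) + 1
        m = sp.coo_matrix((np.ones(len(src)), (src, tgt)), shape=(n, n))
        m.sum_duplicates()
        m.data[:] = 1.0
        return m

    def write_mtx(self, path: str | Path) -> None:
        import scipy.io

        scipy.io.mmwrite(str(path), self.adjacency())


def cg_connect(
    net: Network,
    g: ConnectionGenerator,
    pre: Population | Sequence[int],
    post: Population | Sequence[int],
    param_map: Mapping[str, int] | None = None,
    n_ranks: int = 1,
    rank_assign: RankAssign = rank_of_target,
) -> Network:
    """Create the connections between `pre` and `post` prescribed by `g`.

    `param_map` maps parameter names (e.g. "weight", "delay") to positions
    in the generator's value vector.  Ranks are emulated in-process: for
    each rank the full mask list (source mask = all pre indices everywhere;
    target masks = the rank partition of post indices) is handed to the
    generator together with the local rank, and the local stream is stored.
    The resulting table is independent of ``n_ranks``.
    """
    if not isinstance(pre, Population):
        pre = Population(pre)
    if not isinstance(post, Population):
        post = Population(post)
    param_map = dict(param_map or {})
    if n_ranks < 1:
        raise ValueError(f"n_ranks must be >= 1, got {n_ranks}")

    arity = g.arity()
    if net.strict_arity and arity not in (0, 2):
        raise ValueError(f"strict mode supports only arities 0 and 2, got {arity}")
    if len(set(param_map.values())) != len(param_map):
        raise ValueError("param_map indices must be distinct")
    for name, idx in param_map.items():
        if not 0 <= idx < arity:
            raise ValueError(
                f"param_map entry {name!r} -> {idx} out of range for arity {arity}"
            )

    pre_map, post_map = pre.index_map(), post.index_map()
    source_set = pre_map.index_set()
    rank_targets: list[list[int]] = [[] for _ in range(n_ranks)]
    for j in range(len(post)):
        r = rank_assign(j, n_ranks)
        if not 0 <= r < n_ranks:
            raise ValueError(f"rank assignment returned {r} for {n_ranks} ranks")
        rank_targets[r].append(j)
    masks = [
        MaskSpec(source_set, interval_set_from_ids(ts) if ts else IntervalSet())
        for ts in rank_targets
    ]

    per_rank: list[list[StoredConnection]] = []
    for r in range(n_ranks):
        g.set_masks(masks, r)
        rows: list[StoredConnection] = []
        for c in g:
            params = {name: c.values[idx] for name, idx in param_map.items()}
            rows.append(
                StoredConnection(
                    pre_map.to_gid(c.source),
                    post_map.to_gid(c.target),
                    tuple(sorted(params.items())),
                )
            )
        per_rank.append(rows)

    # Arrival order per rank, merged by rank id: deterministic table order.
    for rows in per_rank:
        net.connections.extend(rows)
    if pre not in net.populations:
        net.populations.append(pre)
    if post is not pre and post not in net.populations:
        net.populations.append(post)
    return net


def network_stats(net: Network) -> dict:
    """Summary of the stored table: counts, in-degrees, parameter ranges,
    multi-edge flags.  Pure — recomputed from the table."""
    in_degree: dict[int, int] = {}
    seen: dict[tuple[int, int], int] = {}
    pranges: dict[str, list[float]] = {}
    for c in net.connections:
        in_degree[c.target_gid] = in_degree.get(c.target_gid, 0) + 1
        seen[(c.source_gid, c.target_gid)] = seen.get((c.source_gid, c.target_gid), 0) + 1
        for k, v in c.params:
            lohi = pranges.setdefault(k, [v, v])
            lohi[0] = min(lohi[0], v)
            lohi[1] = max(lohi[1], v)
    dup = {pair: n for pair, n in seen.items() if n > 1}
    return {
        "total": len(net.connections),
        "in_degree": in_degree,
        "param_ranges": {k: tuple(v) for k, v in pranges.items()},
        "multi_edges": dup,
    }
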