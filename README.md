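# connset

Declarative generation of neuronal-network connectivity: a Python
implementation of the connection-set algebra (CSA) together with the generic
*connection-generator* protocol that lets any simulator-like consumer stream
connections out of a CSA expression — including per-rank partitioning for
parallel consumers, an XML serialization with a pluggable parser registry, a
mock simulator kernel, and a CLI that materializes edge lists.

## Who this is for

Computational neuroscientists and simulator developers who want network
connectivity specified once, declaratively and simulator-independently, and
realized reproducibly at any scale and on any number of processes.

## The algebra

A *connection-set* is a set of connections between a source population
`P_s` and a target population `P_t`, addressed by 0-based indices
`(i, j) ∈ I_s × I_t`, plus zero or more *value sets* `V_k(i, j) → ℝ`
(weight, delay, …): `C = (M, V₀, V₁, …)`. The number of value sets is the
*arity*; an arity-0 connection-set is a *mask* — a Boolean indicator
`M(i, j)` that may have infinite support. Elementary masks include

- `δ` (`delta()`) — the one-to-one mask, `(i, j) ∈ δ ⟺ i = j`;
- `ρ(p)` (`random_mask(p, seed)`) — Erdős–Rényi connectivity: an infinite
  matrix of independent Bernoulli(p) realizations, *fixed once realized*.
  Membership is a pure counter-based hash of `(seed, i, j)`, so every
  process, window and iteration order sees the same mask;
- `I_s × I_t` (`cross(...)`) — the Cartesian product of two finite index
  sets; intersecting with it cuts an infinite mask to a concrete matrix;
- explicit pair lists and the `full` mask.

Masks combine with intersection, union and set difference (`&`, `|`, `-`):
`ρ(p) − δ` is random connectivity without self-connections.

A `CSAGenerator` cuts an expression to finite per-rank windows and streams
`Connection(source, target, values)` in ascending (target, source) order —
all sources per target. Target windows partition over ranks, so the union of
per-rank streams always equals the serial stream.

## Worked example

```python
import connset as cs

# Fixed random connectivity without self-connections, with weights and
# distance-independent constant delays:
expr = cs.cset(cs.random_mask(0.1, seed=42) - cs.delta(),
               cs.constant(0.5), cs.constant(1.5))

net = cs.cg_connect(cs.Network(), cs.CSAGenerator(expr),
                    pre=range(1, 101), post=range(1, 101),
                    param_map={"weight": 0, "delay": 1}, n_ranks=4)
stats = cs.network_stats(net)
print(stats["total"], stats["param_ranges"])
```

prints

```
999 {'delay': (1.5, 1.5), 'weight': (0.5, 0.5)}
```

— 999 connections realized among 100·100 − 100 = 9,900 eligible pairs
(expectation 990, within sampling error of p = 0.1), each carrying the two
named parameters. Re-running with `n_ranks=1` stores the identical table:
rank partitioning never changes the realized network.

The same expression round-trips through XML (`cs.serialize` /
`cs.from_xml`), e.g. to prepare connectivity on one machine and realize it
on another; see `docs/xml-dialect.md`.

From the shell:

```sh
connset build --expr oneToOne --sources 0:7 --targets 0:7 --out edges.tsv
# wrote 7 connections (arity 0, seed 0) to edges.tsv [tsv]
connset bench-pop --mask random --p 0.1 --n 100,1000,10000
```

Range specs on the CLI are half-open (`0:7` = indices 0–6).

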