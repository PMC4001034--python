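# The connset XML dialect

Version 1.0. Root tag `CSA` with a mandatory `version` attribute and
exactly one child: either a mask expression or a `connectionSet`. Unknown
elements and missing required attributes are errors — nothing is silently
dropped. Seeds are mandatory on every random node so a document realizes
the identical network on any machine.

The parser registry maps root tags to parsers; the builtin dialect is
registered under `CSA`. Other description languages can be installed with
`select_cg_implementation(tag, module)` where `module` is an importable
plugin exposing `register_parsers(registry)`.

## Mask elements

| element | attributes / children | meaning |
|---|---|---|
| `<oneToOne/>` | — | the one-to-one mask δ |
| `<full/>` | — | every pair |
| `<random p="0.1" seed="0"/>` | `p`, `seed` (required) | Bernoulli mask ρ(p) |
| `<cross>` | `<sources>`, `<targets>`, each holding `<interval lo=".." hi=".."/>` (closed) | Cartesian product of two index sets |
| `<explicit>` | `<c i=".." j=".."/>` per pair | exactly the listed pairs |
| `<intersection>`, `<union>`, `<difference>` | exactly two mask children | pointwise Boolean combination |

## Connection-sets with values

```xml
<CSA version="1.0">
  <connectionSet>
    <mask>
      <difference>
        <random p="0.1" seed="42"/>
        <oneToOne/>
      </difference>
    </mask>
    <valueSet kind="constant" value="0.5"/>
    <valueSet kind="uniform_random" low="1.0" high="2.0" seed="7"/>
  </connectionSet>
</CSA>
```

`valueSet` kinds and their attributes:

- `constant` — `value`
- `uniform_random` — `low`, `high`, `seed`
- `clipped_normal_noise` — `mean`, `sigma`, `lo`, `hi`, `seed`
- `distance_delay` — `velocity`, `base`, `sigma`, `lo`, `hi`, `seed`, plus
  two children `<positions role="source">` / `<positions role="target">`
  holding `<pos id=".." x=".." y=".." [z=".."]/>` rows (ids are 0-based
  population indices)

Custom Python value sets do not serialize; `serialize` raises naming the
offending node. `from_xml` / `from_xml_file` return a generator with masks
unset; round-trip identity (identical streamed connections and values on
any finite window) is part of the test suite.
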