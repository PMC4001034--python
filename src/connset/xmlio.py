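"""XML serialization of connection-set expressions and the parser registry.

Expressions serialize to a small, fully specified XML dialect (see
docs/xml-dialect.md) whose root tag is ``CSA``.  Seeds are mandatory on
every random node, so a document parsed on another machine reproduces the
identical connectivity.  Parsing returns a :class:`CSAGenerator` with masks
unset — the consumer supplies the windows.

A :class:`ParserRegistry` maps XML root tags to parser callables, so
several connectivity description languages can coexist in one process;
``select_cg_implementation(tag, library)`` imports `library` as a plugin
module and lets it register its parsers (the in-process analogue of
dynamically loading a connectivity-generating shared library).
"""

from __future__ import annotations

import importlib
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Callable

from .algebra import (
    CartesianProduct,
    ExplicitMask,
    Full,
    OneToOne,
    OperatorNode,
    RandomMask,
)
from .core import ConnectionSet, Mask, as_connection_set
from .generator import CSAGenerator
from .intervals import IntervalSet
from .values import (
    ClippedNormalNoise,
    Constant,
    DistanceDelay,
    UniformRandom,
    ValueSet,
    positions_from_array,
)

__all__ = [
    "serialize",
    "from_xml",
    "from_xml_file",
    "ParserRegistry",
    "default_registry",
    "register_parsers",
    "select_cg_implementation",
    "SerializationError",
]

DIALECT_VERSION = "1.0"
ROOT_TAG = "CSA"


class SerializationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# serialization


def _intervals_el(tag: str, ivs: IntervalSet) -> ET.Element:
    el = ET.Element(tag)
    for lo, hi in ivs.intervals:
        ET.SubElement(el, "interval", lo=str(lo), hi=str(hi))
    return el


def _mask_el(mask: Mask) -> ET.Element:
    if isinstance(mask, OneToOne):
        return ET.Element("oneToOne")
    if isinstance(mask, Full):
        return ET.Element("full")
    if isinstance(mask, RandomMask):
        return ET.Element("random", p=repr(mask.p), seed=str(mask.seed))
    if isinstance(mask, CartesianProduct):
        el = ET.Element("cross")
        el.append(_intervals_el("sources", mask.sources))
        el.append(_intervals_el("targets", mask.targets))
        return el
    if isinstance(mask, ExplicitMask):
        el = ET.Element("explicit")
        for i, j in sorted(mask.pairs, key=lambda ij: (ij[1], ij[0])):
            ET.SubElement(el, "c", i=str(i), j=str(j))
        return el
    if isinstance(mask, OperatorNode):
        el = ET.Element(mask.op)
        el.append(_mask_el(mask.left))
        el.append(_mask_el(mask.right))
        return el
    raise SerializationError(f"mask node {mask!r} is not serializable")


def _positions_el(role: str, pos_fn) -> ET.Element:
    items = getattr(pos_fn, "items", None)
    if items is None:
        raise SerializationError(
            f"distance_delay {role} positions are a custom callable; only "
            "table-backed positions serialize"
        )
    el = ET.Element("positions", role=role)
    for idx, xyz in items():
        attrs = {"id": str(idx)}
        for name, v in zip(("x", "y", "z"), xyz):
            attrs[name] = repr(float(v))
        ET.SubElement(el, "pos", **attrs)
    return el


def _value_el(v: ValueSet) -> ET.Element:
    if isinstance(v, Constant):
        return ET.Element("valueSet", kind="constant", value=repr(v.value))
    if isinstance(v, UniformRandom):
        return ET.Element(
            "valueSet", kind="uniform_random",
            low=repr(v.low), high=repr(v.high), seed=str(v.seed),
        )
    if isinstance(v, ClippedNormalNoise):
        return ET.Element(
            "valueSet", kind="clipped_normal_noise",
            mean=repr(v.mean), sigma=repr(v.sigma),
            lo=repr(v.lo), hi=repr(v.hi), seed=str(v.seed),
        )
    if isinstance(v, DistanceDelay):
        el = ET.Element(
            "valueSet", kind="distance_delay",
            velocity=repr(v.velocity), base=repr(v.base), sigma=repr(v.sigma),
            lo=repr(v.lo), hi=repr(v.hi), seed=str(v.seed),
        )
        el.append(_positions_el("source", v.pos_source))
        el.append(_positions_el("target", v.pos_target))
        return el
    raise SerializationError(
        f"value set of kind {getattr(v, 'kind', '?')!r} ({type(v).__name__}) "
        "is not serializable"
    )


def serialize(expr: Mask | ConnectionSet) -> str:
    """Serialize a connection-set expression to XML text (deterministic)."""
    cs = as_connection_set(expr)
    root = ET.Element(ROOT_TAG, version=DIALECT_VERSION)
    if cs.arity == 0:
        root.append(_mask_el(cs.mask))
    else:
        top = ET.SubElement(root, "connectionSet")
        m = ET.SubElement(top, "mask")
        m.append(_mask_el(cs.mask))
        for v in cs.value_sets:
            top.append(_value_el(v))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# parsing


def _attr(el: ET.Element, name: str, conv=float):
    if name not in el.attrib:
        raise SerializationError(f"<{el.tag}> is missing required attribute {name!r}")
    return conv(el.attrib[name])


def _parse_intervals(el: ET.Element) -> IntervalSet:
    ivs = []
    for child in el:
        if child.tag != "interval":
            raise SerializationError(f"unknown element <{child.tag}> in <{el.tag}>")
        ivs.append((_attr(child, "lo", int), _attr(child, "hi", int)))
    return IntervalSet(ivs)


def _parse_positions(el: ET.Element):
    ids, coords = [], []
    for child in el:
        if child.tag != "pos":
            raise SerializationError(f"unknown element <{child.tag}> in <positions>")
        ids.append(_attr(child, "id", int))
        xyz = [_attr(child, "x"), _attr(child, "y")]
        if "z" in child.attrib:
            xyz.append(float(child.attrib["z"]))
        coords.append(xyz)
    return positions_from_array(ids, coords)


def _parse_mask(el: ET.Element) -> Mask:
    tag = el.tag
    if tag == "oneToOne":
        return OneToOne()
    if tag == "full":
        return Full()
    if tag == "random":
        return RandomMask(_attr(el, "p"), _attr(el, "seed", int))
    if tag == "cross":
        parts = {c.tag: c for c in el}
        if set(parts) != {"sources", "targets"}:
            raise SerializationError("<cross> needs <sources> and <targets>")
        return CartesianProduct(
            _parse_intervals(parts["sources"]), _parse_intervals(parts["targets"])
        )
    if tag == "explicit":
        pairs = []
        for c in el:
            if c.tag != "c":
                raise SerializationError(f"unknown element <{c.tag}> in <explicit>")
            pairs.append((_attr(c, "i", int), _attr(c, "j", int)))
        return ExplicitMask(pairs)
    if tag in ("intersection", "union", "difference"):
        children = list(el)
        if len(children) != 2:
            raise SerializationError(f"<{tag}> needs exactly two children")
        return OperatorNode(tag, _parse_mask(children[0]), _parse_mask(children[1]))
    raise SerializationError(f"unknown mask element <{tag}>")


def _parse_value(el: ET.Element) -> ValueSet:
    kind = el.attrib.get("kind")
    if kind == "constant":
        return Constant(_attr(el, "value"))
    if kind == "uniform_random":
        return UniformRandom(_attr(el, "low"), _attr(el, "high"), _attr(el, "seed", int))
    if kind == "clipped_normal_noise":
        return ClippedNormalNoise(
            _attr(el, "mean"), _attr(el, "sigma"),
            _attr(el, "lo"), _attr(el, "hi"), _attr(el, "seed", int),
        )
    if kind == "distance_delay":
        pos = {c.attrib.get("role"): _parse_positions(c) for c in el if c.tag == "positions"}
        if set(pos) != {"source", "target"}:
            raise SerializationError(
                "distance_delay valueSet needs <positions role='source'> and "
                "<positions role='target'>"
            )
        return DistanceDelay(
            pos["source"], pos["target"],
            velocity=_attr(el, "velocity"), base=_attr(el, "base"),
            sigma=_attr(el, "sigma"), lo=_attr(el, "lo"), hi=_attr(el, "hi"),
            seed=_attr(el, "seed", int),
        )
    raise SerializationError(f"unknown valueSet kind {kind!r}")


def _parse_csa(root: ET.Element) -> CSAGenerator:
    children = list(root)
    if len(children) != 1:
        raise SerializationError(f"<{ROOT_TAG}> needs exactly one child expression")
    top = children[0]
    if top.tag == "connectionSet":
        mask_el = None
        values = []
        for c in top:
            if c.tag == "mask":
                kids = list(c)
                if mask_el is not None or len(kids) != 1:
                    raise SerializationError("<connectionSet> needs exactly one <mask>")
                mask_el = kids[0]
            elif c.tag == "valueSet":
                values.append(_parse_value(c))
            else:
                raise SerializationError(f"unknown element <{c.tag}> in <connectionSet>")
        if mask_el is None:
            raise SerializationError("<connectionSet> is missing its <mask>")
        return CSAGenerator(ConnectionSet(_parse_mask(mask_el), tuple(values)))
    return CSAGenerator(_parse_mask(top))


# ---------------------------------------------------------------------------
# registry

Parser = Callable[[ET.Element], CSAGenerator]


class ParserRegistry:
    """Maps XML root tags (identifying description languages) to parsers."""

    def __init__(self):
        self._parsers: dict[str, Parser] = {}

    def register(self, tag: str, parser: Parser) -> None:
        if tag in self._parsers and self._parsers[tag] is not parser:
            warnings.warn(f"replacing previously registered parser for tag {tag!r}")
        self._parsers[tag] = parser

    def parser_for(self, tag: str) -> Parser:
        try:
            return self._parsers[tag]
        except KeyError:
            raise SerializationError(
                f"no parser registered for root tag {tag!r}; "
                f"registered tags: {sorted(self._parsers) or 'none'}"
            ) from None

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(sorted(self._parsers))


default_registry = ParserRegistry()


def register_parsers(registry: ParserRegistry) -> None:
    """Plugin entry point for the builtin dialect."""
    registry.register(ROOT_TAG, _parse_csa)


register_parsers(default_registry)


def select_cg_implementation(
    tag: str, library: str, registry: ParserRegistry | None = None
) -> None:
    """Associate root tag `tag` with the parser plugin `library`.

    `library` is an importable module exposing ``register_parsers(registry)``.
    """
    registry = registry if registry is not None else default_registry
    try:
        mod = importlib.import_module(library)
    except ImportError as e:
        raise SerializationError(f"parser plugin {library!r} not found: {e}") from e
    hook = getattr(mod, "register_parsers", None)
    if hook is None:
        raise SerializationError(
            f"plugin {library!r} lacks the register_parsers(registry) entry point"
        )
    hook(registry)
    registry.parser_for(tag)  # raises if the plugin did not provide the tag


def from_xml(xml: str, registry: ParserRegistry | None = None) -> CSAGenerator:
    """Parse an XML serialization of a connection generator.

    Dispatches on the document's root tag via the registry; the returned
    generator has no masks set.
    """
    registry = registry if registry is not None else default_registry
    root = ET.fromstring(xml)  # ET.ParseError carries line/column
    return registry.parser_for(root.tag)(root)


def from_xml_file(fname: str | Path, registry: ParserRegistry | None = None) -> CSAGenerator:
    """Same as :func:`from_xml`, reading the stream from a file."""
    return from_xml(Path(fname).read_text(encoding="utf-8"), registry)
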