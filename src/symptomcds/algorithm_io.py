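"""Reading and writing algorithm definition documents (XML).

The dialect mirrors the in-memory model one-to-one: ``algorithm``, ``node``,
``branch``, ``predicate``, ``terminal``, ``recommendation-ref``, with the
data dictionary embedded.  Documents are validated against the shipped XSD
before interpretation, so malformed input fails with an error naming the
offending element rather than surfacing deep inside the builder.
"""

from __future__ import annotations

from decimal import Decimal
from importlib import resources
from pathlib import Path

from lxml import etree

from .algorithm_model import (
    Branch,
    BooleanPredicate,
    CategoryPredicate,
    DataDictionary,
    DecisionAlgorithm,
    DecisionNode,
    Interval,
    IntervalPredicate,
    MedClassPredicate,
    TerminalNode,
    VariableSpec,
)

__all__ = ["algorithm_to_xml", "algorithm_from_xml", "load_algorithm", "save_algorithm", "ParseError"]


class ParseError(ValueError):
    """Malformed algorithm document; message names the offending element."""


def _schema() -> etree.XMLSchema:
    with resources.files("symptomcds.schemas").joinpath("algorithm.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def _dec(text: str) -> Decimal:
    return Decimal(text)


def algorithm_to_xml(alg: DecisionAlgorithm) -> bytes:
    """Deterministic serialization (dictionary first, nodes in declaration order)."""
    root = etree.Element("algorithm", name=alg.name, root=alg.root)
    dict_el = etree.SubElement(root, "dictionary")
    for spec in alg.dictionary:
        attrs = {"name": spec.name, "kind": spec.kind}
        if spec.kind == "numeric":
            attrs |= {
                "lower": str(spec.lower),
                "upper": str(spec.upper),
                "resolution": str(spec.resolution),
            }
        if spec.units:
            attrs["units"] = spec.units
        attrs["source"] = spec.source
        if spec.inputs:
            attrs["inputs"] = " ".join(spec.inputs)
        var_el = etree.SubElement(dict_el, "variable", **attrs)
        for cat in spec.categories:
            etree.SubElement(var_el, "category").text = cat

    for nid, node in alg.nodes.items():
        if isinstance(node, TerminalNode):
            t_el = etree.SubElement(root, "terminal", id=nid)
            for rid in node.recommendations:
                etree.SubElement(t_el, "recommendation-ref", id=rid)
            continue
        n_el = etree.SubElement(root, "node", id=nid, variable=node.variable)
        for b in node.branches:
            b_el = etree.SubElement(n_el, "branch", target=b.target)
            p_el = etree.SubElement(b_el, "predicate", variable=b.predicate.variable)
            p = b.predicate
            if isinstance(p, IntervalPredicate):
                etree.SubElement(
                    p_el,
                    "interval",
                    lower=str(p.interval.lower),
                    upper=str(p.interval.upper),
                    **{
                        "lower-closed": str(p.interval.lower_closed).lower(),
                        "upper-closed": str(p.interval.upper_closed).lower(),
                    },
                )
            elif isinstance(p, CategoryPredicate):
                c_el = etree.SubElement(p_el, "categories")
                for cat in sorted(p.categories):
                    etree.SubElement(c_el, "category").text = cat
            elif isinstance(p, BooleanPredicate):
                etree.SubElement(p_el, "boolean", value=str(p.value).lower())
            elif isinstance(p, MedClassPredicate):
                etree.SubElement(
                    p_el,
                    "medication-class",
                    present=str(p.present).lower(),
                    **{"class": p.drug_class},
                )
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _parse_variable(el: etree._Element) -> VariableSpec:
    kind = el.get("kind")
    kwargs = dict(
        name=el.get("name"),
        kind=kind,
        units=el.get("units", ""),
        source=el.get("source", "patient-reported"),
        inputs=tuple(el.get("inputs", "").split()) if el.get("inputs") else (),
    )
    if kind == "numeric":
        kwargs |= dict(
            lower=_dec(el.get("lower")),
            upper=_dec(el.get("upper")),
            resolution=_dec(el.get("resolution")),
        )
    cats = tuple(c.text for c in el.findall("category"))
    if cats:
        kwargs["categories"] = cats
    return VariableSpec(**kwargs)


def _parse_predicate(el: etree._Element):
    variable = el.get("variable")
    iv = el.find("interval")
    if iv is not None:
        return IntervalPredicate(
            variable,
            Interval(
                _dec(iv.get("lower")),
                _dec(iv.get("upper")),
                iv.get("lower-closed", "true") == "true",
                iv.get("upper-closed", "true") == "true",
            ),
        )
    cats = el.find("categories")
    if cats is not None:
        return CategoryPredicate(variable, frozenset(c.text for c in cats.findall("category")))
    bl = el.find("boolean")
    if bl is not None:
        return BooleanPredicate(variable, bl.get("value") == "true")
    mc = el.find("medication-class")
    if mc is not None:
        return MedClassPredicate(variable, mc.get("class"), mc.get("present", "true") == "true")
    raise ParseError(f"predicate for {variable!r} carries no recognised test element")


def algorithm_from_xml(
    data: bytes, dictionary: DataDictionary | None = None
) -> DecisionAlgorithm:
    """Parse and schema-validate an algorithm document.

    If ``dictionary`` is given it replaces the embedded one (so shipped
    content can share the standard dictionary object).
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as e:
        raise ParseError(f"not well-formed XML: {e}") from e
    schema = _schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise ParseError(f"schema violation at line {err.line}: {err.message}")

    if dictionary is None:
        dict_el = root.find("dictionary")
        if dict_el is None:
            raise ParseError("element 'algorithm' lacks a dictionary and none was supplied")
        dictionary = DataDictionary(_parse_variable(v) for v in dict_el.findall("variable"))

    nodes: dict[str, DecisionNode | TerminalNode] = {}
    for el in root:
        if el.tag == "node":
            branches = tuple(
                Branch(_parse_predicate(b.find("predicate")), b.get("target"))
                for b in el.findall("branch")
            )
            nodes[el.get("id")] = DecisionNode(el.get("id"), el.get("variable"), branches)
        elif el.tag == "terminal":
            nodes[el.get("id")] = TerminalNode(
                el.get("id"),
                tuple(r.get("id") for r in el.findall("recommendation-ref")),
            )
    return DecisionAlgorithm(
        name=root.get("name"), root=root.get("root"), nodes=nodes, dictionary=dictionary
    )


def save_algorithm(alg: DecisionAlgorithm, path: str | Path) -> None:
    Path(path).write_bytes(algorithm_to_xml(alg))


def load_algorithm(path: str | Path, dictionary: DataDictionary | None = None) -> DecisionAlgorithm:
    return algorithm_from_xml(Path(path).read_bytes(), dictionary=dictionary)
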