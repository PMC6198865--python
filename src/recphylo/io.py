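"""Reading and writing recPhyloXML documents.

The reader is namespace-tolerant (it matches on local tag names) and runs in
one of two modes: *strict*, where any deviation from the grammar is an error,
and *lenient*, where recoverable deviations (unknown phyloXML child tags,
nameless geography areas, an explicit ``rooted="false"``) become warnings.
Unknown clade children are preserved verbatim as opaque blobs and re-emitted
on write, so foreign phyloXML annotations survive a round trip.

The writer emits UTF-8 with two-space indentation and a fixed attribute order
(``speciesLocation`` / ``destinationSpecies`` first), so identical documents
always serialize to identical bytes.
"""

from __future__ import annotations

import io as _stdio
import os
import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

import dendropy

from recphylo.model import (
    Event,
    EventSequence,
    EventType,
    GeneNode,
    GeographyAnnotation,
    ModelError,
    RecPhyloDocument,
    SpeciesNode,
    make_event,
)

__all__ = [
    "ParseOptions",
    "ParseIssue",
    "RecPhyloParseError",
    "read_recphylo",
    "write_recphylo",
    "recphylo_to_string",
    "read_geography",
    "read_plain_tree",
    "PlainNode",
]


class RecPhyloParseError(ValueError):
    """Unrecoverable deviation from the recPhyloXML grammar."""


@dataclass
class ParseOptions:
    strictness: str = "strict"  # "strict" | "lenient"
    keep_unknown_tags: bool = True

    @property
    def strict(self) -> bool:
        return self.strictness == "strict"


@dataclass
class ParseIssue:
    severity: str  # "error" | "warning"
    xml_path: str
    message: str


_EVENT_TAGS = {t.value for t in EventType}

# phyloXML clade children the model represents directly.
_KNOWN_CLADE_CHILDREN = {
    "name",
    "branch_length",
    "confidence",
    "eventsRec",
    "geography",
    "clade",
}


def _localname(elem) -> str:
    tag = elem.tag
    if not isinstance(tag, str):
        return ""  # comments / processing instructions
    return tag.rsplit("}", 1)[-1]


def _children(elem):
    return [c for c in elem if isinstance(c.tag, str)]


def _find(elem, name):
    return [c for c in _children(elem) if _localname(c) == name]


def _path(elem) -> str:
    try:
        return elem.getroottree().getpath(elem)
    except Exception:  # pragma: no cover
        return "?"


class _Parser:
    def __init__(self, options: ParseOptions):
        self.options = options
        self.issues: List[ParseIssue] = []

    def error(self, elem, message: str):
        self.issues.append(ParseIssue("error", _path(elem), message))
        raise RecPhyloParseError(f"{_path(elem)}: {message}")

    def deviation(self, elem, message: str):
        """Recoverable in lenient mode; fatal in strict mode."""
        if self.options.strict:
            self.error(elem, message)
        self.issues.append(ParseIssue("warning", _path(elem), message))

    # -- geography -------------------------------------------------------

    def read_geography(self, geo_elem) -> Tuple[GeographyAnnotation, ...]:
        areas = []
        for area in _find(geo_elem, "area"):
            name = None
            description = value = source = kml = None
            for child in _children(area):
                local = _localname(child)
                text = (child.text or "").strip()
                if local == "name":
                    name = text
                elif local == "description":
                    description = text
                elif local == "value":
                    try:
                        value = float(text)
                    except ValueError:
                        self.deviation(child, f"non-numeric area value {text!r}")
                elif local == "source":
                    source = text
                elif local == "kml":
                    # opaque payload: inner content preserved byte-verbatim
                    kml = (child.text or "") + "".join(
                        etree.tostring(g, encoding="unicode") for g in child
                    )
                else:
                    self.deviation(child, f"unknown area child <{local}>")
            if name is None:
                self.deviation(area, "area without a name")
                name = "<unnamed area>"
            areas.append(
                GeographyAnnotation(
                    area_name=name,
                    description=description,
                    value=value,
                    source=source,
                    kml_payload=kml,
                )
            )
        return tuple(areas)

    # -- events ----------------------------------------------------------

    def read_events(self, events_elem) -> EventSequence:
        events = []
        for ev_elem in _children(events_elem):
            local = _localname(ev_elem)
            if local not in _EVENT_TAGS:
                self.error(ev_elem, f"unknown event tag <{local}>")
            try:
                events.append(make_event(local, dict(ev_elem.attrib)))
            except ModelError as exc:
                self.error(ev_elem, str(exc))
        try:
            return EventSequence(events)
        except ModelError as exc:
            self.error(events_elem, str(exc))
            raise  # unreachable

    # -- clades ----------------------------------------------------------

    def _clade_common(self, clade_elem):
        name = ""
        branch_length = None
        support = None
        geography: Tuple[GeographyAnnotation, ...] = ()
        extras: List[str] = []
        events_elem = None
        child_elems = []
        if "branch_length" in clade_elem.attrib:
            branch_length = float(clade_elem.attrib["branch_length"])
        for child in _children(clade_elem):
            local = _localname(child)
            if local == "name":
                name = (child.text or "").strip()
            elif local == "branch_length":
                branch_length = float((child.text or "").strip())
            elif local == "confidence":
                try:
                    support = float((child.text or "").strip())
                except ValueError:
                    self.deviation(child, "non-numeric confidence")
            elif local == "eventsRec":
                events_elem = child
            elif local == "geography":
                geography = self.read_geography(child)
            elif local == "clade":
                child_elems.append(child)
            else:
                self.deviation(child, f"unknown clade child <{local}>")
                if self.options.keep_unknown_tags:
                    extras.append(
                        etree.tostring(child, encoding="unicode").strip()
                    )
        return name, branch_length, support, geography, tuple(extras), events_elem, child_elems

    def read_gene_clade(self, clade_elem) -> GeneNode:
        (name, branch_length, support, geography, extras,
         events_elem, child_elems) = self._clade_common(clade_elem)
        if events_elem is None:
            self.error(clade_elem, "gene clade without <eventsRec>")
        events = self.read_events(events_elem)
        children = tuple(self.read_gene_clade(c) for c in child_elems)
        try:
            return GeneNode(
                name=name,
                events=events,
                children=children,
                branch_length=branch_length,
                support=support,
                geography=geography,
                extras=extras,
            )
        except ModelError as exc:
            self.error(clade_elem, str(exc))
            raise  # unreachable

    def read_species_clade(self, clade_elem) -> SpeciesNode:
        (name, branch_length, support, geography, extras,
         events_elem, child_elems) = self._clade_common(clade_elem)
        if events_elem is not None:
            self.deviation(clade_elem, "species clade carries <eventsRec>")
        if support is not None:
            extras = extras + (f"<confidence>{support:g}</confidence>",)
        children = tuple(self.read_species_clade(c) for c in child_elems)
        try:
            return SpeciesNode(
                name=name,
                children=children,
                branch_length=branch_length,
                geography=geography,
                extras=extras,
            )
        except ModelError as exc:
            self.error(clade_elem, str(exc))
            raise  # unreachable

    def read_phylogeny(self, wrapper_elem, kind: str):
        """``wrapper_elem`` is <spTree> or <recGeneTree>; returns root clade."""
        phylos = _find(wrapper_elem, "phylogeny")
        if len(phylos) != 1:
            self.error(wrapper_elem, f"<{_localname(wrapper_elem)}> must contain exactly one <phylogeny>")
        phylo = phylos[0]
        if kind == "gene" and phylo.get("rooted", "true").lower() != "true":
            self.deviation(phylo, 'reconciled gene trees are always rooted; expected rooted="true"')
        clades = _find(phylo, "clade")
        if len(clades) != 1:
            self.error(phylo, "<phylogeny> must contain exactly one root <clade>")
        if kind == "gene":
            return self.read_gene_clade(clades[0])
        return self.read_species_clade(clades[0])

    def read_document(self, root) -> RecPhyloDocument:
        if _localname(root) != "recPhylo":
            self.error(root, f"root tag must be <recPhylo>, got <{_localname(root)}>")
        sp_elems = _find(root, "spTree")
        gene_elems = _find(root, "recGeneTree")
        for child in _children(root):
            if _localname(child) not in ("spTree", "recGeneTree"):
                self.deviation(child, f"unknown recPhylo child <{_localname(child)}>")
        if len(sp_elems) > 1:
            self.error(root, f"at most one species tree allowed, found {len(sp_elems)}")
        if not gene_elems:
            self.error(root, "a recPhylo document requires at least one gene tree")
        species_tree = self.read_phylogeny(sp_elems[0], "species") if sp_elems else None
        gene_trees = tuple(self.read_phylogeny(g, "gene") for g in gene_elems)
        try:
            return RecPhyloDocument(gene_trees=gene_trees, species_tree=species_tree)
        except ModelError as exc:
            self.error(root, str(exc))
            raise  # unreachable


def _as_bytes(source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, str):
        if source.lstrip().startswith("<"):
            return source.encode("utf-8")
        return open(source, "rb").read()
    if isinstance(source, os.PathLike):
        return open(source, "rb").read()
    data = source.read()
    return data.encode("utf-8") if isinstance(data, str) else data


def read_recphylo(
    source, options: Optional[ParseOptions] = None
) -> Tuple[RecPhyloDocument, List[ParseIssue]]:
    """Parse a recPhyloXML document.

    ``source`` may be a path, an XML string/bytes, or an open stream.
    Returns the document and the list of parse issues; unrecoverable
    deviations raise :class:`RecPhyloParseError`.
    """
    options = options or ParseOptions()
    data = _as_bytes(source)
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise RecPhyloParseError(f"malformed XML: {exc}") from exc
    parser = _Parser(options)
    doc = parser.read_document(root)
    return doc, parser.issues


# ---------------------------------------------------------------------------
# Writer

def _fmt_float(x: float) -> str:
    return repr(float(x))


def _event_to_xml(event: Event) -> str:
    tag = event.event_type.value
    parts = [tag]
    if event.species_location is not None:
        parts.append(f"speciesLocation={quoteattr(event.species_location)}")
    if event.destination_species is not None:
        parts.append(f"destinationSpecies={quoteattr(event.destination_species)}")
    if event.confidence is not None:
        parts.append(f"confidence={quoteattr(_fmt_float(event.confidence))}")
    if event.time_slice is not None:
        parts.append(f"timeSlice={quoteattr(str(event.time_slice))}")
    if event.gene_name is not None:
        parts.append(f"geneName={quoteattr(event.gene_name)}")
    return f"<{' '.join(parts)}></{tag}>"


def _geography_lines(geography, indent: str) -> List[str]:
    lines = [f"{indent}<geography>"]
    for area in geography:
        lines.append(f"{indent}  <area>")
        lines.append(f"{indent}    <name>{escape(area.area_name)}</name>")
        if area.description is not None:
            lines.append(f"{indent}    <description>{escape(area.description)}</description>")
        if area.value is not None:
            lines.append(f"{indent}    <value>{_fmt_float(area.value)}</value>")
        if area.source is not None:
            lines.append(f"{indent}    <source>{escape(area.source)}</source>")
        if area.kml_payload is not None:
            lines.append(f"{indent}    <kml>{area.kml_payload}</kml>")
        lines.append(f"{indent}  </area>")
    lines.append(f"{indent}</geography>")
    return lines


def _clade_lines(node, indent: str, is_gene: bool) -> List[str]:
    lines = [f"{indent}<clade>"]
    inner = indent + "  "
    if node.name:
        lines.append(f"{inner}<name>{escape(node.name)}</name>")
    if node.branch_length is not None:
        lines.append(f"{inner}<branch_length>{_fmt_float(node.branch_length)}</branch_length>")
    if is_gene and node.support is not None:
        lines.append(f"{inner}<confidence>{_fmt_float(node.support)}</confidence>")
    if node.geography:
        lines.extend(_geography_lines(node.geography, inner))
    if is_gene:
        lines.append(f"{inner}<eventsRec>")
        for event in node.events:
            lines.append(f"{inner}  {_event_to_xml(event)}")
        lines.append(f"{inner}</eventsRec>")
    for blob in node.extras:
        lines.append(f"{inner}{blob}")
    for child in node.children:
        lines.extend(_clade_lines(child, inner, is_gene))
    lines.append(f"{indent}</clade>")
    return lines


def recphylo_to_string(doc: RecPhyloDocument) -> str:
    """Serialize a document to its canonical recPhyloXML text."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<recPhylo>"]
    if doc.species_tree is not None:
        lines.append("  <spTree>")
        lines.append('    <phylogeny rooted="true">')
        lines.extend(_clade_lines(doc.species_tree, "      ", is_gene=False))
        lines.append("    </phylogeny>")
        lines.append("  </spTree>")
    for gene_tree in doc.gene_trees:
        lines.append("  <recGeneTree>")
        lines.append('    <phylogeny rooted="true">')
        lines.extend(_clade_lines(gene_tree, "      ", is_gene=True))
        lines.append("    </phylogeny>")
        lines.append("  </recGeneTree>")
    lines.append("</recPhylo>")
    return "\n".join(lines) + "\n"


def write_recphylo(doc: RecPhyloDocument, sink) -> None:
    """Write a document as UTF-8 recPhyloXML to a path or open stream."""
    text = recphylo_to_string(doc)
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "wb") as fh:
            fh.write(text.encode("utf-8"))
        return
    if hasattr(sink, "buffer"):  # text-mode stdout etc.
        sink = sink.buffer
    try:
        sink.write(text.encode("utf-8"))
    except TypeError:
        sink.write(text)


def read_geography(clade_elem) -> List[GeographyAnnotation]:
    """Parse the ``<geography>`` child of an lxml clade element (lenient)."""
    parser = _Parser(ParseOptions(strictness="lenient"))
    return list(parser.read_geography(clade_elem))


# ---------------------------------------------------------------------------
# Plain Newick / NHX reading (unreconciled trees)

@dataclass(eq=False)  # identity equality: nodes are tree positions
class PlainNode:
    """An unreconciled rooted tree node as read from Newick/NHX."""

    name: str = ""
    branch_length: Optional[float] = None
    support: Optional[float] = None
    nhx: dict = field(default_factory=dict)
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf]


_NHX_RE = re.compile(r"&&NHX:(.*)", re.S)


def parse_nhx_comment(comment: str) -> Optional[dict]:
    """Parse one ``&&NHX:k=v:k=v`` comment into a dict, else None."""
    m = _NHX_RE.match(comment.strip())
    if not m:
        return None
    fields = {}
    for item in m.group(1).split(":"):
        if not item:
            continue
        key, _, value = item.partition("=")
        fields[key] = value
    return fields


def read_plain_tree(source: str, format: str = "newick") -> PlainNode:
    """Read a single rooted tree from Newick or NHX text.

    NHX comment fields (``[&&NHX:key=value:...]``) are collected into each
    node's ``nhx`` dict.  Raises ``ValueError`` on syntax errors such as
    unbalanced parentheses or forbidden characters in unquoted labels.
    """
    if format not in ("newick", "nhx"):
        raise ValueError(f"unknown tree format {format!r}")
    text = source
    if not any(ch in text for ch in "();") and os.path.exists(text):
        with open(text) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # gene trees may repeat names (LOST)
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse {format} tree: {exc}") from exc

    def convert(nd) -> PlainNode:
        label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
        node = PlainNode(name=label or "", branch_length=nd.edge.length)
        for comment in nd.comments:
            fields = parse_nhx_comment(comment)
            if fields is not None:
                node.nhx.update(fields)
        node.children = [convert(c) for c in nd.child_nodes()]
        if not node.children and not node.name:
            raise ValueError("unnamed leaf in input tree")
        return node

    root = convert(tree.seed_node)
    # a comment trailing the root label ends up on the Tree object
    for comment in tree.comments:
        fields = parse_nhx_comment(comment)
        if fields is not None:
            root.nhx.update(fields)
    return root
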