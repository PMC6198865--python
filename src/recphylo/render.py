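"""SVG rendering of a gene tree embedded in its species tree.

The species tree is drawn as nested horizontal tubes (time runs left to
right, root at the left); the gene tree runs inside the tubes, one horizontal
lane per gene node within each species.  Event glyphs follow the usual
conventions of reconciled-tree figures:

=================  =========  =====================================
event              glyph      CSS class
=================  =========  =====================================
speciation         circle     ``event-speciation``
duplication        square     ``event-duplication``
loss               cross      ``event-loss``
branchingOut       diamond    ``event-branchingOut`` (transfer out)
transferBack       triangle   ``event-transferBack`` (transfer in)
bifurcationOut     star       ``event-bifurcationOut``
leaf               dot        ``event-leaf``
=================  =========  =====================================

The circle for speciation and the four-point star for ``bifurcationOut`` are
this library's conventions (figures in the field fix only squares, crosses,
diamonds and triangles).  Every glyph carries a stable element id and its
event-type class, so colors can be restyled by editing the embedded CSS.
Unsampled-lineage events are drawn in a reserved margin band above the
species tubes.  Layout and output are fully deterministic: identical
documents produce byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple
from xml.sax.saxutils import escape, quoteattr

from recphylo.model import (
    EventType,
    GeneNode,
    RecPhyloDocument,
    SpeciesNode,
    UNSAMPLED,
)
from recphylo.validation import build_reconciliation_map

__all__ = ["Layout", "layout", "to_svg", "render_svg", "DEFAULT_THEME"]

# geometry constants (user units)
_DX = 120.0          # width of one species-tree depth level
_LANE = 14.0         # vertical distance between gene lanes
_PAD = 10.0          # tube padding
_MARGIN = 40.0       # outer margin
_BAND = 60.0         # height of the unsampled margin band

DEFAULT_THEME = {
    "tube_fill": "#d9d9d9",
    "tube_stroke": "#404040",
    "gene_stroke": "#1f6fb2",
    "transfer_stroke": "#c04000",
    "glyph_size": 5.0,
    "font_size": 10.0,
    "colors": {
        "speciation": "#1f6fb2",
        "duplication": "#d62728",
        "loss": "#7f7f7f",
        "branchingOut": "#c04000",
        "transferBack": "#2ca02c",
        "bifurcationOut": "#9467bd",
        "leaf": "#1f6fb2",
    },
}


@dataclass
class Glyph:
    event_type: EventType
    x: float
    y: float
    element_id: str
    label: Optional[str] = None


@dataclass
class Route:
    points: List[Tuple[float, float]]
    is_transfer: bool = False


@dataclass
class Layout:
    """Geometric placement: species tubes, gene anchors, event glyphs and
    connecting routes."""

    tubes: Dict[str, Tuple[float, float, float, float]] = field(default_factory=dict)
    anchors: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    glyphs: List[Glyph] = field(default_factory=list)
    routes: List[Route] = field(default_factory=list)
    width: float = 0.0
    height: float = 0.0
    band: Tuple[float, float] = (0.0, 0.0)  # y-range of the unsampled band
    species_of_anchor: Dict[int, str] = field(default_factory=dict)


def _species_metrics(doc: RecPhyloDocument, recmap):
    """Per-species lane counts and x/y extents of the tubes."""
    root = doc.species_tree
    depth: Dict[SpeciesNode, int] = {root: 0}
    order: List[SpeciesNode] = []
    for node in root.walk():
        order.append(node)
        for child in node.children:
            depth[child] = depth[node] + 1
    max_depth = max(depth.values())

    lanes: Dict[SpeciesNode, int] = {s: 0 for s in order}
    for node, target in recmap.assignment.items():
        if target is not UNSAMPLED:
            lanes[target] += 1

    x: Dict[SpeciesNode, Tuple[float, float]] = {}
    for node in order:
        x0 = _MARGIN + depth[node] * _DX
        x1 = _MARGIN + (max_depth + 1) * _DX if node.is_leaf else x0 + _DX
        x[node] = (x0, x1)

    heights = {s: _PAD * 2 + _LANE * max(1, lanes[s]) for s in order}
    y: Dict[SpeciesNode, Tuple[float, float]] = {}
    cursor = [_MARGIN + _BAND]

    def place(node: SpeciesNode):
        if node.is_leaf:
            y0 = cursor[0]
            y[node] = (y0, y0 + heights[node])
            cursor[0] = y0 + heights[node] + _PAD * 2
            return
        place(node.children[0])
        # the parent corridor sits between its two children
        y0 = cursor[0]
        y[node] = (y0, y0 + heights[node])
        cursor[0] = y0 + heights[node] + _PAD * 2
        place(node.children[1])

    place(root)
    return depth, lanes, x, y


def layout(doc: RecPhyloDocument) -> Layout:
    """Compute a deterministic layout of the document.

    Requires a species tree; documents without one should be rendered as
    plain trees by other tools.
    """
    if doc.species_tree is None:
        raise ValueError(
            "cannot draw a reconciliation without a species tree; "
            "convert to plain Newick and use an ordinary tree viewer")
    recmap = build_reconciliation_map(doc)
    depth, lanes, x, y = _species_metrics(doc, recmap)

    lay = Layout()
    for node in doc.species_tree.walk():
        x0, x1 = x[node]
        y0, y1 = y[node]
        lay.tubes[node.name] = (x0, x1, y0, y1)
    lay.band = (_MARGIN * 0.5, _MARGIN * 0.5 + _BAND * 0.6)

    # assign one horizontal lane per gene node within its species, in
    # document order (stable tie-break)
    lane_index: Dict[int, int] = {}
    seen: Dict[SpeciesNode, int] = {}
    unsampled_seen = [0]
    for tree in doc.gene_trees:
        for node in tree.walk():
            target = recmap[node]
            if target is UNSAMPLED:
                lane_index[id(node)] = unsampled_seen[0]
                unsampled_seen[0] += 1
            else:
                lane_index[id(node)] = seen.get(target, 0)
                seen[target] = seen.get(target, 0) + 1

    glyph_counter = [0]

    def glyph_id() -> str:
        glyph_counter[0] += 1
        return f"glyph-{glyph_counter[0]}"

    def anchor_of(node: GeneNode) -> Tuple[float, float]:
        target = recmap[node]
        if target is UNSAMPLED:
            gx = _MARGIN + _DX * (1 + lane_index[id(node)] % 8)
            gy = lay.band[0] + 10.0 + 12.0 * (lane_index[id(node)] // 8)
            return gx, gy
        x0, x1, y0, y1 = lay.tubes[target.name]
        gy = y0 + _PAD + _LANE * lane_index[id(node)] + _LANE * 0.5
        et = node.events.terminal.event_type
        if et in (EventType.SPECIATION, EventType.LEAF):
            gx = x1 - 3.0  # meet the end of the species branch
        else:
            gx = x0 + (x1 - x0) * 0.5
        return gx, gy

    def place_events(node: GeneNode, ax: float, ay: float, target):
        """One glyph per event of the node's sequence, ending at the anchor."""
        events = list(node.events)
        n = len(events)
        for i, ev in enumerate(events):
            if i == n - 1:
                ex, ey = ax, ay
            else:  # leading transferBacks: just left of the anchor
                ex, ey = ax - 10.0 * (n - 1 - i), ay
            label = ev.gene_name or (node.name if ev.event_type is EventType.LEAF else None)
            lay.glyphs.append(Glyph(ev.event_type, ex, ey, glyph_id(), label))

    def walk(node: GeneNode, parent_anchor, parent_target):
        ax, ay = anchor_of(node)
        target = recmap[node]
        lay.anchors[id(node)] = (ax, ay)
        lay.species_of_anchor[id(node)] = (
            UNSAMPLED.name if target is UNSAMPLED else target.name
        )
        if parent_anchor is not None:
            crosses = (
                target is not parent_target
                or node.events[0].event_type is EventType.TRANSFER_BACK
            )
            if node.events[0].event_type is EventType.TRANSFER_BACK or (
                parent_target is UNSAMPLED or target is UNSAMPLED
            ):
                lay.routes.append(Route([parent_anchor, (ax, ay)], is_transfer=True))
            elif crosses:
                px, py = parent_anchor
                lay.routes.append(Route([(px, py), (px, ay), (ax, ay)]))
            else:
                px, py = parent_anchor
                lay.routes.append(Route([(px, py), (px, ay), (ax, ay)]))
        place_events(node, ax, ay, target)
        for child in node.children:
            walk(child, (ax, ay), target)

    for tree in doc.gene_trees:
        walk(tree, None, None)

    max_x = max(x1 for (_, x1, _, _) in lay.tubes.values())
    max_y = max(y1 for (_, _, _, y1) in lay.tubes.values())
    lay.width = max_x + _MARGIN + 80.0  # room for leaf labels
    lay.height = max_y + _MARGIN
    return lay


# ---------------------------------------------------------------------------
# SVG generation

def _glyph_svg(glyph: Glyph, size: float) -> str:
    et = glyph.event_type
    x, y, s = glyph.x, glyph.y, size
    cls = f"event-{et.value}"
    ident = quoteattr(glyph.element_id)
    if et is EventType.SPECIATION:
        return f'<circle id={ident} class="glyph {cls}" cx="{x:g}" cy="{y:g}" r="{s:g}"/>'
    if et is EventType.LEAF:
        return f'<circle id={ident} class="glyph {cls}" cx="{x:g}" cy="{y:g}" r="{s * 0.6:g}"/>'
    if et is EventType.DUPLICATION:
        return (f'<rect id={ident} class="glyph {cls}" x="{x - s:g}" y="{y - s:g}" '
                f'width="{2 * s:g}" height="{2 * s:g}"/>')
    if et is EventType.LOSS:
        return (f'<path id={ident} class="glyph {cls}" d="M {x - s:g} {y - s:g} '
                f'L {x + s:g} {y + s:g} M {x - s:g} {y + s:g} L {x + s:g} {y - s:g}"/>')
    if et is EventType.BRANCHING_OUT:
        pts = f"{x:g},{y - s:g} {x + s:g},{y:g} {x:g},{y + s:g} {x - s:g},{y:g}"
        return f'<polygon id={ident} class="glyph {cls}" points="{pts}"/>'
    if et is EventType.TRANSFER_BACK:
        pts = f"{x - s:g},{y - s:g} {x + s:g},{y:g} {x - s:g},{y + s:g}"
        return f'<polygon id={ident} class="glyph {cls}" points="{pts}"/>'
    # bifurcationOut: four-point star
    h = s * 0.4
    pts = (f"{x:g},{y - s:g} {x + h:g},{y - h:g} {x + s:g},{y:g} {x + h:g},{y + h:g} "
           f"{x:g},{y + s:g} {x - h:g},{y + h:g} {x - s:g},{y:g} {x - h:g},{y - h:g}")
    return f'<polygon id={ident} class="glyph {cls}" points="{pts}"/>'


def to_svg(lay: Layout, theme: Optional[dict] = None) -> str:
    """Serialize a layout to standalone SVG 1.1 text."""
    th = dict(DEFAULT_THEME)
    th.update(theme or {})
    colors = dict(DEFAULT_THEME["colors"])
    colors.update((theme or {}).get("colors", {}))
    size = float(th["glyph_size"])

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{lay.width:g}" height="{lay.height:g}" '
        f'viewBox="0 0 {lay.width:g} {lay.height:g}">',
        "<style>",
        f".species-tube {{ fill: {th['tube_fill']}; stroke: {th['tube_stroke']}; }}",
        f".gene-route {{ fill: none; stroke: {th['gene_stroke']}; stroke-width: 1.5; }}",
        f".transfer-route {{ fill: none; stroke: {th['transfer_stroke']}; "
        "stroke-width: 1.5; stroke-dasharray: 4 2; }",
        f".species-label, .gene-label {{ font: {th['font_size']:g}px sans-serif; }}",
    ]
    for et in EventType:
        out.append(
            f".event-{et.value} {{ fill: {colors[et.value]}; stroke: {colors[et.value]}; }}"
        )
    out.append(".event-loss { fill: none; stroke-width: 2; }")
    out.append("</style>")

    out.append('<g id="species">')
    for name, (x0, x1, y0, y1) in lay.tubes.items():
        out.append(
            f'<rect class="species-tube" id={quoteattr("tube-" + name)} '
            f'x="{x0:g}" y="{y0:g}" width="{x1 - x0:g}" height="{y1 - y0:g}"/>'
        )
        out.append(
            f'<text class="species-label" x="{x1 + 4:g}" '
            f'y="{(y0 + y1) / 2:g}">{escape(name)}</text>'
        )
    out.append("</g>")

    out.append('<g id="gene-routes">')
    for i, route in enumerate(lay.routes):
        pts = " ".join(f"{px:g},{py:g}" for px, py in route.points)
        cls = "transfer-route" if route.is_transfer else "gene-route"
        out.append(f'<polyline class="{cls}" id="route-{i}" points="{pts}"/>')
    out.append("</g>")

    out.append('<g id="events">')
    for glyph in lay.glyphs:
        out.append(_glyph_svg(glyph, size))
        if glyph.label and glyph.event_type is EventType.LEAF:
            out.append(
                f'<text class="gene-label" x="{glyph.x + 8:g}" '
                f'y="{glyph.y + 3:g}">{escape(glyph.label)}</text>'
            )
    out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def render_svg(doc: RecPhyloDocument, theme: Optional[dict] = None) -> str:
    """Layout + SVG in one call (single document, all families overlaid)."""
    return to_svg(layout(doc), theme)
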