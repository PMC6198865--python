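"""Interchange and bookkeeping: Newick/NHX conversion, event censuses,
combining documents and extracting gene trees.

The NHX encoding of a reconciled tree is this library's own dialect (there is
no standard NHX vocabulary for reconciliations).  Each node carries one
``[&&NHX:...]`` comment with the keys

* ``Ev`` — semicolon-separated event-type tags in sequence order
  (``transferBack;...;terminal``), written verbatim to avoid clashing with
  other tools' one-letter codes;
* ``S``  — species of the terminal event (absent for ``bifurcationOut``);
* ``D``  — comma-separated ``transferBack`` destinations, in order;
* ``T``  — comma-separated per-event timeSlices (empty slot = absent);
* ``C``  — comma-separated per-event confidences (empty slot = absent);
* ``G``  — ``geneName`` of a leaf event;
* ``B``  — node support value.

``from_nhx`` inverts ``to_newick(..., mode="nhx")`` exactly, event sequences
included.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

from recphylo.io import PlainNode, read_plain_tree
from recphylo.model import (
    Event,
    EventSequence,
    EventType,
    GeneNode,
    ModelError,
    RecPhyloDocument,
    species_trees_equal,
)

__all__ = [
    "EventCensus",
    "to_newick",
    "from_nhx",
    "count_events",
    "combine",
    "extract",
]

_QUOTE_NEEDED = re.compile(r"[\s,:;()\[\]']")


def quote_label(label: str) -> str:
    """Quote a Newick label if it contains forbidden characters
    (whitespace or any of ``, : ; ( ) [ ]``)."""
    if label and not _QUOTE_NEEDED.search(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt(x: float) -> str:
    return repr(float(x))


def _nhx_comment(node: GeneNode) -> str:
    events = list(node.events)
    fields = [("Ev", ";".join(e.event_type.value for e in events))]
    terminal = events[-1]
    if terminal.species_location is not None:
        fields.append(("S", terminal.species_location))
    dests = [e.destination_species for e in events
             if e.event_type is EventType.TRANSFER_BACK]
    if dests:
        fields.append(("D", ",".join(dests)))
    if any(e.time_slice is not None for e in events):
        fields.append(("T", ",".join(
            "" if e.time_slice is None else str(e.time_slice) for e in events)))
    if any(e.confidence is not None for e in events):
        fields.append(("C", ",".join(
            "" if e.confidence is None else _fmt(e.confidence) for e in events)))
    if terminal.gene_name is not None:
        fields.append(("G", terminal.gene_name))
    if node.support is not None:
        fields.append(("B", _fmt(node.support)))
    return "[&&NHX:" + ":".join(f"{k}={v}" for k, v in fields) + "]"


def to_newick(tree: GeneNode, mode: str = "plain") -> str:
    """Serialize a reconciled gene tree as Newick (``plain``) or NHX.

    Plain mode keeps topology, names and branch lengths only; NHX mode also
    encodes the full event sequence of every node (see module docstring).
    """
    if mode not in ("plain", "nhx"):
        raise ValueError(f"unknown mode {mode!r}")

    def render(node: GeneNode) -> str:
        parts = ""
        if node.children:
            parts = "(" + ",".join(render(c) for c in node.children) + ")"
        out = parts + quote_label(node.name) if node.name else parts
        if node.branch_length is not None:
            out += f":{_fmt(node.branch_length)}"
        if mode == "nhx":
            out += _nhx_comment(node)
        return out

    return render(tree) + ";"


def _split_slots(value: Optional[str], n: int, convert):
    if value is None:
        return [None] * n
    slots = value.split(",")
    if len(slots) != n:
        raise ModelError(f"NHX field has {len(slots)} slots for {n} events")
    return [convert(s) if s else None for s in slots]


def _events_from_nhx(nhx: dict, path: str) -> EventSequence:
    if "Ev" not in nhx:
        raise ModelError(
            f"node {path!r} has no Ev key: this is not reconciled NHX "
            "produced by this library (for a plain gene tree, reconcile it "
            "first with the lca module)")
    try:
        types = [EventType(t) for t in nhx["Ev"].split(";")]
    except ValueError as exc:
        raise ModelError(f"unknown event code in {nhx['Ev']!r}") from exc
    n = len(types)
    slices = _split_slots(nhx.get("T"), n, int)
    confs = _split_slots(nhx.get("C"), n, float)
    dests = (nhx.get("D") or "").split(",") if nhx.get("D") else []
    di = iter(dests)
    events = []
    for i, et in enumerate(types):
        kwargs = dict(time_slice=slices[i], confidence=confs[i])
        if et is EventType.TRANSFER_BACK:
            try:
                kwargs["destination_species"] = next(di)
            except StopIteration:
                raise ModelError("fewer D destinations than transferBack events") from None
        elif i == n - 1:
            if "S" in nhx:
                kwargs["species_location"] = nhx["S"]
            if "G" in nhx:
                kwargs["gene_name"] = nhx["G"]
        events.append(Event(et, **kwargs))
    return EventSequence(events)


def from_nhx(source: str) -> GeneNode:
    """Rebuild a reconciled gene tree from this library's NHX dialect."""
    plain = read_plain_tree(source, format="nhx")

    def rebuild(node: PlainNode, path: str) -> GeneNode:
        events = _events_from_nhx(node.nhx, path or "root")
        support = float(node.nhx["B"]) if "B" in node.nhx else None
        children = tuple(
            rebuild(c, f"{path}.{i}") for i, c in enumerate(node.children)
        )
        return GeneNode(
            name=node.name,
            events=events,
            children=children,
            branch_length=node.branch_length,
            support=support,
        )

    return rebuild(plain, "0")


# ---------------------------------------------------------------------------
# Event census

@dataclass
class EventCensus:
    """Per-tree and total event counts of a document."""

    per_tree: List[Counter] = field(default_factory=list)

    @property
    def total(self) -> Counter:
        out: Counter = Counter()
        for c in self.per_tree:
            out.update(c)
        return out

    def __getitem__(self, event_type: EventType) -> int:
        return self.total[EventType(event_type)]

    def __add__(self, other: "EventCensus") -> "EventCensus":
        return EventCensus(per_tree=[Counter(c) for c in self.per_tree]
                           + [Counter(c) for c in other.per_tree])

    def __eq__(self, other) -> bool:
        return isinstance(other, EventCensus) and [
            {k: v for k, v in c.items() if v} for c in self.per_tree
        ] == [{k: v for k, v in c.items() if v} for c in other.per_tree]

    def to_tsv(self) -> str:
        lines = ["event_type\ttree_index\tcount"]
        for t, counts in enumerate(self.per_tree):
            for et in EventType:
                if counts[et]:
                    lines.append(f"{et.value}\t{t}\t{counts[et]}")
        for et in EventType:
            if self.total[et]:
                lines.append(f"{et.value}\ttotal\t{self.total[et]}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_tree": [
                    {et.value: c[et] for et in EventType if c[et]}
                    for c in self.per_tree
                ],
                "total": {et.value: self.total[et] for et in EventType if self.total[et]},
            },
            indent=2,
        )


def count_events(doc: RecPhyloDocument) -> EventCensus:
    """Count every event of every sequence (non-terminal transferBacks
    included) exactly once, per gene tree and in total."""
    census = EventCensus()
    for tree in doc.gene_trees:
        counts: Counter = Counter()
        for node in tree.walk():
            for ev in node.events:
                counts[ev.event_type] += 1
        census.per_tree.append(counts)
    return census


# ---------------------------------------------------------------------------
# Combination / extraction

def _first_divergence(a, b) -> Optional[str]:
    """Name of the first node at which two species trees differ, else None.
    Sibling order is immaterial."""
    if a.name != b.name:
        return a.name or b.name or "<unnamed>"
    if len(a.children) != len(b.children):
        return a.name or "<unnamed>"
    if not a.children:
        return None
    a1, a2 = a.children
    b1, b2 = b.children
    if species_trees_equal(a1, b1):
        return _first_divergence(a2, b2)
    if species_trees_equal(a1, b2):
        return _first_divergence(a2, b1)
    d = _first_divergence(a1, b1)
    return d if d is not None else (a.name or "<unnamed>")


def combine(docs: Sequence[RecPhyloDocument]) -> RecPhyloDocument:
    """Merge documents into one: the shared species tree (an absent species
    tree counts as unspecified, not different) plus all gene trees in input
    order."""
    if not docs:
        raise ValueError("combine requires at least one document")
    species = None
    for doc in docs:
        if doc.species_tree is None:
            continue
        if species is None:
            species = doc.species_tree
        elif not species_trees_equal(species, doc.species_tree):
            where = _first_divergence(species, doc.species_tree)
            raise ModelError(
                f"conflicting species trees: first divergence at node {where!r}")
    gene_trees = [t for doc in docs for t in doc.gene_trees]
    return RecPhyloDocument(gene_trees=gene_trees, species_tree=species)


def extract(doc: RecPhyloDocument, selectors: Sequence[Union[int, str]]) -> RecPhyloDocument:
    """Keep only the selected gene trees (0-based index or gene-tree root
    name), in selector order; the species tree is retained."""
    chosen = []
    for sel in selectors:
        if isinstance(sel, int) or (isinstance(sel, str) and re.fullmatch(r"-?\d+", sel)):
            idx = int(sel)
            if not 0 <= idx < len(doc.gene_trees):
                raise IndexError(
                    f"gene tree index {idx} out of range (document has "
                    f"{len(doc.gene_trees)} trees)")
            chosen.append(doc.gene_trees[idx])
        else:
            matches = [t for t in doc.gene_trees if t.name == sel]
            if not matches:
                raise KeyError(f"no gene tree with root name {sel!r}")
            if len(matches) > 1:
                raise KeyError(
                    f"root name {sel!r} matches {len(matches)} gene trees; "
                    "select by index instead")
            chosen.append(matches[0])
    return RecPhyloDocument(gene_trees=chosen, species_tree=doc.species_tree)
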