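"""In-memory object model for recPhyloXML documents.

The event grammar distinguishes one *non-terminal* event (``transferBack``,
which may be repeated) from six *terminal* events, exactly one of which closes
every event sequence.  Terminal events either bifurcate the gene tree
(``speciation``, ``duplication``, ``branchingOut``, ``bifurcationOut``) or end
a lineage (``leaf``, ``loss``); the number of children of a clade is therefore
fully determined by its terminal event.

Constructors validate these invariants eagerly; every type also exposes an
``unchecked`` classmethod so that lenient readers and the validator's own test
harness can materialize deliberately malformed objects.  Gene and species
nodes compare by identity (two nodes with equal content are still distinct
tree positions); value-level comparison is provided by the structural-equality
helpers at the bottom of the module, which treat sibling order as meaningless.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union


class ModelError(ValueError):
    """An object violating the recPhyloXML grammar was constructed."""


class EventType(str, enum.Enum):
    """The seven event tags of the reconciled-gene-tree grammar."""

    LEAF = "leaf"
    SPECIATION = "speciation"
    LOSS = "loss"
    DUPLICATION = "duplication"
    BRANCHING_OUT = "branchingOut"
    TRANSFER_BACK = "transferBack"
    BIFURCATION_OUT = "bifurcationOut"

    def __str__(self) -> str:  # tag name, not Enum repr
        return self.value


#: Events allowed only as the last element of a sequence.
TERMINAL_EVENTS = frozenset(
    {
        EventType.LEAF,
        EventType.SPECIATION,
        EventType.LOSS,
        EventType.DUPLICATION,
        EventType.BRANCHING_OUT,
        EventType.BIFURCATION_OUT,
    }
)
#: Terminal events after which the clade bifurcates.
BIFURCATING_EVENTS = frozenset(
    {
        EventType.SPECIATION,
        EventType.DUPLICATION,
        EventType.BRANCHING_OUT,
        EventType.BIFURCATION_OUT,
    }
)
#: Terminal events that end the lineage (no children).
LINEAGE_ENDING_EVENTS = frozenset({EventType.LEAF, EventType.LOSS})
#: Events that carry a ``speciesLocation`` attribute.
LOCATED_EVENTS = frozenset(
    {
        EventType.LEAF,
        EventType.SPECIATION,
        EventType.LOSS,
        EventType.DUPLICATION,
        EventType.BRANCHING_OUT,
    }
)


class _Unsampled:
    """Sentinel for lineages evolving outside the sampled species tree.

    ``bifurcationOut`` events happen in an unsampled or extinct species that
    the species tree does not contain; reconciliation maps send such gene
    nodes here.  Identity-based, so it can never collide with a user species.
    """

    name = "<UNSAMPLED>"

    def __repr__(self) -> str:
        return "UNSAMPLED"

    def __reduce__(self):
        return (_get_unsampled, ())


def _get_unsampled() -> "_Unsampled":
    return UNSAMPLED


UNSAMPLED = _Unsampled()


@dataclass(frozen=True)
class Event:
    """One evolutionary event with its attributes.

    ``species_location`` is mandatory for located events (leaf, speciation,
    loss, duplication, branchingOut), forbidden otherwise; ``transferBack``
    instead carries the mandatory ``destination_species`` (the recipient of
    the transfer); ``bifurcationOut`` carries neither, since it takes place in
    an unsampled lineage.  ``confidence`` is an unconstrained support value,
    ``time_slice`` a non-negative integer rank in a dated subdivision of the
    species tree, and ``gene_name`` (leaf only) names the extant gene.
    """

    event_type: EventType
    species_location: Optional[str] = None
    destination_species: Optional[str] = None
    confidence: Optional[float] = None
    time_slice: Optional[int] = None
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        et = self.event_type
        if et in LOCATED_EVENTS:
            if self.species_location is None:
                raise ModelError(f"<{et}> requires a speciesLocation attribute")
        elif self.species_location is not None:
            raise ModelError(f"<{et}> must not carry speciesLocation")
        if et is EventType.TRANSFER_BACK:
            if self.destination_species is None:
                raise ModelError("<transferBack> requires destinationSpecies")
        elif self.destination_species is not None:
            raise ModelError(f"<{et}> must not carry destinationSpecies")
        if self.gene_name is not None and et is not EventType.LEAF:
            raise ModelError(f"geneName is only allowed on <leaf>, not <{et}>")
        if self.time_slice is not None:
            if not isinstance(self.time_slice, int) or isinstance(self.time_slice, bool):
                raise ModelError("timeSlice must be an integer")
            if self.time_slice < 0:
                raise ModelError("timeSlice must be non-negative")

    @property
    def is_terminal(self) -> bool:
        return self.event_type in TERMINAL_EVENTS

    @classmethod
    def unchecked(cls, event_type: "EventType", **fields) -> "Event":
        """Bypass attribute validation (for the validator's own tests)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "event_type", event_type)
        for name in ("species_location", "destination_species", "confidence",
                     "time_slice", "gene_name"):
            object.__setattr__(obj, name, fields.get(name))
        return obj


_ATTRIBUTE_FIELDS = {
    "speciesLocation": "species_location",
    "destinationSpecies": "destination_species",
    "confidence": "confidence",
    "timeSlice": "time_slice",
    "geneName": "gene_name",
}


def make_event(event_type: Union[EventType, str], attributes: Optional[Mapping[str, object]] = None) -> Event:
    """Build an :class:`Event` from a tag name and an XML-style attribute map.

    Raises :class:`ModelError` on unknown attributes or any attribute/event
    combination the grammar forbids (e.g. ``speciesLocation`` on
    ``bifurcationOut``).
    """
    event_type = EventType(event_type)
    kwargs: dict = {}
    for key, value in (attributes or {}).items():
        try:
            field_name = _ATTRIBUTE_FIELDS[key]
        except KeyError:
            raise ModelError(f"unknown event attribute {key!r}") from None
        if field_name == "confidence":
            value = float(value)  # type: ignore[arg-type]
        elif field_name == "time_slice":
            try:
                value = int(str(value))
            except ValueError:
                raise ModelError(f"timeSlice must be an integer, got {value!r}") from None
        kwargs[field_name] = value
    return Event(event_type, **kwargs)


class EventSequence:
    """The ordered ``<eventsRec>`` content of one gene-tree clade.

    Non-empty; all elements but the last are ``transferBack``; the last is
    the unique terminal event.
    """

    __slots__ = ("events",)

    def __init__(self, events: Sequence[Event]):
        events = tuple(events)
        if not events:
            raise ModelError("eventsRec must contain at least one event")
        for ev in events[:-1]:
            if ev.event_type is not EventType.TRANSFER_BACK:
                if ev.is_terminal:
                    raise ModelError(
                        f"terminal event <{ev.event_type}> may only close the sequence"
                    )
                raise ModelError(f"unexpected non-terminal event <{ev.event_type}>")
        if not events[-1].is_terminal:
            raise ModelError(
                "eventsRec must end with exactly one terminal event, "
                f"got <{events[-1].event_type}>"
            )
        self.events = events

    @classmethod
    def unchecked(cls, events: Sequence[Event]) -> "EventSequence":
        """Bypass grammar validation (for lenient ingestion and testing)."""
        obj = cls.__new__(cls)
        obj.events = tuple(events)
        return obj

    @property
    def terminal(self) -> Event:
        """The last event of the sequence (the unique terminal event)."""
        return self.events[-1]

    @property
    def transfer_backs(self) -> tuple:
        return tuple(e for e in self.events if e.event_type is EventType.TRANSFER_BACK)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventSequence) and self.events == other.events

    def __hash__(self) -> int:
        return hash(self.events)

    def __repr__(self) -> str:
        return f"EventSequence({list(self.events)!r})"


def arity_of(event: Event) -> int:
    """Number of children implied by a terminal event: 2 if bifurcating, 0 if
    lineage-ending.  ``transferBack`` is non-terminal and has no arity."""
    if event.event_type in BIFURCATING_EVENTS:
        return 2
    if event.event_type in LINEAGE_ENDING_EVENTS:
        return 0
    raise ModelError("transferBack is non-terminal and has no arity")


@dataclass(frozen=True)
class GeographyAnnotation:
    """One ``<area>`` of a recGeoXML ``<geography>`` annotation.

    ``kml_payload`` is preserved verbatim and never interpreted.
    """

    area_name: str
    description: Optional[str] = None
    value: Optional[float] = None
    source: Optional[str] = None
    kml_payload: Optional[str] = None


class GeneNode:
    """A reconciled gene-tree clade.

    Carries a (possibly empty) name, optional branch length and support, the
    event sequence, optional geography annotations, pass-through blobs for
    unmodeled phyloXML children (``extras``), and 0 or 2 children as dictated
    by the terminal event.  Identity-based equality/hash: a node is a tree
    position, not a value.
    """

    __slots__ = ("name", "branch_length", "support", "events", "geography", "children", "extras")

    def __init__(
        self,
        name: str = "",
        events: Optional[EventSequence] = None,
        children: Sequence["GeneNode"] = (),
        branch_length: Optional[float] = None,
        support: Optional[float] = None,
        geography: Sequence[GeographyAnnotation] = (),
        extras: Sequence[str] = (),
    ):
        if events is None:
            raise ModelError("a gene node requires an event sequence")
        children = tuple(children)
        if len(children) not in (0, 2):
            raise ModelError(
                f"gene clades are binary: got {len(children)} children at {name!r}"
            )
        expected = arity_of(events.terminal)
        if len(children) != expected:
            raise ModelError(
                f"terminal event <{events.terminal.event_type}> requires "
                f"{expected} children, got {len(children)} at {name!r}"
            )
        if branch_length is not None and branch_length < 0:
            raise ModelError("branch length must be non-negative")
        self.name = name
        self.branch_length = branch_length
        self.support = support
        self.events = events
        self.geography = tuple(geography)
        self.children = children
        self.extras = tuple(extras)

    @classmethod
    def unchecked(cls, name="", events=None, children=(), branch_length=None,
                  support=None, geography=(), extras=()) -> "GeneNode":
        obj = cls.__new__(cls)
        obj.name = name
        obj.branch_length = branch_length
        obj.support = support
        obj.events = events
        obj.geography = tuple(geography)
        obj.children = tuple(children)
        obj.extras = tuple(extras)
        return obj

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["GeneNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def __repr__(self) -> str:
        return f"<GeneNode {self.name!r} {self.events.terminal.event_type if self.events else '?'}>"


def terminal_event(node: GeneNode) -> Event:
    """The terminal (last) event of a gene node's sequence."""
    return node.events.terminal


class SpeciesNode:
    """A species-tree clade: name, optional branch length, 0 or 2 children."""

    __slots__ = ("name", "branch_length", "geography", "children", "extras")

    def __init__(
        self,
        name: str = "",
        children: Sequence["SpeciesNode"] = (),
        branch_length: Optional[float] = None,
        geography: Sequence[GeographyAnnotation] = (),
        extras: Sequence[str] = (),
    ):
        children = tuple(children)
        if len(children) not in (0, 2):
            raise ModelError(
                f"species clades are binary: got {len(children)} children at {name!r}"
            )
        if branch_length is not None and branch_length < 0:
            raise ModelError("branch length must be non-negative")
        self.name = name
        self.branch_length = branch_length
        self.geography = tuple(geography)
        self.children = children
        self.extras = tuple(extras)

    @classmethod
    def unchecked(cls, name="", children=(), branch_length=None, geography=(), extras=()) -> "SpeciesNode":
        obj = cls.__new__(cls)
        obj.name = name
        obj.branch_length = branch_length
        obj.geography = tuple(geography)
        obj.children = tuple(children)
        obj.extras = tuple(extras)
        return obj

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["SpeciesNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def by_name(self) -> dict:
        """Mapping species name -> node over the subtree; duplicate names
        raise, since speciesLocation resolution requires uniqueness."""
        index: dict = {}
        for node in self.walk():
            if node.name in index:
                raise ModelError(f"duplicate species name {node.name!r}")
            index[node.name] = node
        return index

    def __repr__(self) -> str:
        return f"<SpeciesNode {self.name!r}>"


class RecPhyloDocument:
    """A ``<recPhylo>`` unit: at most one species tree, one or more reconciled
    gene trees."""

    __slots__ = ("species_tree", "gene_trees")

    def __init__(
        self,
        gene_trees: Sequence[GeneNode],
        species_tree: Optional[SpeciesNode] = None,
    ):
        gene_trees = tuple(gene_trees)
        if not gene_trees:
            raise ModelError("a recPhylo document requires at least one gene tree")
        if species_tree is not None:
            species_tree.by_name()  # enforce species-name uniqueness
        self.species_tree = species_tree
        self.gene_trees = gene_trees

    @classmethod
    def unchecked(cls, gene_trees, species_tree=None) -> "RecPhyloDocument":
        obj = cls.__new__(cls)
        obj.species_tree = species_tree
        obj.gene_trees = tuple(gene_trees)
        return obj


@dataclass
class ReconciliationMap:
    """Gene node -> species node of its terminal event; ``bifurcationOut``
    nodes map to :data:`UNSAMPLED`."""

    assignment: dict = field(default_factory=dict)

    def __getitem__(self, node: GeneNode):
        return self.assignment[node]

    def __len__(self) -> int:
        return len(self.assignment)

    def __contains__(self, node: GeneNode) -> bool:
        return node in self.assignment


# ---------------------------------------------------------------------------
# Structural equality (value comparison; sibling order ignored)

def events_equal(a: EventSequence, b: EventSequence) -> bool:
    return tuple(a) == tuple(b)


def _scalar_fields_equal(a, b) -> bool:
    return (
        a.name == b.name
        and _close(a.branch_length, b.branch_length)
        and a.geography == b.geography
        and a.extras == b.extras
    )


def _close(x: Optional[float], y: Optional[float]) -> bool:
    if x is None or y is None:
        return x is None and y is None
    return abs(x - y) <= 1e-9 * max(1.0, abs(x), abs(y))


def gene_trees_equal(a: GeneNode, b: GeneNode) -> bool:
    """Recursive value equality, invariant to swapping sibling order."""
    if not (_scalar_fields_equal(a, b) and _close(a.support, b.support)
            and events_equal(a.events, b.events)):
        return False
    if len(a.children) != len(b.children):
        return False
    if not a.children:
        return True
    a1, a2 = a.children
    b1, b2 = b.children
    return (gene_trees_equal(a1, b1) and gene_trees_equal(a2, b2)) or (
        gene_trees_equal(a1, b2) and gene_trees_equal(a2, b1)
    )


def species_trees_equal(a: SpeciesNode, b: SpeciesNode) -> bool:
    if not _scalar_fields_equal(a, b):
        return False
    if len(a.children) != len(b.children):
        return False
    if not a.children:
        return True
    a1, a2 = a.children
    b1, b2 = b.children
    return (species_trees_equal(a1, b1) and species_trees_equal(a2, b2)) or (
        species_trees_equal(a1, b2) and species_trees_equal(a2, b1)
    )


def documents_equal(a: RecPhyloDocument, b: RecPhyloDocument) -> bool:
    if (a.species_tree is None) != (b.species_tree is None):
        return False
    if a.species_tree is not None and not species_trees_equal(a.species_tree, b.species_tree):
        return False
    if len(a.gene_trees) != len(b.gene_trees):
        return False
    return all(gene_trees_equal(x, y) for x, y in zip(a.gene_trees, b.gene_trees))
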