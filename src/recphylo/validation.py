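"""Two-level validation of reconciled-tree documents.

*Level 1* (:func:`validate_structure`) re-checks the event grammar and
document structure from scratch, so it also works on objects materialized
through the model's ``unchecked`` constructors (e.g. by a lenient reader):
exactly one terminal event closing each sequence, clade arity matching the
terminal event, attribute presence rules, and document cardinality.

*Level 2* (:func:`validate_semantics`) checks the reconciliation against the
species tree.  The format itself only pins down local tag grammar; the
cross-node rules here are derived from the meaning of the events — a
speciation sends its two children into the two child species, a duplication
keeps both children in place, a lateral transfer is a donor-side
``branchingOut``/``bifurcationOut`` paired with a recipient-side
``transferBack`` — and all rules the format does not strictly mandate are
enforced only in ``strict`` mode.  ``lenient`` mode checks only that species
references resolve and that timeSlices do not run backwards.

The *starting species* of a gene branch is the destination of its first
event if that event is a ``transferBack``, otherwise the species of its
terminal event (``UNSAMPLED`` for ``bifurcationOut``).  A chain of k
``transferBack`` events is read as k successive species changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Union

from recphylo.model import (
    BIFURCATING_EVENTS,
    Event,
    EventType,
    GeneNode,
    LINEAGE_ENDING_EVENTS,
    LOCATED_EVENTS,
    ModelError,
    RecPhyloDocument,
    ReconciliationMap,
    SpeciesNode,
    TERMINAL_EVENTS,
    UNSAMPLED,
)

__all__ = [
    "ValidationIssue",
    "ValidationReport",
    "validate_structure",
    "validate_semantics",
    "build_reconciliation_map",
    "starting_species",
]


@dataclass
class ValidationIssue:
    code: str
    severity: str  # "error" | "warning"
    gene_tree_index: int  # -1 for document / species-tree findings
    node_path: str
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def codes(self) -> set:
        return {i.code for i in self.issues}

    def error(self, code, tree, path, message):
        self.issues.append(ValidationIssue(code, "error", tree, path, message))

    def warning(self, code, tree, path, message):
        self.issues.append(ValidationIssue(code, "warning", tree, path, message))

    def extend(self, other: "ValidationReport"):
        self.issues.extend(other.issues)

    def to_tsv(self) -> str:
        lines = ["code\tseverity\ttree_index\tnode_path\tmessage"]
        for i in self.issues:
            lines.append(f"{i.code}\t{i.severity}\t{i.gene_tree_index}\t{i.node_path}\t{i.message}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "valid": self.valid,
                "issues": [
                    {
                        "code": i.code,
                        "severity": i.severity,
                        "gene_tree_index": i.gene_tree_index,
                        "node_path": i.node_path,
                        "message": i.message,
                    }
                    for i in self.issues
                ],
            },
            indent=2,
        )


def _walk_with_paths(root: GeneNode):
    stack = [(root, "0")]
    while stack:
        node, path = stack.pop()
        yield node, path
        for i, child in enumerate(reversed(node.children)):
            stack.append((child, f"{path}.{len(node.children) - 1 - i}"))


# ---------------------------------------------------------------------------
# Level 1: structure

def _check_event_attributes(ev: Event, report, tree, path):
    et = ev.event_type
    if et in LOCATED_EVENTS and ev.species_location is None:
        report.error("E_ATTR", tree, path, f"<{et}> requires speciesLocation")
    if et not in LOCATED_EVENTS and ev.species_location is not None:
        report.error("E_ATTR", tree, path, f"<{et}> must not carry speciesLocation")
    if et is EventType.TRANSFER_BACK and ev.destination_species is None:
        report.error("E_ATTR", tree, path, "<transferBack> requires destinationSpecies")
    if et is not EventType.TRANSFER_BACK and ev.destination_species is not None:
        report.error("E_ATTR", tree, path, f"<{et}> must not carry destinationSpecies")
    if ev.gene_name is not None and et is not EventType.LEAF:
        report.error("E_ATTR", tree, path, f"geneName forbidden on <{et}>")
    if ev.time_slice is not None and ev.time_slice < 0:
        report.error("E_ATTR", tree, path, "timeSlice must be non-negative")
    if ev.confidence is not None and not (0.0 <= ev.confidence <= 1.0):
        report.warning("W_CONFIDENCE", tree, path,
                       f"confidence {ev.confidence} outside [0, 1]")


def _check_gene_node_structure(node: GeneNode, report, tree, path):
    events = list(node.events) if node.events is not None else []
    if not events:
        report.error("E_NO_TERMINAL", tree, path, "empty eventsRec")
        return
    terminals = [i for i, e in enumerate(events) if e.event_type in TERMINAL_EVENTS]
    if not terminals:
        report.error("E_NO_TERMINAL", tree, path, "no terminal event in eventsRec")
    if len(terminals) > 1:
        report.error("E_MULTI_TERMINAL", tree, path,
                     f"{len(terminals)} terminal events in one eventsRec")
    for i in terminals:
        if i != len(events) - 1:
            report.error("E_EARLY_TERMINAL", tree, path,
                         f"terminal <{events[i].event_type}> at position {i} is not last")
    for ev in events:
        _check_event_attributes(ev, report, tree, path)
    if terminals and terminals[-1] == len(events) - 1:
        terminal = events[-1]
        expected = 2 if terminal.event_type in BIFURCATING_EVENTS else 0
        if len(node.children) != expected:
            report.error("E_ARITY", tree, path,
                         f"<{terminal.event_type}> requires {expected} children, "
                         f"got {len(node.children)}")
    elif len(node.children) not in (0, 2):
        report.error("E_ARITY", tree, path,
                     f"gene clades are binary, got {len(node.children)} children")


def validate_structure(doc: RecPhyloDocument) -> ValidationReport:
    """Check the event grammar and document structure (level 1)."""
    report = ValidationReport()
    if not doc.gene_trees:
        report.error("E_DOC", -1, "/", "document has no gene tree")
    if doc.species_tree is not None:
        seen = {}
        for node in doc.species_tree.walk():
            if len(node.children) not in (0, 2):
                report.error("E_ARITY", -1, node.name or "?",
                             f"species clades are binary, got {len(node.children)}")
            if node.name:
                if node.name in seen:
                    report.error("E_DOC", -1, node.name,
                                 f"duplicate species name {node.name!r}")
                seen[node.name] = node
    for t, tree in enumerate(doc.gene_trees):
        for node, path in _walk_with_paths(tree):
            _check_gene_node_structure(node, report, t, path)
    return report


# ---------------------------------------------------------------------------
# Level 2: semantics

def starting_species(node: GeneNode) -> Union[str, object]:
    """Species in which a gene branch starts: the destination of a leading
    ``transferBack``, else the terminal event's species (``UNSAMPLED`` for
    ``bifurcationOut``)."""
    first = node.events[0]
    if first.event_type is EventType.TRANSFER_BACK:
        return first.destination_species
    terminal = node.events.terminal
    if terminal.event_type is EventType.BIFURCATION_OUT:
        return UNSAMPLED
    return terminal.species_location


def _is_emigrant(node: GeneNode) -> bool:
    """Does this branch leave the sampled tree right away (transfer child)?"""
    first = node.events[0]
    return (
        first.event_type is EventType.TRANSFER_BACK
        or node.events.terminal.event_type is EventType.BIFURCATION_OUT
    )


def validate_semantics(doc: RecPhyloDocument, level: str = "strict") -> ValidationReport:
    """Check reconciliation consistency against the species tree (level 2).

    ``level`` is ``"strict"`` (full rule set) or ``"lenient"`` (species-name
    resolution and timeSlice monotonicity only).  Documents should pass
    :func:`validate_structure` first; findings never raise.
    """
    if level not in ("strict", "lenient"):
        raise ValueError(f"unknown validation level {level!r}")
    strict = level == "strict"
    report = ValidationReport()
    if doc.species_tree is None:
        report.warning("W_NO_SPTREE", -1, "/",
                       "no species tree: semantic rules skipped")
        return report
    species = {}
    for node in doc.species_tree.walk():
        species.setdefault(node.name, node)

    def resolve(name, t, path) -> Optional[SpeciesNode]:
        if name not in species:
            report.error("E_SPECIES_UNKNOWN", t, path,
                         f"species {name!r} is not in the species tree")
            return None
        return species[name]

    for t, tree in enumerate(doc.gene_trees):
        _check_tree_semantics(tree, t, report, species, resolve, strict)
        _check_time_slices(tree, t, report)
    return report


def _check_tree_semantics(tree, t, report, species, resolve, strict):
    for node, path in _walk_with_paths(tree):
        events = node.events
        terminal = events.terminal
        # species references must resolve (both levels)
        for ev in events:
            if ev.species_location is not None:
                resolve(ev.species_location, t, path)
            if ev.destination_species is not None:
                resolve(ev.destination_species, t, path)
        # successive transferBack destinations are genuine species changes;
        # the terminal event must take place where the last transfer landed
        if strict:
            current = None
            for ev in events:
                if ev.event_type is EventType.TRANSFER_BACK:
                    if ev.destination_species == current:
                        report.error(
                            "E_TRANSFER_SELF", t, path,
                            f"transferBack into {current!r}, the species the "
                            "lineage already occupies")
                    current = ev.destination_species
            if current is not None:
                if terminal.event_type is EventType.BIFURCATION_OUT:
                    report.error(
                        "E_TRANSFERBACK_TERMINUS", t, path,
                        f"lineage re-entered {current!r} but terminal "
                        "bifurcationOut takes place outside the sampled tree")
                elif (terminal.species_location is not None
                      and terminal.species_location != current):
                    report.error(
                        "E_TRANSFERBACK_TERMINUS", t, path,
                        f"terminal <{terminal.event_type}> at "
                        f"{terminal.species_location!r} but the last "
                        f"transferBack landed in {current!r}")
        # transferBack reception requires a donor-side branching event
        if events[0].event_type is EventType.TRANSFER_BACK and node is tree:
            report.warning("W_ROOT_TRANSFERBACK", t, path,
                           "root lineage enters via transferBack "
                           "(origin outside the sampled tree)")
        if strict:
            _check_children_semantics(node, t, path, report, species)


def _check_children_semantics(node, t, path, report, species):
    terminal = node.events.terminal
    et = terminal.event_type
    if et in LINEAGE_ENDING_EVENTS or len(node.children) != 2:
        return
    c1, c2 = node.children
    starts = [starting_species(c) for c in (c1, c2)]
    s_name = terminal.species_location
    s_node = species.get(s_name) if s_name is not None else None

    # reception without a donor-side branching event
    for child, cpath in ((c1, path + ".0"), (c2, path + ".1")):
        if (child.events[0].event_type is EventType.TRANSFER_BACK
                and et not in (EventType.BRANCHING_OUT, EventType.BIFURCATION_OUT)):
            report.error("E_ORPHAN_TRANSFERBACK", t, cpath,
                         f"branch begins with transferBack but parent ends "
                         f"with <{et}>, not a transfer origin")

    if et is EventType.SPECIATION:
        if s_node is None:
            return
        expected = {c.name for c in s_node.children}
        if not s_node.children or set(starts) != expected:
            report.error(
                "E_SPECIATION_CHILDREN", t, path,
                f"speciation at {s_name!r}: children start in "
                f"{sorted(str(x) for x in starts)}, expected the two child "
                f"species {sorted(expected)}")
    elif et is EventType.DUPLICATION:
        for start, cpath in zip(starts, (path + ".0", path + ".1")):
            if start != s_name:
                report.error(
                    "E_DUP_CHILDREN", t, cpath,
                    f"duplication at {s_name!r}: child starts in {start!r}")
    elif et is EventType.BRANCHING_OUT:
        resident = [c for c in (c1, c2)
                    if not _is_emigrant(c) and starting_species(c) == s_name]
        emigrant = [c for c in (c1, c2) if _is_emigrant(c)]
        if not (len(resident) == 1 and len(emigrant) == 1
                and resident[0] is not emigrant[0]):
            report.error(
                "E_BRANCHINGOUT_CHILDREN", t, path,
                f"branchingOut at {s_name!r}: expected one child remaining in "
                f"{s_name!r} and one emigrant (transferBack or "
                f"bifurcationOut), got starts "
                f"{sorted(str(x) for x in starts)}")
    elif et is EventType.BIFURCATION_OUT:
        for child, cpath in ((c1, path + ".0"), (c2, path + ".1")):
            if not _is_emigrant(child):
                report.error(
                    "E_BIFOUT_CHILDREN", t, cpath,
                    "child of bifurcationOut must re-enter via transferBack "
                    "or bifurcate again in the unsampled compartment")


def _check_time_slices(tree, t, report):
    # timeSlice ranks must not decrease from the root toward the leaves
    def descend(node, path, last):
        for ev in node.events:
            if ev.time_slice is not None:
                if last is not None and ev.time_slice < last:
                    report.warning(
                        "W_TIMESLICE", t, path,
                        f"timeSlice {ev.time_slice} after {last} on a "
                        "root-to-leaf path")
                last = ev.time_slice
        for i, child in enumerate(node.children):
            descend(child, f"{path}.{i}", last)

    descend(tree, "0", None)


# ---------------------------------------------------------------------------

def build_reconciliation_map(doc: RecPhyloDocument) -> ReconciliationMap:
    """Materialize gene node -> species node from the terminal events.

    ``bifurcationOut`` nodes map to :data:`recphylo.model.UNSAMPLED`.
    Unresolvable species references raise :class:`ModelError`.
    """
    if doc.species_tree is None:
        raise ModelError("cannot build a reconciliation map without a species tree")
    species = doc.species_tree.by_name()
    assignment = {}
    for tree in doc.gene_trees:
        for node in tree.walk():
            terminal = node.events.terminal
            if terminal.event_type is EventType.BIFURCATION_OUT:
                assignment[node] = UNSAMPLED
                continue
            name = terminal.species_location
            if name not in species:
                raise ModelError(
                    f"species {name!r} is not in the species tree")
            assignment[node] = species[name]
    return ReconciliationMap(assignment)
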