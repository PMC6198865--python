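"""Independent oracles used by the test suite.

These are deliberately written as first-principles re-implementations that
share no code with the package internals they check:

* :func:`consistent` — a recursive legality checker for reconciled gene
  trees that threads the lineage's location (a sampled species or the
  unsampled compartment) through the event sequences, instead of applying
  per-code rules like the package validator does.
* :func:`brute_force_dl_cost` — exhaustive minimization of the
  duplication + loss cost over all species assignments of the internal gene
  nodes, against which the LCA reconciler is compared.
"""

from __future__ import annotations

import itertools

from recphylo.model import EventType, GeneNode, RecPhyloDocument, SpeciesNode

OUT = "<out>"  # unsampled compartment marker


def _species_children(root: SpeciesNode):
    kids = {}
    for node in root.walk():
        kids[node.name] = [c.name for c in node.children]
    return kids


def _branch_ok(node: GeneNode, entry, kids, names) -> bool:
    """Is this gene branch legal given its entry location?

    ``entry`` is a species name, OUT, or None (root: unconstrained).
    """
    events = list(node.events)
    location = entry
    for i, ev in enumerate(events[:-1]):
        if ev.event_type is not EventType.TRANSFER_BACK:
            return False  # only transferBack may precede the terminal
        dest = ev.destination_species
        if dest not in names:
            return False
        if i == 0:
            # reception straight after entering the branch: only legal when
            # the lineage arrives from outside the sampled tree
            if location not in (OUT, None):
                return False
        elif dest == location:
            return False  # no self-transfer within a chain
        location = dest
    terminal = events[-1]
    et = terminal.event_type

    if et is EventType.BIFURCATION_OUT:
        # must currently be outside the sampled tree
        if location not in (OUT, None):
            return False
        if len(node.children) != 2:
            return False
        return all(_branch_ok(c, OUT, kids, names) for c in node.children)

    where = terminal.species_location
    if where is None or where not in names:
        return False
    if location is None:
        location = where
    if location is OUT:
        return False  # a located terminal needs a transferBack first
    if where != location:
        return False

    if et in (EventType.LEAF, EventType.LOSS):
        return not node.children
    if len(node.children) != 2:
        return False
    c1, c2 = node.children
    if et is EventType.SPECIATION:
        if len(kids[where]) != 2:
            return False
        left, right = kids[where]
        return (_branch_ok(c1, left, kids, names) and _branch_ok(c2, right, kids, names)) or (
            _branch_ok(c1, right, kids, names) and _branch_ok(c2, left, kids, names)
        )
    if et is EventType.DUPLICATION:
        return _branch_ok(c1, where, kids, names) and _branch_ok(c2, where, kids, names)
    if et is EventType.BRANCHING_OUT:
        return (_branch_ok(c1, where, kids, names) and _branch_ok(c2, OUT, kids, names)) or (
            _branch_ok(c1, OUT, kids, names) and _branch_ok(c2, where, kids, names)
        )
    return False


def consistent(doc: RecPhyloDocument) -> bool:
    """True iff every gene tree is a legal reconciliation against the
    species tree (transfer chains included)."""
    if doc.species_tree is None:
        return True
    kids = _species_children(doc.species_tree)
    names = set(kids)
    return all(_branch_ok(tree, None, kids, names) for tree in doc.gene_trees)


# ---------------------------------------------------------------------------
# Exhaustive duplication-loss minimization

def brute_force_dl_cost(gene_root, leaf_species: dict, species_root: SpeciesNode):
    """Minimum duplication + loss cost over all loss-free-node assignments.

    ``gene_root`` is any binary tree object with ``children`` and ``name``
    (leaves named); ``leaf_species`` maps gene-leaf name -> species name.
    Every internal gene node is assigned some species node, each leaf its
    mapped species; an assignment is feasible when every node's species is an
    ancestor-or-self of both children's species.  A node is a speciation when
    its children's species lie under distinct children of its own species
    (cost: the losses along both descents, minus the first step each); any
    other feasible node is a duplication (cost: 1 plus the full descents).
    """
    nodes = list(species_root.walk())
    parent = {species_root: None}
    depth = {species_root: 0}
    for s in nodes:
        for c in s.children:
            parent[c] = s
            depth[c] = depth[s] + 1
    by_name = {s.name: s for s in nodes}

    def is_ancestor(a, b):  # a ancestor-or-self of b
        while b is not None and depth[b] >= depth[a]:
            if b is a:
                return True
            b = parent[b]
        return False

    def dist(a, b):  # edges from ancestor a down to b
        d = 0
        while b is not a:
            b = parent[b]
            d += 1
        return d

    def child_toward(s, target):  # child of s on the path to target (s != target)
        step = target
        while parent[step] is not s:
            step = parent[step]
        return step

    gene_internals = []
    gene_leaves = []

    def collect(g):
        (gene_leaves if not g.children else gene_internals).append(g)
        for c in g.children:
            collect(c)

    collect(gene_root)
    fixed = {id(g): by_name[leaf_species[g.name]] for g in gene_leaves}

    best = None
    for combo in itertools.product(nodes, repeat=len(gene_internals)):
        assign = dict(fixed)
        for g, s in zip(gene_internals, combo):
            assign[id(g)] = s
        cost = 0
        feasible = True
        for g in gene_internals:
            s = assign[id(g)]
            s1 = assign[id(g.children[0])]
            s2 = assign[id(g.children[1])]
            if not (is_ancestor(s, s1) and is_ancestor(s, s2)):
                feasible = False
                break
            speciation_possible = (
                s1 is not s
                and s2 is not s
                and len(s.children) == 2
                and child_toward(s, s1) is not child_toward(s, s2)
            )
            if speciation_possible:
                cost += (dist(s, s1) - 1) + (dist(s, s2) - 1)
            else:
                cost += 1 + dist(s, s1) + dist(s, s2)
        if feasible and (best is None or cost < best):
            best = cost
    return best
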