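"""Most-parsimonious duplication–loss reconciliation by LCA mapping.

Given a rooted binary gene tree, a rooted binary species tree and a total
leaf mapping, each gene node g is assigned M(g), the lowest common ancestor
in the species tree of the species of its descendant leaves.  An internal
node is a duplication when M(g) equals the mapping of one of its children
(the two gene copies stay in the same species branch), otherwise a
speciation.  For each child c, one explicit loss leaf is inserted on every
species branch the lineage must have traversed without surviving: the
species nodes strictly between M(g) and M(c) under a speciation, and the
nodes from M(g) (inclusive) down to above M(c) under a duplication.  This
classical assignment minimizes the total number of duplications plus losses
among all reconciliations without transfers.

The output is a full recPhyloXML document (species tree included) that
passes strict validation; loss leaves are named ``LOST`` and extant leaves
carry their gene name in the ``geneName`` attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from recphylo.io import PlainNode, read_plain_tree
from recphylo.model import (
    Event,
    EventSequence,
    EventType,
    GeneNode,
    ModelError,
    RecPhyloDocument,
    SpeciesNode,
)

__all__ = ["LeafMapping", "lca_reconcile", "species_tree_from_plain", "reconcile_files"]


@dataclass
class LeafMapping:
    """Total mapping from gene-leaf names to species-leaf names."""

    pairs: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, text: str) -> "LeafMapping":
        """Two tab-separated columns: gene name, species name."""
        pairs = {}
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"mapping line {ln}: expected 2 columns, got {len(parts)}")
            gene, species = (p.strip() for p in parts)
            if gene in pairs:
                raise ValueError(f"mapping line {ln}: duplicate gene name {gene!r}")
            pairs[gene] = species
        return cls(pairs)

    @classmethod
    def from_prefix(cls, gene_leaf_names, separator: str = "_") -> "LeafMapping":
        """Name-convention mapping ``<species><sep><gene id>``."""
        pairs = {}
        for name in gene_leaf_names:
            species, sep, _ = name.partition(separator)
            if not sep or not species:
                raise ValueError(
                    f"gene leaf {name!r} does not follow the "
                    f"'species{separator}gene' convention")
            pairs[name] = species
        return cls(pairs)

    def __getitem__(self, gene_name: str) -> str:
        return self.pairs[gene_name]


def species_tree_from_plain(plain: PlainNode, autoname: str = "S") -> SpeciesNode:
    """Convert a parsed plain tree to a SpeciesNode tree, naming unnamed
    internal nodes ``S1, S2, ...`` (preorder) so every node is addressable."""
    used = {n.name for n in plain.walk() if n.name}
    counter = [0]

    def fresh() -> str:
        while True:
            counter[0] += 1
            candidate = f"{autoname}{counter[0]}"
            if candidate not in used:
                used.add(candidate)
                return candidate

    def convert(node: PlainNode) -> SpeciesNode:
        if len(node.children) not in (0, 2):
            raise ModelError(
                f"species tree must be binary; node {node.name!r} has "
                f"{len(node.children)} children")
        return SpeciesNode(
            name=node.name or fresh(),
            children=tuple(convert(c) for c in node.children),
            branch_length=node.branch_length,
        )

    return convert(plain)


class _SpeciesIndex:
    def __init__(self, root: SpeciesNode):
        self.root = root
        self.parent: Dict[SpeciesNode, Optional[SpeciesNode]] = {root: None}
        self.depth: Dict[SpeciesNode, int] = {root: 0}
        for node in root.walk():
            for child in node.children:
                self.parent[child] = node
                self.depth[child] = self.depth[node] + 1
        self.by_name = root.by_name()

    def lca(self, a: SpeciesNode, b: SpeciesNode) -> SpeciesNode:
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            else:
                a = self.parent[a]
        return a

    def path_down(self, top: SpeciesNode, bottom: SpeciesNode):
        """Nodes from ``top`` to ``bottom`` inclusive, top first."""
        path = []
        node = bottom
        while node is not top:
            path.append(node)
            node = self.parent[node]
            if node is None:
                raise ModelError("path_down: top is not an ancestor of bottom")
        path.append(top)
        path.reverse()
        return path


def _loss_leaf(species: SpeciesNode) -> GeneNode:
    return GeneNode(
        name="LOST",
        events=EventSequence([Event(EventType.LOSS, species_location=species.name)]),
    )


def lca_reconcile(
    gene_tree: PlainNode,
    species_tree: SpeciesNode,
    mapping: LeafMapping,
) -> RecPhyloDocument:
    """Reconcile a plain gene tree with a species tree under the LCA
    duplication–loss model; returns a recPhyloXML document.

    Raises :class:`ModelError` if the mapping is not total over the gene
    leaves, maps to unknown species, or either tree is non-binary.
    """
    index = _SpeciesIndex(species_tree)
    species_leaves = {n.name for n in species_tree.walk() if n.is_leaf}

    M: Dict[PlainNode, SpeciesNode] = {}

    def assign(node: PlainNode) -> SpeciesNode:
        if node.is_leaf:
            try:
                target = mapping[node.name]
            except KeyError:
                raise ModelError(
                    f"gene leaf {node.name!r} missing from the leaf mapping") from None
            if target not in species_leaves:
                raise ModelError(
                    f"gene leaf {node.name!r} maps to {target!r}, which is "
                    "not a species-tree leaf")
            M[node] = index.by_name[target]
            return M[node]
        if len(node.children) != 2:
            raise ModelError(
                f"gene tree must be binary; node {node.name!r} has "
                f"{len(node.children)} children")
        a, b = (assign(c) for c in node.children)
        M[node] = index.lca(a, b)
        return M[node]

    assign(gene_tree)

    def chain_losses(subtree: GeneNode, top: SpeciesNode, bottom: SpeciesNode) -> GeneNode:
        """Wrap ``subtree`` (which starts in species ``bottom``) in speciation
        nodes with a LOST sibling at every species node from ``top`` down to
        just above ``bottom``."""
        path = index.path_down(top, bottom)
        wrapped = subtree
        # walk upward: at each intermediate node the lineage speciates and is
        # lost in the branch off the path
        for i in range(len(path) - 2, -1, -1):
            here, down = path[i], path[i + 1]
            sibling = next(c for c in here.children if c is not down)
            wrapped = GeneNode(
                name="",
                events=EventSequence(
                    [Event(EventType.SPECIATION, species_location=here.name)]
                ),
                children=(wrapped, _loss_leaf(sibling)),
            )
        return wrapped

    def build(node: PlainNode) -> GeneNode:
        s = M[node]
        if node.is_leaf:
            return GeneNode(
                name=node.name,
                events=EventSequence(
                    [Event(EventType.LEAF, species_location=s.name,
                           gene_name=node.name)]
                ),
                branch_length=node.branch_length,
            )
        c1, c2 = node.children
        is_dup = M[c1] is s or M[c2] is s
        children = []
        for child in (c1, c2):
            sub = build(child)
            if is_dup:
                # the copy starts inside branch s itself
                sub = chain_losses(sub, s, M[child])
            else:
                # speciation at s: the copy enters the child branch of s
                # leading toward M(child)
                entry = index.path_down(s, M[child])[1] if M[child] is not s else s
                sub = chain_losses(sub, entry, M[child])
            children.append(sub)
        event = EventType.DUPLICATION if is_dup else EventType.SPECIATION
        return GeneNode(
            name=node.name,
            events=EventSequence([Event(event, species_location=s.name)]),
            children=tuple(children),
            branch_length=node.branch_length,
            support=node.support,
        )

    root = build(gene_tree)
    return RecPhyloDocument(gene_trees=[root], species_tree=species_tree)


def reconcile_files(
    gene_newick: str,
    species_newick: str,
    mapping_tsv: Optional[str] = None,
    prefix_separator: Optional[str] = None,
) -> RecPhyloDocument:
    """Convenience wrapper: Newick texts in, document out.

    Exactly one of ``mapping_tsv`` (two-column text) or ``prefix_separator``
    (species-prefix naming convention) selects the leaf mapping.
    """
    gene = read_plain_tree(gene_newick)
    species = species_tree_from_plain(read_plain_tree(species_newick))
    if (mapping_tsv is None) == (prefix_separator is None):
        raise ValueError("provide exactly one of mapping_tsv / prefix_separator")
    if mapping_tsv is not None:
        mapping = LeafMapping.from_tsv(mapping_tsv)
    else:
        mapping = LeafMapping.from_prefix(
            [n.name for n in gene.leaves()], separator=prefix_separator
        )
    return lca_reconcile(gene, species, mapping)
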