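"""Duplication–transfer–loss simulation along a dated species tree.

A single gene lineage enters the species tree at the top of the root branch
and evolves toward the present.  Along a species branch, the waiting time to
the next event is exponential with total rate ``dup + transfer + loss`` (per
unit branch length, i.e. per unit time on an ultrametric tree):

* duplication — the lineage splits, both copies continue in the same branch;
* loss — the lineage ends (a ``LOST`` leaf with a ``loss`` event);
* transfer — a ``branchingOut``: one copy stays in the donor branch, the
  other leaves the sampled tree.  The emigrant spends an exponential
  (transfer-rate) dwell time in an undated unsampled compartment, capped at
  the time remaining, then re-enters a uniformly chosen species branch alive
  at the re-entry time (the donor is excluded for a direct re-entry); with
  probability ``unsampled_bifurcation_prob`` it first bifurcates in the
  unsampled compartment (``bifurcationOut``) and both daughters re-enter
  independently.

Reaching a speciation node of the species tree emits a ``speciation`` with
one child per descendant branch; reaching the present emits a ``leaf`` named
``<species>_<k>``.  Every lateral transfer is therefore written as the
two-step donor (``branchingOut``/``bifurcationOut``) + recipient
(``transferBack``) representation, and every simulated document passes
strict validation.

Events carry a ``timeSlice``: the rank (0 = oldest) of the inter-speciation
time interval containing the event, so slices are non-decreasing from the
root toward the leaves.  All randomness flows from a single seed through one
``random.Random`` stream; identical parameters give byte-identical output.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

from recphylo.io import read_plain_tree
from recphylo.lca import species_tree_from_plain
from recphylo.model import (
    Event,
    EventSequence,
    EventType,
    GeneNode,
    ModelError,
    RecPhyloDocument,
    SpeciesNode,
)

__all__ = ["SimParams", "DatedSpeciesTree", "simulate_family", "simulate_dataset", "load_params"]

_ULTRAMETRIC_TOL = 1e-9


@dataclass
class SimParams:
    """Simulation parameters; rates are events per unit branch length."""

    dup_rate: float = 0.1
    transfer_rate: float = 0.1
    loss_rate: float = 0.1
    unsampled_bifurcation_prob: float = 0.1
    n_families: int = 1
    seed: int = 0
    condition_on_survival: bool = True
    emit_time_slices: bool = True
    allow_nested_bifurcation: bool = False

    def __post_init__(self):
        for name in ("dup_rate", "transfer_rate", "loss_rate"):
            rate = getattr(self, name)
            if not (rate >= 0 and math.isfinite(rate)):
                raise ValueError(f"{name} must be finite and non-negative")
        if not 0.0 <= self.unsampled_bifurcation_prob <= 1.0:
            raise ValueError("unsampled_bifurcation_prob must be in [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")


class DatedSpeciesTree:
    """A binary ultrametric species tree with strictly positive branch
    lengths; node times count backward from the contemporaneous leaves
    (time 0)."""

    def __init__(self, root: SpeciesNode):
        self.root = root
        self.times: Dict[SpeciesNode, float] = {}
        self.parent: Dict[SpeciesNode, Optional[SpeciesNode]] = {root: None}
        self._compute_times(root)
        root.by_name()  # enforce unique names
        # origin: top of the root branch if it has a length, else the root node
        self.origin_time = self.times[root] + (root.branch_length or 0.0)
        # slice boundaries: distinct internal node times, oldest first
        internal = sorted(
            {self.times[n] for n in root.walk() if not n.is_leaf},
            reverse=True,
        )
        self._cuts = internal

    def _compute_times(self, root: SpeciesNode) -> None:
        def height(node: SpeciesNode) -> float:
            if node.is_leaf:
                self.times[node] = 0.0
                return 0.0
            hs = []
            for child in node.children:
                self.parent[child] = node
                if child.branch_length is None or child.branch_length <= 0:
                    raise ModelError(
                        f"dated species tree requires strictly positive "
                        f"branch lengths (node {child.name!r})")
                hs.append(height(child) + child.branch_length)
            if abs(hs[0] - hs[1]) > _ULTRAMETRIC_TOL * max(1.0, abs(hs[0])):
                raise ModelError(
                    f"species tree is not ultrametric at node {node.name!r}: "
                    f"child heights {hs[0]} vs {hs[1]}")
            self.times[node] = max(hs)
            return self.times[node]

        height(root)

    @classmethod
    def from_newick(cls, text: str) -> "DatedSpeciesTree":
        return cls(species_tree_from_plain(read_plain_tree(text)))

    def time_slice(self, t: float) -> int:
        """Rank (0 = oldest interval) of the time interval containing t."""
        return sum(1 for cut in self._cuts if cut > t + 1e-12)

    def branches_alive(self, t: float) -> List[SpeciesNode]:
        """Species branches whose interval [t_node, t_top) contains t, in
        preorder (deterministic)."""
        alive = []
        for node in self.root.walk():
            top = self.origin_time if node is self.root else self.times[self.parent[node]]
            bottom = self.times[node]
            if bottom <= t < top or (node.is_leaf and t <= 0.0):
                alive.append(node)
        return alive


class _FamilySimulator:
    def __init__(self, tree: DatedSpeciesTree, params: SimParams, rng: random.Random):
        self.tree = tree
        self.params = params
        self.rng = rng
        self.leaf_counter: Dict[str, int] = {}
        self.total_rate = params.dup_rate + params.transfer_rate + params.loss_rate
        self.n_leaves = 0

    def _slice_attrs(self, t: float) -> dict:
        if not self.params.emit_time_slices:
            return {}
        return {"time_slice": self.tree.time_slice(t)}

    def _leaf_name(self, species: str) -> str:
        k = self.leaf_counter.get(species, 0) + 1
        self.leaf_counter[species] = k
        return f"{species}_{k}"

    def run(self) -> GeneNode:
        return self._lineage(self.tree.root, self.tree.origin_time, [])

    def _lineage(self, sp: SpeciesNode, t: float, prefix: List[Event]) -> GeneNode:
        """Evolve one lineage inside branch ``sp`` from time ``t`` down."""
        params = self.params
        t_node = self.tree.times[sp]
        while True:
            wait = (
                self.rng.expovariate(self.total_rate)
                if self.total_rate > 0
                else math.inf
            )
            if t - wait <= t_node:
                break
            t = t - wait
            u = self.rng.random() * self.total_rate
            if u < params.dup_rate:
                event = Event(EventType.DUPLICATION, species_location=sp.name,
                              **self._slice_attrs(t))
                return GeneNode(
                    name="",
                    events=EventSequence(prefix + [event]),
                    children=(
                        self._lineage(sp, t, []),
                        self._lineage(sp, t, []),
                    ),
                )
            if u < params.dup_rate + params.loss_rate:
                event = Event(EventType.LOSS, species_location=sp.name,
                              **self._slice_attrs(t))
                return GeneNode(name="LOST", events=EventSequence(prefix + [event]))
            # transfer: donor-side branchingOut unless no recipient can exist
            if len(self.tree.times) > 1:
                event = Event(EventType.BRANCHING_OUT, species_location=sp.name,
                              **self._slice_attrs(t))
                return GeneNode(
                    name="",
                    events=EventSequence(prefix + [event]),
                    children=(
                        self._lineage(sp, t, []),
                        self._emigrant(sp, t, can_bifurcate=True),
                    ),
                )
            # single-branch tree: nowhere to go, the draw is a no-op
        # reached the bottom of the branch
        if sp.is_leaf:
            name = self._leaf_name(sp.name)
            self.n_leaves += 1
            event = Event(EventType.LEAF, species_location=sp.name,
                          gene_name=name, **self._slice_attrs(0.0))
            return GeneNode(name=name, events=EventSequence(prefix + [event]))
        event = Event(EventType.SPECIATION, species_location=sp.name,
                      **self._slice_attrs(t_node))
        return GeneNode(
            name="",
            events=EventSequence(prefix + [event]),
            children=tuple(
                self._lineage(child, t_node, []) for child in sp.children
            ),
        )

    def _emigrant(self, donor: SpeciesNode, t: float, can_bifurcate: bool) -> GeneNode:
        """A lineage that just left ``donor`` at time ``t`` into the
        unsampled compartment."""
        params = self.params
        if can_bifurcate and self.rng.random() < params.unsampled_bifurcation_prob:
            dwell = self._dwell(t)
            t_bif = t - dwell
            event = Event(EventType.BIFURCATION_OUT, **self._slice_attrs(t_bif))
            nested = params.allow_nested_bifurcation
            return GeneNode(
                name="",
                events=EventSequence([event]),
                children=(
                    self._emigrant(donor, t_bif, can_bifurcate=nested),
                    self._emigrant(donor, t_bif, can_bifurcate=nested),
                ),
            )
        t_re = t - self._dwell(t)
        candidates = [
            b for b in self.tree.branches_alive(t_re) if b is not donor
        ] or self.tree.branches_alive(t_re)
        recipient = candidates[self.rng.randrange(len(candidates))]
        back = Event(EventType.TRANSFER_BACK,
                     destination_species=recipient.name,
                     **self._slice_attrs(t_re))
        return self._lineage(recipient, t_re, [back])

    def _dwell(self, t: float) -> float:
        """Time spent in the unsampled compartment, capped at the time left."""
        rate = self.params.transfer_rate
        dwell = self.rng.expovariate(rate) if rate > 0 else math.inf
        return min(dwell, t)


def simulate_family(
    species_tree: DatedSpeciesTree,
    params: SimParams,
    rng: Optional[random.Random] = None,
) -> GeneNode:
    """Simulate one gene family; with ``condition_on_survival`` families with
    no surviving leaf are rejected and redrawn."""
    rng = rng if rng is not None else random.Random(params.seed)
    for _ in range(100_000):
        sim = _FamilySimulator(species_tree, params, rng)
        tree = sim.run()
        if not params.condition_on_survival or sim.n_leaves > 0:
            return tree
    raise RuntimeError(
        "no surviving family in 100000 draws; loss rate is too high to "
        "condition on survival")


def simulate_dataset(
    species_tree: DatedSpeciesTree, params: SimParams
) -> RecPhyloDocument:
    """Simulate ``n_families`` families reconciled to the same species tree;
    fully reproducible from ``params.seed``."""
    rng = random.Random(params.seed)
    families = [
        simulate_family(species_tree, params, rng)
        for _ in range(params.n_families)
    ]
    return RecPhyloDocument(gene_trees=families, species_tree=species_tree.root)


def load_params(path: str, **overrides) -> SimParams:
    """Read parameters from a YAML (or ``key=value`` lines) config file."""
    import yaml

    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text)
    if isinstance(data, str):  # plain key=value lines
        data = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = yaml.safe_load(value.strip())
    if not isinstance(data, dict):
        raise ValueError(f"cannot interpret config file {path!r}")
    params = SimParams()
    return replace(params, **{k: v for k, v in data.items()})
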