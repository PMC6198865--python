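"""DTL simulator: limits, determinism, validator closure and the pure-birth
expectation."""

import math
import random

import pytest

from oracles import consistent
from recphylo.convert import count_events
from recphylo.io import recphylo_to_string
from recphylo.model import EventType, ModelError
from recphylo.simulate import (
    DatedSpeciesTree,
    SimParams,
    load_params,
    simulate_dataset,
    simulate_family,
)
from recphylo.validation import validate_semantics, validate_structure


class TestDatedSpeciesTree:
    def test_node_times_from_branch_lengths(self, dated_tree):
        times = {n.name: t for n, t in dated_tree.times.items()}
        assert times == {"A": 0.0, "B": 0.0, "C": 0.0, "AB": 1.0, "R": 2.0}
        assert dated_tree.origin_time == pytest.approx(2.5)

    def test_non_ultrametric_tree_is_rejected(self):
        with pytest.raises(ModelError, match="ultrametric"):
            DatedSpeciesTree.from_newick("((A:1,B:2):1,C:2);")

    def test_nonpositive_branch_length_is_rejected(self):
        with pytest.raises(ModelError, match="positive"):
            DatedSpeciesTree.from_newick("((A:1,B:1):0,C:1);")

    def test_branches_alive_excludes_finished_lineages(self, dated_tree):
        alive = {n.name for n in dated_tree.branches_alive(1.5)}
        assert alive == {"AB", "C"}
        alive0 = {n.name for n in dated_tree.branches_alive(0.0)}
        assert alive0 == {"A", "B", "C"}

    def test_time_slices_rank_from_the_root(self, dated_tree):
        assert dated_tree.time_slice(2.2) == 0  # above the root speciation
        assert dated_tree.time_slice(1.5) == 1  # between R and AB
        assert dated_tree.time_slice(0.5) == 2  # below AB


class TestLimits:
    def test_zero_rates_reproduce_the_species_tree(self, dated_tree):
        params = SimParams(dup_rate=0, transfer_rate=0, loss_rate=0,
                           n_families=1, seed=5)
        doc = simulate_dataset(dated_tree, params)
        census = count_events(doc)
        assert dict(census.total) == {EventType.SPECIATION: 2, EventType.LEAF: 3}
        leaves = sorted(
            n.events.terminal.species_location
            for n in doc.gene_trees[0].walk() if not n.children
        )
        assert leaves == ["A", "B", "C"]

    def test_zero_transfer_rate_emits_no_transfer_tags(self, dated_tree):
        params = SimParams(dup_rate=0.5, transfer_rate=0, loss_rate=0.3,
                           n_families=20, seed=11)
        census = count_events(simulate_dataset(dated_tree, params)).total
        assert census[EventType.BRANCHING_OUT] == 0
        assert census[EventType.TRANSFER_BACK] == 0
        assert census[EventType.BIFURCATION_OUT] == 0

    def test_pure_duplication_mean_matches_exponential_growth(self):
        """Pure-birth process on one branch of length T: E[leaves] = e^{dT},
        checked within 3 Monte-Carlo standard errors."""
        tree = DatedSpeciesTree.from_newick("A:1;")
        delta = 0.5
        params = SimParams(dup_rate=delta, transfer_rate=0, loss_rate=0,
                           n_families=1, seed=0, condition_on_survival=False,
                           emit_time_slices=False)
        rng = random.Random(1234)
        n = 10_000
        counts = []
        for _ in range(n):
            family = simulate_family(tree, params, rng)
            counts.append(sum(1 for nd in family.walk() if not nd.children))
        mean = sum(counts) / n
        var = sum((c - mean) ** 2 for c in counts) / (n - 1)
        se = math.sqrt(var / n)
        assert abs(mean - math.exp(delta)) <= 3 * se


class TestDataset:
    def test_family_count(self, dated_tree):
        params = SimParams(n_families=5, seed=3)
        doc = simulate_dataset(dated_tree, params)
        assert len(doc.gene_trees) == 5
        assert doc.species_tree is dated_tree.root

    def test_same_seed_gives_byte_identical_output(self, dated_tree):
        params = SimParams(dup_rate=0.4, transfer_rate=0.4, loss_rate=0.3,
                           unsampled_bifurcation_prob=0.4, n_families=4, seed=99)
        one = recphylo_to_string(simulate_dataset(dated_tree, params))
        two = recphylo_to_string(simulate_dataset(dated_tree, params))
        assert one == two

    def test_unconditioned_high_loss_families_still_validate(self, dated_tree):
        params = SimParams(dup_rate=0.05, transfer_rate=0.05, loss_rate=3.0,
                           n_families=20, seed=7, condition_on_survival=False)
        doc = simulate_dataset(dated_tree, params)
        assert validate_structure(doc).valid
        assert validate_semantics(doc, level="strict").valid

    def test_survival_conditioning_keeps_at_least_one_leaf(self, dated_tree):
        params = SimParams(dup_rate=0.05, transfer_rate=0.05, loss_rate=1.2,
                           n_families=30, seed=8, condition_on_survival=True)
        doc = simulate_dataset(dated_tree, params)
        for tree in doc.gene_trees:
            assert any(
                n.events.terminal.event_type is EventType.LEAF for n in tree.walk()
            )


class TestClosure:
    def test_simulated_documents_pass_strict_validation(self, dated_tree, rng):
        """Validator closure over random parameter draws (structure,
        semantics, and the independent oracle)."""
        for i in range(250):
            params = SimParams(
                dup_rate=rng.uniform(0, 0.8),
                transfer_rate=rng.uniform(0, 0.8),
                loss_rate=rng.uniform(0, 0.8),
                unsampled_bifurcation_prob=rng.uniform(0, 1),
                n_families=1,
                seed=rng.randrange(2**31),
                condition_on_survival=False,
            )
            doc = simulate_dataset(dated_tree, params)
            assert validate_structure(doc).valid
            assert validate_semantics(doc, level="strict").valid
            if i % 10 == 0:
                assert consistent(doc)

    def test_two_step_transfer_representation(self, simulated_corpus):
        """Every reception (transferBack) hangs below a donor-side
        branchingOut or bifurcationOut."""
        n_transfers = 0
        for doc in simulated_corpus:
            for tree in doc.gene_trees:
                stack = [(tree, None)]
                while stack:
                    node, parent = stack.pop()
                    if node.events[0].event_type is EventType.TRANSFER_BACK:
                        n_transfers += 1
                        assert parent is not None
                        assert parent.events.terminal.event_type in (
                            EventType.BRANCHING_OUT, EventType.BIFURCATION_OUT)
                    stack.extend((c, node) for c in node.children)
        assert n_transfers > 0  # the corpus exercises transfers

    def test_recipients_are_alive_at_the_transfer_time(self, dated_tree):
        """timeSlice of each transferBack is compatible with the recipient
        branch's life span."""
        params = SimParams(dup_rate=0.2, transfer_rate=0.8, loss_rate=0.2,
                           unsampled_bifurcation_prob=0.3, n_families=20, seed=21)
        doc = simulate_dataset(dated_tree, params)
        spans = {}
        for node in dated_tree.root.walk():
            top = (dated_tree.origin_time if node is dated_tree.root
                   else dated_tree.times[dated_tree.parent[node]])
            spans[node.name] = (dated_tree.times[node], top)
        checked = 0
        for tree in doc.gene_trees:
            for node in tree.walk():
                for ev in node.events:
                    if ev.event_type is not EventType.TRANSFER_BACK:
                        continue
                    bottom, top = spans[ev.destination_species]
                    lo = dated_tree.time_slice(top - 1e-9)
                    hi = dated_tree.time_slice(bottom)
                    assert lo <= ev.time_slice <= hi
                    checked += 1
        assert checked > 0


class TestConfig:
    def test_yaml_and_keyvalue_configs(self, tmp_path):
        y = tmp_path / "params.yaml"
        y.write_text("dup_rate: 0.2\nn_families: 7\n")
        params = load_params(str(y))
        assert params.dup_rate == 0.2 and params.n_families == 7
        k = tmp_path / "params.cfg"
        k.write_text("loss_rate=0.4\nseed=12\n")
        params = load_params(str(k))
        assert params.loss_rate == 0.4 and params.seed == 12

    def test_invalid_rates_are_rejected(self):
        with pytest.raises(ValueError):
            SimParams(dup_rate=-1)
        with pytest.raises(ValueError):
            SimParams(unsampled_bifurcation_prob=1.5)
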