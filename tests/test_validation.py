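"""Structural and semantic validation, checked against an independent
lineage-threading legality oracle."""

import itertools
import random

import pytest

import listings
from oracles import consistent
from recphylo.io import read_recphylo
from recphylo.model import (
    Event,
    EventSequence,
    EventType,
    GeneNode,
    ModelError,
    RecPhyloDocument,
    SpeciesNode,
    UNSAMPLED,
    make_event,
)
from recphylo.validation import (
    build_reconciliation_map,
    validate_semantics,
    validate_structure,
)


def ev(tag, **attrs):
    mapping = {"species_location": "speciesLocation",
               "destination_species": "destinationSpecies",
               "time_slice": "timeSlice"}
    return make_event(tag, {mapping.get(k, k): v for k, v in attrs.items()})


def leaf(species, name="g"):
    return GeneNode(name=name, events=EventSequence([ev("leaf", species_location=species)]))


def species_bca():
    return SpeciesNode(name="A", children=(SpeciesNode(name="B"), SpeciesNode(name="C")))


class TestStructure:
    def test_canonical_branchingout_document_is_valid(self, listing_documents):
        assert validate_structure(listing_documents["branchingOut"]).valid

    def test_early_terminal_is_flagged(self):
        bad_seq = EventSequence.unchecked(
            [ev("leaf", species_location="C"), ev("loss", species_location="C")]
        )
        node = GeneNode.unchecked(name="x", events=bad_seq)
        doc = RecPhyloDocument.unchecked([node])
        report = validate_structure(doc)
        assert not report.valid
        assert "E_EARLY_TERMINAL" in report.codes()

    def test_missing_terminal_is_flagged(self):
        bad_seq = EventSequence.unchecked([ev("transferBack", destination_species="B")])
        doc = RecPhyloDocument.unchecked([GeneNode.unchecked(name="x", events=bad_seq)])
        assert "E_NO_TERMINAL" in validate_structure(doc).codes()

    def test_arity_mismatch_is_flagged(self):
        node = GeneNode.unchecked(
            name="x",
            events=EventSequence.unchecked([ev("speciation", species_location="A")]),
            children=(),
        )
        report = validate_structure(RecPhyloDocument.unchecked([node]))
        assert "E_ARITY" in report.codes()

    def test_attribute_rules_are_flagged(self):
        bad = Event.unchecked(EventType.BIFURCATION_OUT, species_location="A")
        node = GeneNode.unchecked(
            name="x", events=EventSequence.unchecked([bad]),
            children=(leaf("C"), leaf("C")),
        )
        assert "E_ATTR" in validate_structure(RecPhyloDocument.unchecked([node])).codes()

    def test_document_cardinality_is_flagged(self):
        assert "E_DOC" in validate_structure(RecPhyloDocument.unchecked([])).codes()

    def test_out_of_range_confidence_is_a_warning_not_an_error(self):
        node = GeneNode(
            name="x",
            events=EventSequence([make_event("leaf", {"speciesLocation": "C",
                                                      "confidence": "1.7"})]),
        )
        report = validate_structure(RecPhyloDocument([node]))
        assert report.valid
        assert "W_CONFIDENCE" in report.codes()


class TestSemantics:
    def doc(self, *trees, sp=None):
        return RecPhyloDocument(gene_trees=list(trees), species_tree=sp or species_bca())

    def test_unknown_species_is_an_error_in_both_levels(self):
        d = self.doc(leaf("Z"))
        for level in ("strict", "lenient"):
            report = validate_semantics(d, level=level)
            assert "E_SPECIES_UNKNOWN" in report.codes()
            assert not report.valid

    def test_missing_species_tree_downgrades_to_warning(self):
        d = RecPhyloDocument(gene_trees=[leaf("Z")])
        report = validate_semantics(d)
        assert report.valid
        assert "W_NO_SPTREE" in report.codes()

    def test_speciation_children_must_be_the_two_child_species(self):
        bad = GeneNode(
            name="n",
            events=EventSequence([ev("speciation", species_location="A")]),
            children=(leaf("C"), leaf("C")),
        )
        report = validate_semantics(self.doc(bad))
        assert "E_SPECIATION_CHILDREN" in report.codes()
        assert not consistent(self.doc(bad))

    def test_duplication_children_must_stay_in_place(self):
        bad = GeneNode(
            name="n",
            events=EventSequence([ev("duplication", species_location="A")]),
            children=(leaf("B"), leaf("C")),
        )
        report = validate_semantics(self.doc(bad))
        assert "E_DUP_CHILDREN" in report.codes()
        assert not consistent(self.doc(bad))

    def test_orphan_transferback_is_an_error(self):
        receiver = GeneNode(
            name="r",
            events=EventSequence([
                ev("transferBack", destination_species="B"),
                ev("leaf", species_location="B"),
            ]),
        )
        bad = GeneNode(
            name="n",
            events=EventSequence([ev("duplication", species_location="C")]),
            children=(leaf("C"), receiver),
        )
        report = validate_semantics(self.doc(bad))
        assert "E_ORPHAN_TRANSFERBACK" in report.codes()
        assert not consistent(self.doc(bad))

    def test_fig2c_branchingout_with_resident_loss_is_valid(self, listing_documents):
        doc = listing_documents["branchingOut_loss"]
        assert validate_semantics(doc, level="strict").valid
        assert consistent(doc)

    def test_root_transferback_is_a_warning_only(self, listing_documents):
        doc = listing_documents["transferBack"]
        report = validate_semantics(doc)
        assert report.valid
        assert "W_ROOT_TRANSFERBACK" in report.codes()

    def test_self_transfer_in_a_chain_is_an_error(self):
        receiver = GeneNode(
            name="r",
            events=EventSequence([
                ev("transferBack", destination_species="B"),
                ev("transferBack", destination_species="B"),
                ev("leaf", species_location="B"),
            ]),
        )
        bad = GeneNode(
            name="n",
            events=EventSequence([ev("branchingOut", species_location="C")]),
            children=(leaf("C"), receiver),
        )
        report = validate_semantics(self.doc(bad))
        assert "E_TRANSFER_SELF" in report.codes()
        assert not consistent(self.doc(bad))

    def test_timeslice_must_not_decrease_toward_the_leaves(self):
        child = GeneNode(
            name="g",
            events=EventSequence([make_event("leaf", {"speciesLocation": "C",
                                                      "timeSlice": "0"})]),
        )
        other = GeneNode(
            name="h",
            events=EventSequence([make_event("leaf", {"speciesLocation": "B",
                                                      "timeSlice": "2"})]),
        )
        root = GeneNode(
            name="n",
            events=EventSequence([make_event("speciation", {"speciesLocation": "A",
                                                            "timeSlice": "1"})]),
            children=(other, child),
        )
        report = validate_semantics(self.doc(root))
        assert "W_TIMESLICE" in report.codes()
        assert report.valid  # a warning, not an error

    def test_lenient_level_only_checks_resolution_and_timeslices(self):
        bad = GeneNode(
            name="n",
            events=EventSequence([ev("duplication", species_location="A")]),
            children=(leaf("B"), leaf("C")),
        )
        assert validate_semantics(self.doc(bad), level="lenient").valid
        assert not validate_semantics(self.doc(bad), level="strict").valid


class TestReconciliationMap:
    def test_leaf_maps_to_its_species(self, listing_documents):
        doc = listing_documents["leaf"]
        recmap = build_reconciliation_map(doc)
        assert recmap[doc.gene_trees[0]].name == "C"

    def test_bifurcationout_maps_to_unsampled(self, listing_documents):
        doc = listing_documents["bifurcationOut"]
        recmap = build_reconciliation_map(doc)
        assert recmap[doc.gene_trees[0]] is UNSAMPLED
        # total assignment over all gene nodes
        assert len(recmap) == sum(
            1 for t in doc.gene_trees for _ in t.walk()
        )

    def test_unknown_species_raises(self):
        doc = RecPhyloDocument(gene_trees=[leaf("Z")], species_tree=species_bca())
        with pytest.raises(ModelError, match="'Z'"):
            build_reconciliation_map(doc)


# ---------------------------------------------------------------------------
# Validator vs independent oracle

def _sequence_options(species_names, is_leaf):
    """All event sequences with at most one leading transferBack."""
    terminals = []
    if is_leaf:
        for s in species_names:
            terminals.append([ev("leaf", species_location=s)])
            terminals.append([ev("loss", species_location=s)])
    else:
        for s in species_names:
            for tag in ("speciation", "duplication", "branchingOut"):
                terminals.append([ev(tag, species_location=s)])
        terminals.append([ev("bifurcationOut")])
    options = []
    for term in terminals:
        options.append(term)
        for d in species_names:
            options.append([ev("transferBack", destination_species=d)] + term)
    return options


def _three_node_docs(sp):
    names = sorted(n.name for n in sp.walk())
    leaf_opts = _sequence_options(names, is_leaf=True)
    int_opts = _sequence_options(names, is_leaf=False)
    for root_seq, left_seq, right_seq in itertools.product(int_opts, leaf_opts, leaf_opts):
        left = GeneNode.unchecked(name="l", events=EventSequence(left_seq))
        right = GeneNode.unchecked(name="r", events=EventSequence(right_seq))
        root = GeneNode.unchecked(name="n", events=EventSequence(root_seq),
                                  children=(left, right))
        yield RecPhyloDocument.unchecked([root], species_tree=sp)


class TestValidatorAgainstOracle:
    def test_exhaustive_agreement_on_three_node_gene_trees(self):
        """Every event assignment of a cherry over the 3-species tree is
        classified identically by the validator and the oracle."""
        sp = species_bca()
        n_checked = n_valid = 0
        for doc in _three_node_docs(sp):
            verdict = validate_semantics(doc, level="strict").valid
            assert verdict == consistent(doc)
            n_checked += 1
            n_valid += verdict
        assert n_checked == (10 * 4) * (6 * 4) ** 2  # full enumeration ran
        assert 0 < n_valid < n_checked

    def test_randomized_agreement_on_larger_instances(self, rng):
        """Random event assignments on up to 7-node gene trees over a
        4-leaf species tree: validator verdict == oracle verdict."""
        sp = SpeciesNode(
            name="R",
            children=(
                SpeciesNode(name="AB", children=(SpeciesNode(name="A"), SpeciesNode(name="B"))),
                SpeciesNode(name="CD", children=(SpeciesNode(name="C"), SpeciesNode(name="D"))),
            ),
        )
        names = sorted(n.name for n in sp.walk())
        leaf_opts = _sequence_options(names, is_leaf=True)
        int_opts = _sequence_options(names, is_leaf=False)

        def random_tree(n_leaves):
            if n_leaves == 1:
                return GeneNode.unchecked(
                    name="l", events=EventSequence(rng.choice(leaf_opts)))
            k = rng.randint(1, n_leaves - 1)
            return GeneNode.unchecked(
                name="n",
                events=EventSequence(rng.choice(int_opts)),
                children=(random_tree(k), random_tree(n_leaves - k)),
            )

        for _ in range(4000):
            doc = RecPhyloDocument.unchecked(
                [random_tree(rng.randint(2, 4))], species_tree=sp)
            assert validate_semantics(doc, level="strict").valid == consistent(doc)

    def test_oracle_confirms_simulated_documents(self, simulated_corpus):
        """The independent checker agrees on the valid side too: every
        simulated reconciliation is legal."""
        for doc in simulated_corpus[:10]:
            assert validate_semantics(doc, level="strict").valid
            assert consistent(doc)


class TestMutationKillsValidity:
    """Any single corrupting edit to a valid reconciliation flips it invalid."""

    def _valid_doc(self, listing_documents):
        return listing_documents["loss"]  # speciation(A) over leaf(C)+loss(B)

    def test_swapping_a_childs_species_breaks_validity(self, listing_documents):
        text = listings.EVENT_TAG_DOCUMENTS["loss"].replace(
            '<loss speciesLocation="B">', '<loss speciesLocation="C">')
        doc, _ = read_recphylo(text)
        assert not validate_semantics(doc).valid

    def test_retyping_speciation_as_duplication_breaks_validity(self, listing_documents):
        text = listings.EVENT_TAG_DOCUMENTS["loss"].replace(
            '<speciation speciesLocation="A"> </speciation>',
            '<duplication speciesLocation="A"> </duplication>')
        doc, _ = read_recphylo(text)
        assert not validate_semantics(doc).valid

    def test_deleting_the_terminal_event_breaks_validity(self, listing_documents):
        doc = listing_documents["loss"]
        gutted = GeneNode.unchecked(
            name=doc.gene_trees[0].name,
            events=EventSequence.unchecked([]),
            children=doc.gene_trees[0].children,
        )
        bad = RecPhyloDocument.unchecked([gutted], species_tree=doc.species_tree)
        assert not validate_structure(bad).valid
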