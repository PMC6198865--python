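"""Canonical recGeneTreeXML example clades and minimal documents.

Each ``*_CLADE`` constant is one published example clade for a single event
tag, with typographic quotes normalized to XML double quotes.  Fragments
whose terminal event bifurcates are completed with the two child clades the
grammar requires; ``wrap`` embeds a clade in a minimal full document.
"""

SPECIES_TREE_BCA = """
    <spTree>
      <phylogeny rooted="true">
        <clade>
          <name>A</name>
          <clade>
            <name>B</name>
          </clade>
          <clade>
            <name>C</name>
          </clade>
        </clade>
      </phylogeny>
    </spTree>
"""

LEAF_CLADE = """
<clade>
  <name>gene_seq_1</name>
  <eventsRec>
    <leaf speciesLocation="C"></leaf>
  </eventsRec>
</clade>
"""

SPECIATION_CLADE = """
<clade>
 <name>n1</name>
 <eventsRec>
 <speciation speciesLocation="A"></speciation>
 </eventsRec>
 <clade>
  <name>gene_b</name>
  <eventsRec>
   <leaf speciesLocation="B"></leaf>
  </eventsRec>
 </clade>
 <clade>
  <name>gene_c</name>
  <eventsRec>
   <leaf speciesLocation="C"></leaf>
  </eventsRec>
 </clade>
</clade>
"""

LOSS_CLADE = """
<!--Example with end tag <leaf>-->
<clade>
  <name>n1</name>
  <eventsRec>
    <speciation speciesLocation="A"> </speciation>
  </eventsRec>
  <clade>
    <name>gene_seq_1</name>
    <eventsRec>
      <leaf speciesLocation="C"></leaf>
    </eventsRec>
  </clade>
  <clade>
    <name>LOST</name>
    <eventsRec>
      <loss speciesLocation="B"></loss>
    </eventsRec>
  </clade>
</clade>
"""

DUPLICATION_CLADE = """
<clade>
  <name>n1</name>
  <eventsRec>
    <duplication speciesLocation="C">
              </duplication>
  </eventsRec>
  <clade>
    <name>copy_1</name>
    <eventsRec>
      <leaf speciesLocation="C"></leaf>
    </eventsRec>
  </clade>
  <clade>
    <name>copy_2</name>
    <eventsRec>
      <leaf speciesLocation="C"></leaf>
    </eventsRec>
  </clade>
</clade>
"""

BRANCHING_OUT_CLADE = """
<clade>
  <name>n1</name>
  <eventsRec>
    <branchingOut speciesLocation="C">
               </branchingOut>
  </eventsRec>
  <clade>
    <name>resident</name>
    <eventsRec>
      <leaf speciesLocation="C"></leaf>
    </eventsRec>
  </clade>
  <clade>
    <name>gene_seq_2</name>
    <eventsRec>
      <transferBack destinationSpecies="B">
                 </transferBack>
      <leaf speciesLocation="B"></leaf>
    </eventsRec>
  </clade>
</clade>
"""

TRANSFER_BACK_CLADE = """
<!--Example with end tag <leaf> -->
<clade>
  <name>gene_seq_2</name>
  <eventsRec>
    <transferBack destinationSpecies="B">
               </transferBack>
    <leaf speciesLocation="B"></leaf>
  </eventsRec>
</clade>
"""

BIFURCATION_OUT_CLADE = """
<clade>
  <name>n1</name>
  <eventsRec>
    <bifurcationOut></bifurcationOut>
  </eventsRec>
  <clade>
    <name>back_b</name>
    <eventsRec>
      <transferBack destinationSpecies="B"></transferBack>
      <leaf speciesLocation="B"></leaf>
    </eventsRec>
  </clade>
  <clade>
    <name>back_c</name>
    <eventsRec>
      <transferBack destinationSpecies="C"></transferBack>
      <leaf speciesLocation="C"></leaf>
    </eventsRec>
  </clade>
</clade>
"""

# branchingOut followed by a loss on the resident side (transfer where the
# donor copy later disappears)
BRANCHING_OUT_LOSS_CLADE = """
<clade>
  <name>n1</name>
  <eventsRec>
    <branchingOut speciesLocation="C"></branchingOut>
  </eventsRec>
  <clade>
    <name>LOST</name>
    <eventsRec>
      <loss speciesLocation="C"></loss>
    </eventsRec>
  </clade>
  <clade>
    <name>gene_seq_2</name>
    <eventsRec>
      <transferBack destinationSpecies="B"></transferBack>
      <leaf speciesLocation="B"></leaf>
    </eventsRec>
  </clade>
</clade>
"""

RECPHYLO_SKELETON = """
<!-- skeleton of a recphylo object with a species tree and two reconciled gene trees -->
<recPhylo>
  <spTree>
    <phylogeny rooted="true">
      <clade>
        <name>A</name>
        <clade>
          <name>B</name>
        </clade>
        <clade>
          <name>C</name>
        </clade>
      </clade>
    </phylogeny>
  </spTree>
  <recGeneTree>
    <phylogeny rooted="true">
      <clade>
        <name>fam1_gene</name>
        <eventsRec>
          <leaf speciesLocation="B"></leaf>
        </eventsRec>
      </clade>
    </phylogeny>
  </recGeneTree>
  <recGeneTree>
    <phylogeny rooted="true">
      <clade>
        <name>fam2_gene</name>
        <eventsRec>
          <leaf speciesLocation="C"></leaf>
        </eventsRec>
      </clade>
    </phylogeny>
  </recGeneTree>
</recPhylo>
"""

GEOGRAPHY_CLADE = """
<clade>
  <name>gene_seq_1</name>
  <geography>
    <area>
      <name>Lyon</name>
      <description>sampling site</description>
      <value>0.9</value>
      <source>observed</source>
    </area>
  </geography>
  <eventsRec>
    <leaf speciesLocation="C"></leaf>
  </eventsRec>
</clade>
"""


def wrap(clade_xml: str, species_tree: str = SPECIES_TREE_BCA) -> str:
    """Embed one gene clade in a minimal full recPhylo document."""
    return (
        "<recPhylo>"
        + species_tree
        + '<recGeneTree><phylogeny rooted="true">'
        + clade_xml
        + "</phylogeny></recGeneTree></recPhylo>"
    )


EVENT_TAG_DOCUMENTS = {
    "leaf": wrap(LEAF_CLADE),
    "speciation": wrap(SPECIATION_CLADE),
    "loss": wrap(LOSS_CLADE),
    "duplication": wrap(DUPLICATION_CLADE),
    "branchingOut": wrap(BRANCHING_OUT_CLADE),
    "branchingOut_loss": wrap(BRANCHING_OUT_LOSS_CLADE),
    "transferBack": wrap(TRANSFER_BACK_CLADE),
    "bifurcationOut": wrap(BIFURCATION_OUT_CLADE),
    "recPhylo_skeleton": RECPHYLO_SKELETON,
    "geography": wrap(GEOGRAPHY_CLADE),
}
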