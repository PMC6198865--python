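# recphylo

A Python toolkit for **recPhyloXML**, the XML interchange format for
*reconciled gene trees* — gene phylogenies annotated, clade by clade, with
the evolutionary events (speciation, duplication, loss, lateral transfer,
evolution in unsampled lineages) that map them onto a species tree.

It is written for people who produce or consume reconciliations:
phylogenomics pipelines that need to read one tool's reconciliations into
another, developers of reconciliation software who want a validating parser
and a visual check of their output, and teachers/students of gene-tree /
species-tree thinking who need small, correct examples.

## The format and the model behind it

A reconciliation associates each gene-tree node with a species-tree node or
branch plus an event.  recPhyloXML stores the gene tree as ordinary
phyloXML-style nested `<clade>` elements, each carrying an `<eventsRec>`
block: a sequence of zero or more `<transferBack>` events followed by exactly
one *terminal* event:

| tag | meaning | arity |
|---|---|---|
| `speciation` | bifurcation caused by a species split | 2 |
| `duplication` | bifurcation within one species branch | 2 |
| `branchingOut` | donor side of a lateral transfer (one copy stays, one leaves) | 2 |
| `bifurcationOut` | bifurcation while evolving in an unsampled/extinct lineage | 2 |
| `transferBack` | recipient side of a transfer (re-entry into a sampled branch) | — |
| `leaf` | extant gene | 0 |
| `loss` | gene-lineage extinction | 0 |

A lateral transfer is always written in two steps — a donor-side
`branchingOut` (or `bifurcationOut`, when the transfer passes through a
lineage absent from the species tree) paired with a recipient-side
`transferBack` — reflecting that most real transfers originate in unsampled
or extinct lineages.  A document (`<recPhylo>`) holds at most one species
tree and one or more gene trees reconciled to it.

The package provides, as both a library (`import recphylo`) and a single
`recphylo` executable:

* **io** — strict/lenient reader and byte-stable writer (unknown phyloXML
  tags and `<geography>` annotations are carried through);
* **validation** — level 1 (event grammar, arity, attributes, document
  structure) and level 2 (semantic consistency of every event against the
  species tree, with machine-readable issue codes);
* **convert** — Newick / NHX export and re-import, event censuses,
  combining documents and extracting gene trees;
* **lca** — most-parsimonious duplication–loss reconciliation of a plain
  gene tree by LCA mapping, emitting recPhyloXML with explicit `LOST`
  leaves;
* **simulate** — a seeded duplication–transfer–loss simulator along a dated
  species tree whose native output is valid recPhyloXML (including
  transfers through an unsampled compartment);
* **render** — deterministic SVG of the gene tree drawn inside the species
  tree's tubes, one restylable glyph per event.

## Worked example

Reconcile a four-gene family against a three-species tree, using the
`SPECIES_GENE` naming convention for the leaf mapping:

```sh
$ cat gene.nwk                      # ((A_1,B_1),(A_2,C_1));
$ cat species.nwk                   # ((A:1,B:1)AB:1,C:2)R;
$ recphylo reconcile --gene gene.nwk --species species.nwk \
      --prefix-separator _ -o rec.xml
$ recphylo count rec.xml
event_type      tree_index      count
leaf    0       4
speciation      0       4
loss    0       2
duplication     0       1
...
```

The LCA reconciliation places the root in species `R` as a **duplication**
(the family has two copies of the `A`/`B`+`C` pattern), then each copy
speciates down the species tree; one copy lost its `C` descendant and the
other its `B` descendant, giving the minimal cost of 1 duplication + 2
losses.  The same reconciliation as NHX (this library's `Ev/S/D/T/C/G/B`
comment dialect, losslessly re-importable with `recphylo convert --to
recphylo`):

```
(((A_1[&&NHX:Ev=leaf:S=A:G=A_1],B_1[&&NHX:Ev=leaf:S=B:G=B_1])[&&NHX:Ev=speciation:S=AB],
  LOST[&&NHX:Ev=loss:S=C])[&&NHX:Ev=speciation:S=R],
 ((A_2[&&NHX:Ev=leaf:S=A:G=A_2],LOST[&&NHX:Ev=loss:S=B])[&&NHX:Ev=speciation:S=AB],
  C_1[&&NHX:Ev=leaf:S=C:G=C_1])[&&NHX:Ev=speciation:S=R])[&&NHX:Ev=duplication:S=R];
```

`recphylo validate rec.xml` exits 0 (strictly valid); `recphylo draw
rec.xml -o rec.svg` draws it.  A simulated dataset with transfers:

```sh
recphylo simulate --species species.nwk --seed 42 --families 5 \
    --dup-rate 0.3 --transfer-rate 0.4 --loss-rate 0.3 -o sim.xml
```

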