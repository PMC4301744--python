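# Methods

## Problem and model

`paleorder` reconstructs the gene order of ancestral genomes from two
inputs: the gene orders of extant genomes and a forest of gene trees
reconciled with a rooted species tree whose internal nodes are the named
ancestors. The method rests on a parsimony argument about *conserved
oriented gene adjacencies*: if two genes are adjacent, in the same relative
transcriptional orientation, in two extant genomes whose evolutionary path
passes through an ancestor A, the most parsimonious explanation is that the
adjacency already existed in A.

### Ancestral gene content

Every gene-tree node carries a species assignment σ (the species-tree node
the gene existed in) and an event label (speciation or duplication).
Missing labels are filled by LCA reconciliation — σ(n) is the species-tree
LCA of the children's assignments, and n is a duplication exactly when it
maps to the same node as one of its children; labels already present in the
input (e.g. from a TreeBest-style pipeline) take precedence, since curated
reconciliations encode information LCA mapping cannot recover after gene
loss.

The content of ancestor A is obtained by collapsing each family's in-clade
extant genes into equivalence classes: walking from a leaf toward the root,
all nodes assigned strictly below A postdate A and collapse; the walk stops
at the first node assigned at-or-above A. A speciation mapped exactly to A
*is* the ancestral gene (one gene, about to speciate). Any other stopping
node — a duplication mapped to A, or any node strictly above A — predates
A, so the copy the walk arrived through is the ancestral gene. Two
consequences worth stating explicitly:

* a duplication mapped exactly to A is resolved as *above* A: both copies
  are counted in A's content (the inherent ambiguity of reconciliation at
  the boundary, fixed deterministically so tests can assert it);
* losses are not modeled: a gene with no surviving in-clade descendant
  simply never appears (observable parsimony).

An outgroup gene maps to *all* content genes in the gene subtree hanging
from the first node at-or-above A on its root path — several after a
whole-genome duplication (WGD) on A's side, which is how duplicated
ancestral regions keep their outgroup evidence.

### Adjacency graph

Only *informative* species pairs are compared for A: pairs whose
species-tree path passes through A (equivalently, their LCA is A, or
exactly one of the two species lies in A's clade). Each genome is projected
onto A's content — genes without an image (lineage-specific) are dropped,
so ancestrally adjacent genes separated by younger insertions still read as
adjacent — and consecutive pairs are collected as oriented adjacencies in
canonical form (an adjacency equals its reverse complement; a jointly
reversed chromosome changes nothing, a flipped relative orientation breaks
the match). The conserved adjacencies of each informative pair are the
intersection of the two projections' adjacency sets; each pair contributes
each adjacency once, so the edge weight is the number of supporting
pairwise comparisons and is bounded by the number of informative pairs.
Genes with several ancestral images contribute one projected entry per
image (spurious combinations receive low weight and lose in the greedy
round); adjacencies of a gene with itself (tandem copies collapsing onto
one ancestral gene) are discarded, as a linear genome has no self-loops.

### Greedy linearization, twice

A linear chromosome allows each gene one upstream and one downstream
neighbour. Conflicts are resolved greedily: edges sorted by weight
descending (ties by canonical adjacency key, ascending — the published rule
orders only by weight; a total order is needed for bit-reproducibility) are
accepted when the required gene *sides* are free and acceptance closes no
cycle. Internally each gene is two extremities (tail, head); an oriented
adjacency joins the outgoing extremity of one gene to the incoming
extremity of the next, which reduces sign-consistency to extremity
availability, and a union–find over genes rejects cycle-closing edges. The
selected edges decompose into maximal signed paths — the *contigs*; genes
with no selected edge become orientation-0 singletons. The cover is maximal
by construction: every rejected edge stays unaddable at the end state.

The second round treats contigs as atomic units (they are never broken):
each projection is re-expressed as a sequence of signed contig occurrences
(a maximal run of consecutive projected genes following one contig forward
or reversed; partial runs still count as occurrences, so a contig split by
a rearrangement appears several times), contig adjacencies are weighted
over the same informative pairs with the same counting rule, and the same
greedy cover links contigs into the final *blocks*. A gene keeps
orientation 0 only as long as no selected adjacency constrains its sign; a
round-1 singleton linked by round 2 is oriented by the selected signed
contig edge. Blocks are sorted by length (then first gene id), each emitted
in the lexicographically smaller of its two reading directions.

## Family assignment

Proteins of a new species are attached to pre-existing families from
protein-similarity search hits: hits are filtered at e-value ≤ 1e-4
(inclusive — the boundary convention is stated so it is testable), multiple
HSPs against one target are averaged into a single per-target score (so
long proteins do not dominate), per-family means are taken over the query's
passing targets in that family, and the arg-max family wins, ties going to
the lexicographically smallest id with a logged warning.

## Synteny views

All views are rank-based (a gene's coordinate is its 0-based position in
its chromosome), so reconstructed block tables can stand in for genomes.
The dotplot lists homologous pairs with both coordinates (paralog mode when
a genome is compared to itself); karyotype painting labels each gene of one
genome with the chromosome of its homolog in the other (modal chromosome on
multiples, ties lexicographic, NA when none). The region alignment view
takes the up-to-(2·window+1)-gene region around a reference gene (window
default 15 per side, a display convention) and groups homologs per target
chromosome, keeping groups of at least two genes — so a genome lacking the
reference gene still appears through its neighbours — with at most `cap`
(default 200) homologs per call, nearest to the reference first.
"Collinear" is deliberately permissive: same-chromosome membership with no
gap or order constraint, the weakest reading consistent with the two-gene
rule. The collinear-run detector used for WGD signatures scans each
chromosome pair for maximal stretches of strictly monotone partner ranks
with no gap limit, so fractionation (interleaved duplicate losses) shortens
a run but does not break it.

## Simulator

The test harness evolves a root genome of single-copy families (balanced
over the requested chromosomes, random strands) down a binary species tree.
Inversions (uniform interval of length ≥ 2, strands flipped), reciprocal
translocations (suffix swaps), fusions (one side possibly
reverse-complemented) and fissions are fixed counts per branch; tandem
duplication, gene gain and gene loss are per-gene binomial rates; WGD is
full doubling followed by independent per-duplicate retention draws
(fractionation), the retained pairs becoming duplication nodes on that
branch. Within a branch the order is WGD, structural events, tandem
duplications and gains, losses last; impossible events (e.g. fission of a
single-gene chromosome) are skipped with a logged notice. Gene trees grow
alongside: speciations add binary nodes tagged with the species-tree node,
duplications add D-tagged nodes, losses kill pending leaves; emitted NHX
trees are pruned of dead lineages with unifurcations suppressed, and carry
the *true* S/D tags. Every internal node's genome is snapshotted as ground
truth, and all randomness flows from one seeded generator (same seed ⇒
byte-identical dataset).

Evaluation compares canonical oriented adjacency sets of the reconstruction
and the truth, after matching reconstructed ancestral genes to true ones by
extant-descendant sets (exact-set match with a best-overlap fallback). The
truth is restricted to *observable* ancestral genes: those with surviving
descendants whose tree evidence actually places them at the ancestor —
either the gene's own node survives pruning (descendants in two lineages)
or a surviving node above it maps at-or-above the ancestor. A family whose
survivors sit in a single descendant lineage is indistinguishable from a
younger family and no parsimony method can place it; counting such genes
would charge the method for information that does not exist in its input.
With no reconstructed adjacencies precision is reported as 1.0.

What the simulator does *not* emulate — and hence what green tests do not
certify about real data: sequence evolution and annotation error, assembly
fragmentation, gene conversion, horizontal transfer, unequal rates across
branches, and reconciliation error in the input gene trees (the emitted
forest is correct by construction; real TreeBest-style forests are not).

## Problem sizes and defaults

The validation suite exercises the regimes the method is meant for:
no-event recovery on 200 genes / 3 chromosomes / 5 species (exact recovery,
3 blocks); a rearrangement regime of 500 genes / 4 chromosomes with 2
inversions + 1 reciprocal translocation per branch and 2% gene loss and
gain, averaged over 10 replicate seeds (mean adjacency precision ≳ 0.99,
recall ≳ 0.97 at the root, against required floors of 0.95 / 0.80); and a
WGD regime of 300 genes with 40% duplicate retention and mild background
events (1 inversion per branch, 1% loss/gain), which yields paralog
collinear runs tens of pairs long and a duplicated region alignment. These
sizes are small enough to keep the whole suite under a few seconds while
leaving each statistic far from its decision boundary.

## Known limitations

* Homology between two ancestors is defined only along an
  ancestor–descendant line; sibling ancestors are rejected rather than
  guessed.
* The greedy cover is a heuristic: a maximum-weight path cover is NP-hard
  in general, and adversarial weight patterns can make the greedy choice
  suboptimal even when a conflict-free cover exists.
* Round 2 never revisits round-1 contigs; an early wrong join cannot be
  undone.
* Ancestral blocks are scaffolds, not karyotypes: no chromosome-number
  inference, no rearrangement-scenario reconstruction.
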