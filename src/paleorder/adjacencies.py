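"""Conserved oriented gene adjacencies and the weighted adjacency graph.

For an ancestor A, each extant genome is first *projected* onto A's gene
content: genes absent from A (lineage-specific) are dropped, so that two
ancestrally adjacent genes remain adjacent in the projection even when
younger genes have been inserted between them.  Two projections from an
informative species pair are then intersected: an oriented adjacency
(two genes consecutive with their strands) conserved in both genomes is a
candidate ancestral adjacency.  Aggregating over all informative pairs
yields a graph whose edge weights count the number of pairwise comparisons
supporting each adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import GenomeTable
from .trees_reconciliation import (
    GeneForest,
    ReconciliationError,
    SpeciesTree,
    _content,
)

Adjacency = tuple[str, int, str, int]


def canonical_adjacency(x: str, sx: int, y: str, sy: int) -> Adjacency:
    """Canonical form of an oriented adjacency.

    ``x`` with sign ``sx`` immediately followed by ``y`` with sign ``sy``
    describes the same local arrangement as its reverse complement (``y``
    with ``-sy`` followed by ``x`` with ``-sx``); the lexicographically
    smaller of the two tuples is canonical.
    """
    a = (x, sx, y, sy)
    b = (y, -sy, x, -sx)
    return a if a <= b else b


@dataclass
class ProjectedOrder:
    """An extant genome filtered to one ancestor's gene content.

    ``chromosomes`` maps each source chromosome to the ordered list of
    (ancestral_gene_id, sign, source_gene_id); the sign is the source
    gene's strand.  Source genes with several ancestral images (e.g.
    unresolved post-WGD paralogy seen from an outgroup) contribute one
    entry per image at their position and are recorded in ``ambiguous``.
    """

    species: str
    ancestor: str
    chromosomes: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)


@dataclass
class AdjacencyGraph:
    """Weighted graph of candidate ancestral adjacencies.

    Nodes are ancestral gene ids (or contig ids in the second round);
    ``weights`` maps each canonical oriented adjacency to the number of
    informative pairwise comparisons supporting it.
    """

    nodes: set[str] = field(default_factory=set)
    weights: dict[Adjacency, int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.weights)


def project_genome(genome: GenomeTable, ancestor: str, forest: GeneForest,
                   stree: SpeciesTree) -> ProjectedOrder:
    """Project one extant genome onto an ancestor's gene content."""
    if genome.species not in stree:
        raise ReconciliationError(
            f"species {genome.species!r} absent from the species tree")
    content = _content(forest, stree, ancestor)
    in_clade = genome.species in stree.clade_leaves(ancestor)
    out = ProjectedOrder(species=genome.species, ancestor=ancestor)
    outgroup_images: dict[str, list[str]] = {}
    if not in_clade:
        outgroup_images = _outgroup_images(genome, ancestor, forest, stree, content)
    for chrom, recs in genome.chromosomes.items():
        row: list[tuple[str, int, str]] = []
        for rec in recs:
            if in_clade:
                image = content.leaf_image.get(rec.gene_id)
                images = [image.id] if image is not None else []
            else:
                images = outgroup_images.get(rec.gene_id, [])
            if not images:
                continue
            if len(images) > 1:
                out.ambiguous.add(rec.gene_id)
            for anc_id in images:
                row.append((anc_id, rec.strand, rec.gene_id))
        if row:
            out.chromosomes[chrom] = row
    return out


def _outgroup_images(genome, ancestor, forest, stree, content):
    from .trees_reconciliation import map_gene_to_ancestor
    images: dict[str, list[str]] = {}
    trees_with_content = {g.tree_index for g in content.genes}
    for rec in genome.records():
        try:
            tree_index, _ = forest.leaf(rec.gene_id)
        except ReconciliationError:
            continue
        if tree_index not in trees_with_content:
            continue
        hits = map_gene_to_ancestor(forest, stree, rec.gene_id, ancestor)
        if hits:
            images[rec.gene_id] = sorted(g.id for g in hits)
    return images


def _oriented_set(projection: ProjectedOrder) -> set[Adjacency]:
    """Canonical oriented adjacencies of all consecutive pairs.

    Chromosome ends contribute nothing (chromosomes are linear) and
    self-adjacencies — tandem copies collapsing onto one ancestral gene —
    are discarded.
    """
    out: set[Adjacency] = set()
    for row in projection.chromosomes.values():
        for (x, sx, _), (y, sy, _) in zip(row, row[1:]):
            if x == y:
                continue
            out.add(canonical_adjacency(x, sx, y, sy))
    return out


def conserved_adjacencies(p1: ProjectedOrder, p2: ProjectedOrder) -> set[Adjacency]:
    """Oriented adjacencies conserved between two projections.

    The intersection of the two canonical adjacency sets: an adjacency
    matches its reverse complement, so jointly reversing a chromosome
    changes nothing, but a gene pair conserved with flipped relative
    orientation does not count.
    """
    if p1.ancestor != p2.ancestor:
        raise ValueError(
            f"projections target different ancestors: {p1.ancestor!r} vs {p2.ancestor!r}")
    return _oriented_set(p1) & _oriented_set(p2)


def weighted_adjacencies(ancestor: str, genomes: dict[str, GenomeTable],
                         forest: GeneForest, stree: SpeciesTree) -> AdjacencyGraph:
    """Aggregate conserved adjacencies over all informative species pairs.

    Each informative pair contributes each conserved adjacency once,
    regardless of copy number inside that comparison; the edge weight is
    therefore the number of supporting pairs and never exceeds the number
    of informative pairs.  Every content gene is a node, isolated or not.
    """
    pairs = sorted(stree.informative_pairs(ancestor))
    needed = sorted({s for pair in pairs for s in pair})
    missing = [s for s in needed if s not in genomes]
    if missing:
        raise ValueError(
            f"missing genome tables for informative species: {', '.join(missing)}")
    projections = {s: project_genome(genomes[s], ancestor, forest, stree)
                   for s in needed}
    adjacency_sets = {s: _oriented_set(projections[s]) for s in needed}
    graph = AdjacencyGraph()
    content = _content(forest, stree, ancestor)
    graph.nodes = {g.id for g in content.genes}
    for s1, s2 in pairs:
        for adj in adjacency_sets[s1] & adjacency_sets[s2]:
            graph.weights[adj] = graph.weights.get(adj, 0) + 1
    return graph
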