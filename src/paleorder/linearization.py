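"""Greedy linearization of adjacency graphs into contigs and blocks.

The weighted adjacency graph generally contains conflicts: an ancestral
gene linked to more than one upstream or downstream neighbour.  A linear
genome allows at most two adjacencies per gene — one on each side — so the
graph is resolved greedily: edges are visited by decreasing weight (ties
broken by canonical adjacency key for reproducibility) and an edge is kept
only if the required gene *sides* are still free and keeping it would not
close a cycle.  The selected edges decompose into maximal signed paths,
the contigs.

A second round treats the contigs themselves as units: each projection is
re-expressed as a sequence of signed contig occurrences, contig
adjacencies are weighted over the same informative pairs, and the same
greedy rule links contigs into the final ancestral blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adjacencies import (
    Adjacency,
    AdjacencyGraph,
    ProjectedOrder,
    conserved_adjacencies,
    project_genome,
    weighted_adjacencies,
)
from .formats_io import BlockTable, GenomeTable
from .trees_reconciliation import GeneForest, SpeciesTree, _content


@dataclass
class Contig:
    """A maximal linear path of signed ancestral genes.

    Singletons carry orientation 0: no selected adjacency constrains their
    sign.  ``edges`` records the selected adjacencies the path is built
    from, in path order.
    """

    genes: list[tuple[str, int]]
    edges: list[Adjacency] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def reverse_complement(self) -> list[tuple[str, int]]:
        return [(g, -s) for g, s in reversed(self.genes)]


# ---------------------------------------------------------------------------
# round core: greedy maximum-weight path cover
# ---------------------------------------------------------------------------

# Each gene has two extremities, tail 't' and head 'h'; a gene traversed
# with sign +1 is read tail-to-head.  An oriented adjacency (x,sx,y,sy)
# joins the outgoing extremity of x to the incoming extremity of y, and its
# reverse complement joins the very same extremity pair, so sign
# consistency reduces to extremity availability.


def _out_ext(gene: str, sign: int) -> tuple[str, str]:
    return (gene, "h" if sign > 0 else "t")


def _in_ext(gene: str, sign: int) -> tuple[str, str]:
    return (gene, "t" if sign > 0 else "h")


def greedy_path_cover(graph: AdjacencyGraph) -> list[Contig]:
    """Select edges greedily (weight descending, canonical key ascending)
    into sign-consistent acyclic paths covering every node.

    An edge is kept iff both extremities it needs are still unused and its
    two genes are not already on the same partial path (union–find);
    every rejected edge stays rejected, so the result is maximal.  The
    output is canonical: each path is emitted in the lexicographically
    smaller of its two reading directions, and paths are sorted.
    """
    order = sorted(graph.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    parent: dict[str, str] = {}

    def find(g: str) -> str:
        root = g
        while parent[root] != root:
            root = parent[root]
        while parent[g] != root:
            parent[g], g = root, parent[g]
        return root

    used: dict[tuple[str, str], tuple[tuple[str, str], Adjacency]] = {}
    for node in graph.nodes:
        parent[node] = node
    for adj, _w in order:
        x, sx, y, sy = adj
        ex, ey = _out_ext(x, sx), _in_ext(y, sy)
        if ex in used or ey in used:
            continue
        if find(x) == find(y):
            continue
        used[ex] = (ey, adj)
        used[ey] = (ex, adj)
        parent[find(x)] = find(y)

    degree: dict[str, int] = {}
    for (gene, _side) in used:
        degree[gene] = degree.get(gene, 0) + 1

    contigs: list[Contig] = []
    visited: set[str] = set()
    for start in sorted(graph.nodes):
        if start in visited:
            continue
        deg = degree.get(start, 0)
        if deg == 0:
            visited.add(start)
            contigs.append(Contig(genes=[(start, 0)]))
            continue
        if deg == 2:
            continue  # interior gene; reached from an endpoint
        # walk from the free extremity through the path
        free_side = "t" if (start, "t") not in used else "h"
        genes: list[tuple[str, int]] = []
        edges: list[Adjacency] = []
        gene, entry_side = start, free_side
        while True:
            visited.add(gene)
            sign = 1 if entry_side == "t" else -1
            genes.append((gene, sign))
            exit_ext = (gene, "h" if entry_side == "t" else "t")
            hop = used.get(exit_ext)
            if hop is None:
                break
            (gene, entry_side), adj = hop
            edges.append(adj)
        rc = [(g, -s) for g, s in reversed(genes)]
        if rc < genes:
            genes = rc
            edges = list(reversed(edges))
        contigs.append(Contig(genes=genes, edges=edges))
    contigs.sort(key=lambda c: c.genes)
    return contigs


# ---------------------------------------------------------------------------
# round 2: contigs as units
# ---------------------------------------------------------------------------


def label_contigs(contigs: list[Contig]) -> dict[str, Contig]:
    """Deterministic contig ids (sorted by gene list)."""
    ordered = sorted(contigs, key=lambda c: c.genes)
    return {f"C{i:06d}": c for i, c in enumerate(ordered)}


def _placement(by_id: dict[str, Contig]) -> dict[str, tuple[str, int, int]]:
    """gene -> (contig id, index within contig, orientation in contig)."""
    out: dict[str, tuple[str, int, int]] = {}
    for cid, contig in by_id.items():
        for idx, (gene, orient) in enumerate(contig.genes):
            if gene in out:
                raise ValueError(f"gene {gene!r} placed in two contigs")
            out[gene] = (cid, idx, orient)
    return out


def contig_projection(projection: ProjectedOrder,
                      placement: dict[str, tuple[str, int, int]],
                      ancestor: str) -> ProjectedOrder:
    """Re-express a gene-level projection as signed contig occurrences.

    A maximal run of consecutive projected genes that follows one contig in
    order (forward with matching signs, or reversed with flipped signs)
    becomes a single signed contig symbol; partial runs still count as an
    occurrence of that contig.  A contig split by a rearrangement appears
    as several symbols.
    """
    out = ProjectedOrder(species=projection.species, ancestor=ancestor)
    for chrom, row in projection.chromosomes.items():
        symbols: list[tuple[str, int, str]] = []
        i = 0
        while i < len(row):
            gene, sign, _src = row[i]
            place = placement.get(gene)
            if place is None:
                i += 1
                continue
            cid, idx, orient = place
            if orient == 0:
                sigma = sign  # singleton contig, reference orientation +1
            elif sign == orient:
                sigma = 1
            elif sign == -orient:
                sigma = -1
            else:  # pragma: no cover - signs are always +/-1
                i += 1
                continue
            j = i + 1
            cur = idx
            while j < len(row):
                gene2, sign2, _ = row[j]
                place2 = placement.get(gene2)
                if place2 is None or place2[0] != cid:
                    break
                cid2, idx2, orient2 = place2
                if idx2 != cur + sigma or orient2 == 0:
                    break
                if sign2 != orient2 * sigma:
                    break
                cur = idx2
                j += 1
            symbols.append((cid, sigma, f"{chrom}:{i}"))
            i = j
        if symbols:
            out.chromosomes[chrom] = symbols
    return out


def contig_adjacency_graph(contigs: list[Contig], ancestor: str,
                           genomes: dict[str, GenomeTable],
                           forest: GeneForest,
                           stree: SpeciesTree) -> tuple[AdjacencyGraph, dict[str, Contig]]:
    """Weighted adjacency graph over contigs, using the same informative
    pairs and the same per-pair counting rule as the gene-level round."""
    by_id = label_contigs(contigs)
    placement = _placement(by_id)
    content = _content(forest, stree, ancestor)
    content_ids = {g.id for g in content.genes}
    placed = set(placement)
    if placed != content_ids:
        raise ValueError("contigs do not partition the ancestral gene content")
    pairs = sorted(stree.informative_pairs(ancestor))
    needed = sorted({s for pair in pairs for s in pair})
    missing = [s for s in needed if s not in genomes]
    if missing:
        raise ValueError(
            f"missing genome tables for informative species: {', '.join(missing)}")
    projections = {
        s: contig_projection(
            project_genome(genomes[s], ancestor, forest, stree), placement, ancestor)
        for s in needed}
    graph = AdjacencyGraph(nodes=set(by_id))
    for s1, s2 in pairs:
        for adj in conserved_adjacencies(projections[s1], projections[s2]):
            graph.weights[adj] = graph.weights.get(adj, 0) + 1
    return graph, by_id


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def reconstruct_ancestor(ancestor: str, genomes: dict[str, GenomeTable],
                         forest: GeneForest, stree: SpeciesTree) -> BlockTable:
    """Reconstruct one ancestor's gene order.

    Pipeline: infer gene content, build the weighted adjacency graph over
    all informative pairs, linearize greedily into contigs, re-compare the
    genomes at contig granularity, linearize the contig graph, and expand
    the selected contig paths into blocks.  Every ancestral gene appears
    exactly once; the output is deterministic for fixed inputs.
    """
    graph = weighted_adjacencies(ancestor, genomes, forest, stree)
    contigs = greedy_path_cover(graph)
    cgraph, by_id = contig_adjacency_graph(contigs, ancestor, genomes, forest, stree)
    contig_paths = greedy_path_cover(cgraph)

    blocks: list[list[tuple[str, int]]] = []
    for path in contig_paths:
        block: list[tuple[str, int]] = []
        for cid, orient in path.genes:
            contig = by_id[cid]
            if orient == 0:
                # contig unlinked in round 2: keep round-1 signs as they are
                block.extend(contig.genes)
            elif orient == 1:
                block.extend((g, s if s != 0 else 1) for g, s in contig.genes)
            else:
                block.extend((g, -s if s != 0 else -1)
                             for g, s in reversed(contig.genes))
        blocks.append(block)
    blocks.sort(key=lambda b: (-len(b), b[0][0]))

    content = _content(forest, stree, ancestor)
    descendants = {g.id: sorted(g.all_descendants()) for g in content.genes}
    return BlockTable(ancestor=ancestor, blocks=blocks, descendants=descendants)
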