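"""On-disk formats: gene-order tables, Newick species trees, NHX gene-tree
forests, ancestral block tables and adjacency dumps.

All tabular formats are plain tab-separated text.  Coordinates in files are
1-based inclusive; in-memory positional indices are 0-based.  Strands are
written as literal ``1`` / ``-1``.  Lines starting with ``#`` are comments.
Writers are deterministic: re-writing a freshly read object is bit-exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from .trees_reconciliation import (
    DUP,
    SPEC,
    GeneForest,
    GeneTreeNode,
    ReconciledGeneTree,
    SpeciesTree,
    SpeciesTreeNode,
)

logger = logging.getLogger("paleorder")


class FormatError(ValueError):
    """A file could not be parsed; carries path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


# ---------------------------------------------------------------------------
# genome tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one chromosome: 1-based inclusive coordinates, signed strand."""

    species: str
    chromosome: str
    start: int
    end: int
    strand: int
    gene_id: str
    family_id: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}")
        if self.strand not in (1, -1):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be 1 or -1")
        if not self.gene_id:
            raise ValidationError("empty gene id")


class GenomeTable:
    """Ordered, stranded gene lists per chromosome for one genome.

    Within a chromosome, genes are sorted by start coordinate and starts are
    strictly increasing (equal starts would make gene order ambiguous, which
    is all the downstream method consumes).
    """

    def __init__(self, species: str, records=()):
        self.species = species
        self.chromosomes: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        by_chrom: dict[str, list[GeneRecord]] = {}
        for rec in records:
            if rec.gene_id in seen:
                raise ValidationError(
                    f"duplicate gene id {rec.gene_id!r} in genome {species!r}")
            seen.add(rec.gene_id)
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom], key=lambda r: r.start)
            for a, b in zip(recs, recs[1:]):
                if a.start == b.start:
                    raise ValidationError(
                        f"genes {a.gene_id!r} and {b.gene_id!r} share start "
                        f"{a.start} on {chrom!r}; gene order is ambiguous")
            self.chromosomes[chrom] = recs

    def __len__(self) -> int:
        return sum(len(r) for r in self.chromosomes.values())

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenomeTable)
                and self.species == other.species
                and self.chromosomes == other.chromosomes)

    def records(self):
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    def order(self, chrom: str) -> list[tuple[str, int]]:
        """(gene_id, strand) along one chromosome."""
        return [(r.gene_id, r.strand) for r in self.chromosomes[chrom]]

    def positions(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (chromosome, 0-based rank)."""
        out = {}
        for chrom, recs in self.chromosomes.items():
            for i, rec in enumerate(recs):
                out[rec.gene_id] = (chrom, i)
        return out


def read_genome_table(path, species: str | None = None) -> GenomeTable:
    """Read a 5/6-column genes table: chromosome, start, end, strand, gene_id
    [, family_id].  Species defaults to the file stem."""
    path = Path(path)
    if species is None:
        species = path.stem
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (5, 6):
                raise FormatError(
                    f"expected 5 or 6 tab-separated columns, got {len(cols)}",
                    path, lineno)
            chrom, start_s, end_s, strand_s, gene_id = cols[:5]
            family = cols[5] if len(cols) == 6 and cols[5] else None
            try:
                start, end, strand = int(start_s), int(end_s), int(strand_s)
            except ValueError:
                raise FormatError("non-integer coordinate or strand", path, lineno) from None
            try:
                records.append(GeneRecord(species, chrom, start, end, strand,
                                          gene_id, family))
            except ValidationError as exc:
                raise FormatError(str(exc), path, lineno) from None
    try:
        return GenomeTable(species, records)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_genome_table(table: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\tstart\tend\tstrand\tgene_id\tfamily_id\n")
        for rec in table.records():
            fh.write(f"{rec.chromosome}\t{rec.start}\t{rec.end}\t{rec.strand}"
                     f"\t{rec.gene_id}\t{rec.family_id or ''}\n")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def read_species_tree(path) -> SpeciesTree:
    """Read a rooted Newick species tree with *named* internal nodes."""
    path = Path(path)
    return parse_species_tree(path.read_text(), source=path)


def parse_species_tree(newick: str, source=None) -> SpeciesTree:
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"bad Newick: {exc}", source) from None

    def convert(dnode, parent):
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            name = dnode.label
        if not name:
            raise FormatError("unnamed species-tree node (all internal nodes "
                              "must be named ancestors)", source)
        node = SpeciesTreeNode(name, parent)
        if parent is not None:
            parent.children.append(node)
        for child in dnode.child_nodes():
            convert(child, node)
        if node.children and len(node.children) < 2:
            raise FormatError(f"internal node {name!r} has a single child", source)
        return node

    root = convert(dtree.seed_node, None)
    try:
        return SpeciesTree(root)
    except ValueError as exc:
        raise FormatError(str(exc), source) from None


def write_species_tree(stree: SpeciesTree, path) -> None:
    Path(path).write_text(species_tree_newick(stree) + "\n")


def species_tree_newick(stree: SpeciesTree) -> str:
    def fmt(node):
        if node.is_leaf:
            return node.name
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
    return fmt(stree.root) + ";"


# ---------------------------------------------------------------------------
# gene forests (NHX)
# ---------------------------------------------------------------------------


def read_gene_forest(path, stree: SpeciesTree | None = None) -> GeneForest:
    """Read an NHX forest, one tree per line.

    Leaves are named by gene id and carry an ``S`` tag (species); internal
    nodes may carry ``S`` and ``D`` (``Y``/``N``) tags.  Missing tags are
    tolerated — :func:`~paleorder.trees_reconciliation.reconcile` fills
    them.  When a species tree is supplied, leaf species are checked
    against it.
    """
    path = Path(path)
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(_parse_nhx_tree(line, stree, path, lineno))
    return GeneForest(trees)


def parse_gene_forest(text: str, stree: SpeciesTree | None = None) -> GeneForest:
    trees = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        trees.append(_parse_nhx_tree(line, stree, None, lineno))
    return GeneForest(trees)


def _parse_nhx_tree(line: str, stree, path, lineno) -> ReconciledGeneTree:
    try:
        dtree = dendropy.Tree.get(
            data=line, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
            extract_comment_metadata=True)
    except Exception as exc:
        raise FormatError(f"bad NHX tree: {exc}", path, lineno) from None

    def convert(dnode, parent):
        ann = {a.name: a.value for a in dnode.annotations}
        if dnode is dtree.seed_node and dnode.is_leaf():
            # a one-leaf tree: dendropy hoists the NHX comment to tree level
            ann = {**{a.name: a.value for a in dtree.annotations}, **ann}
        species = ann.get("S") or None
        d_tag = ann.get("D")
        node = GeneTreeNode(species=species)
        if dnode.is_leaf():
            gene_id = dnode.taxon.label if dnode.taxon else dnode.label
            if not gene_id:
                raise FormatError("unnamed gene-tree leaf", path, lineno)
            node.gene_id = gene_id
            if species is None:
                raise FormatError(f"leaf {gene_id!r} lacks an S (species) tag",
                                  path, lineno)
            if stree is not None and species not in stree:
                raise FormatError(
                    f"leaf {gene_id!r} assigned to species {species!r} absent "
                    "from the species tree", path, lineno)
        else:
            if d_tag is not None:
                node.event = DUP if d_tag.upper() == "Y" else SPEC
        if parent is not None:
            parent.add_child(node)
        for child in dnode.child_nodes():
            convert(child, node)
        if node.children and len(node.children) != 2:
            raise FormatError(
                f"non-binary gene-tree node ({len(node.children)} children)",
                path, lineno)
        return node

    root = convert(dtree.seed_node, None)
    return ReconciledGeneTree(root)


def write_gene_forest(forest: GeneForest, path) -> None:
    with open(path, "w") as fh:
        for tree in forest:
            fh.write(gene_tree_nhx(tree) + "\n")


def gene_tree_nhx(tree: ReconciledGeneTree) -> str:
    def fmt(node: GeneTreeNode) -> str:
        tags = []
        if node.species:
            tags.append(f"S={node.species}")
        if not node.is_leaf and node.event:
            tags.append("D=" + ("Y" if node.event == DUP else "N"))
        nhx = f"[&&NHX:{':'.join(tags)}]" if tags else ""
        if node.is_leaf:
            return f"{node.gene_id}{nhx}"
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + nhx
    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# block tables
# ---------------------------------------------------------------------------


@dataclass
class BlockTable:
    """Reconstructed ancestral blocks: ordered, signed ancestral genes.

    ``blocks`` is a list of blocks, each an ordered list of
    (ancestral_gene_id, orientation) with orientation in {+1, -1, 0}; 0
    marks a gene whose sign the evidence leaves undetermined (singletons).
    ``descendants`` maps each placed ancestral gene to its extant
    descendant gene ids.
    """

    ancestor: str
    blocks: list[list[tuple[str, int]]] = field(default_factory=list)
    descendants: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for block in self.blocks:
            if not block:
                raise ValidationError("empty block")
            for gene, orient in block:
                if gene in seen:
                    raise ValidationError(f"ancestral gene {gene!r} placed twice")
                seen.add(gene)
                if orient not in (1, -1, 0):
                    raise ValidationError(f"bad orientation {orient!r} for {gene!r}")
                if orient == 0 and len(block) > 1:
                    raise ValidationError(
                        f"orientation 0 on {gene!r} inside a multi-gene block")

    def genes(self):
        for block in self.blocks:
            for gene, _ in block:
                yield gene

    def as_genome_table(self, name: str | None = None,
                        block_prefix: str = "block") -> GenomeTable:
        """View the blocks as a genome (one chromosome per block) so that the
        synteny views can treat ancestors like extant genomes."""
        records = []
        for b, block in enumerate(self.blocks):
            chrom = f"{block_prefix}_{b}"
            for pos, (gene, orient) in enumerate(block):
                start = (pos + 1) * 1000
                records.append(GeneRecord(
                    species=name or self.ancestor, chromosome=chrom,
                    start=start, end=start + 500,
                    strand=orient if orient != 0 else 1, gene_id=gene))
        return GenomeTable(name or self.ancestor, records)


_BLOCK_HEADER = "#ancestor\tblock\tposition\tgene\torientation\tdescendants\n"


def write_blocks(blocks: BlockTable, path) -> None:
    """Write a block table: one row per placed ancestral gene, sorted by
    block then position; bit-exact deterministic."""
    with open(path, "w") as fh:
        fh.write(_BLOCK_HEADER)
        for b, block in enumerate(blocks.blocks):
            for pos, (gene, orient) in enumerate(block):
                desc = ";".join(blocks.descendants.get(gene, ()))
                fh.write(f"{blocks.ancestor}\t{b}\t{pos}\t{gene}\t{orient}\t{desc}\n")


def read_blocks(path) -> BlockTable:
    path = Path(path)
    ancestor = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise FormatError(f"expected 6 columns, got {len(cols)}", path, lineno)
            anc, b_s, pos_s, gene, orient_s, desc = cols
            if ancestor is None:
                ancestor = anc
            elif anc != ancestor:
                raise FormatError(f"mixed ancestors {ancestor!r} and {anc!r}",
                                  path, lineno)
            try:
                rows.append((int(b_s), int(pos_s), gene, int(orient_s), desc))
            except ValueError:
                raise FormatError("non-integer block/position/orientation",
                                  path, lineno) from None
    if ancestor is None:
        return BlockTable(ancestor="", blocks=[])
    rows.sort(key=lambda r: (r[0], r[1]))
    blocks: list[list[tuple[str, int]]] = []
    descendants: dict[str, list[str]] = {}
    for b, pos, gene, orient, desc in rows:
        while len(blocks) <= b:
            blocks.append([])
        blocks[b].append((gene, orient))
        if desc:
            descendants[gene] = desc.split(";")
    return BlockTable(ancestor=ancestor, blocks=blocks, descendants=descendants)


# ---------------------------------------------------------------------------
# adjacency dumps
# ---------------------------------------------------------------------------


def write_adjacencies(graph, path) -> None:
    """Dump a weighted adjacency graph: gene1, sign1, gene2, sign2, weight."""
    with open(path, "w") as fh:
        fh.write("#gene1\tsign1\tgene2\tsign2\tweight\n")
        for (x, sx, y, sy) in sorted(graph.weights):
            fh.write(f"{x}\t{sx}\t{y}\t{sy}\t{graph.weights[(x, sx, y, sy)]}\n")


def read_adjacencies(path):
    from .adjacencies import AdjacencyGraph
    path = Path(path)
    weights = {}
    nodes = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"expected 5 columns, got {len(cols)}", path, lineno)
            x, sx, y, sy, w = cols[0], int(cols[1]), cols[2], int(cols[3]), int(cols[4])
            weights[(x, sx, y, sy)] = w
            nodes.update((x, y))
    return AdjacencyGraph(nodes=nodes, weights=weights)
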