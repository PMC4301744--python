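"""Genome-evolution simulator with known ground truth.

A root genome of single-copy gene families is evolved down a (binary)
species tree.  Along each branch the genome can undergo inversions,
reciprocal translocations, chromosome fusions and fissions, tandem
duplications, whole-genome duplication with fractionation, gene gains and
gene losses.  The simulator emits the extant genome tables, the true gene
order of every internal node, a fully reconciled NHX gene-tree forest whose
labels match the logged events, and the event log itself — everything the
reconstruction pipeline consumes plus the truth to score it against.

Event semantics (kept deliberately simple so tests can assert them):
inversions reverse a uniformly chosen interval of length >= 2 and flip
strands; translocations swap uniformly chosen suffixes of two chromosomes;
fusion concatenates two chromosomes (second possibly reverse-complemented);
fission splits at a uniform internal breakpoint; WGD doubles every
chromosome and keeps each extra copy independently with the retention
probability; gains create new single-gene families; losses delete genes.
Within a branch, order is WGD, then structural events, then tandem
duplications and gains, with losses last.  Events that need more material
than the genome has (e.g. a translocation with one chromosome) are skipped
with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import BlockTable, GeneRecord, GenomeTable
from .trees_reconciliation import (
    DUP,
    SPEC,
    AncestralGene,
    GeneForest,
    GeneTreeNode,
    ReconciledGeneTree,
    SpeciesTree,
)
from .adjacencies import canonical_adjacency

logger = logging.getLogger("paleorder")


@dataclass
class SimulationParams:
    """Knobs of the simulator.

    ``inversions``, ``translocations``, ``fusions`` and ``fissions`` are
    fixed event counts per branch; ``tandem``, ``loss`` and ``gain`` are
    per-gene rates per branch (binomially drawn counts); ``wgd`` maps a
    branch — named by its child node — to a duplicate-retention fraction
    in (0, 1].
    """

    genes: int = 200
    chromosomes: int = 3
    inversions: int = 0
    translocations: int = 0
    fusions: int = 0
    fissions: int = 0
    tandem: float = 0.0
    loss: float = 0.0
    gain: float = 0.0
    wgd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.genes < self.chromosomes:
            raise ValueError("need at least one gene per chromosome")
        for value in (self.inversions, self.translocations, self.fusions,
                      self.fissions):
            if value < 0:
                raise ValueError("event counts must be non-negative")
        for rate in (self.tandem, self.loss, self.gain):
            if rate < 0:
                raise ValueError("event rates must be non-negative")
        for branch, retention in self.wgd.items():
            if not 0 < retention <= 1:
                raise ValueError(f"WGD retention on {branch!r} must be in (0, 1]")


class _SimNode:
    """Gene-tree node under construction; pending leaves later become
    speciation/duplication nodes or extant leaves."""

    __slots__ = ("children", "parent", "event", "species", "gene_id", "alive")

    def __init__(self):
        self.children: list[_SimNode] = []
        self.parent: "_SimNode | None" = None
        self.event: str | None = None
        self.species: str | None = None
        self.gene_id: str | None = None
        self.alive = True

    def add_child(self, child: "_SimNode") -> "_SimNode":
        child.parent = self
        self.children.append(child)
        return child

    def has_survivor(self) -> bool:
        stack = [self]
        while stack:
            n = stack.pop()
            if not n.children:
                if n.alive and n.gene_id is not None:
                    return True
            else:
                stack.extend(n.children)
        return False

    def branch_survives(self) -> bool:
        """Whether this node remains after pruning dead lineages and
        suppressing single-child nodes."""
        if not self.children:
            return self.alive and self.gene_id is not None
        return sum(1 for c in self.children if c.has_survivor()) >= 2


class _Copy:
    __slots__ = ("uid", "sign", "node", "family")

    def __init__(self, uid: int, sign: int, node: _SimNode, family: int):
        self.uid = uid
        self.sign = sign
        self.node = node
        self.family = family


@dataclass
class SyntheticDataset:
    """Everything one simulation run produced.

    ``genomes`` holds the extant leaves, ``ancestors`` the true gene order
    of every internal node.  ``truth_nodes`` keeps, per internal node, the
    raw gene-tree node each ancestral gene corresponds to, from which true
    descendant sets are derived.
    """

    stree: SpeciesTree
    params: SimulationParams
    genomes: dict[str, GenomeTable]
    ancestors: dict[str, GenomeTable]
    forest: GeneForest
    events: pd.DataFrame
    truth_nodes: dict[str, dict[str, _SimNode]]

    def true_descendants(self, ancestor: str, gene_id: str) -> frozenset[str]:
        """Extant gene ids descending from one true ancestral gene."""
        node = self.truth_nodes[ancestor][gene_id]
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if not n.children:
                if n.alive and n.gene_id is not None:
                    out.append(n.gene_id)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def observable_truth(self, ancestor: str) -> dict[str, frozenset[str]]:
        """True ancestral genes a parsimony reconstruction can see.

        A gene must have surviving extant descendants, *and* there must be
        evidence it already existed at the ancestor: either its own node
        survives pruning (descendants in two lineages), or some surviving
        node above it maps at-or-above the ancestor (descendants outside
        the clade, or a retained duplicate).  A family whose survivors are
        confined to one descendant lineage is indistinguishable from a
        younger family and is not observable at this ancestor.
        """
        out = {}
        for gene_id, node in self.truth_nodes[ancestor].items():
            desc = self.true_descendants(ancestor, gene_id)
            if not desc:
                continue
            ok = node.branch_survives()
            p = node.parent
            while not ok and p is not None:
                if p.branch_survives() and self.stree.at_or_above(
                        p.species, ancestor):
                    ok = True
                p = p.parent
            if ok:
                out[gene_id] = desc
        return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_dataset(stree: SpeciesTree, params: SimulationParams) -> SyntheticDataset:
    """Run one simulation; byte-identical for identical seeds."""
    for node in stree._nodes.values():
        if node.children and len(node.children) != 2:
            raise ValueError("the simulator requires a binary species tree")
    for branch in params.wgd:
        stree.node(branch)  # raises on unknown branch

    rng = np.random.default_rng(params.seed)
    uid_counter = [0]

    def new_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0]

    # root genome: single-copy families spread evenly over chromosomes
    family_roots: list[_SimNode] = []
    state: list[list[_Copy]] = [[] for _ in range(params.chromosomes)]
    for f in range(params.genes):
        node = _SimNode()
        family_roots.append(node)
        sign = 1 if rng.random() < 0.5 else -1
        state[f % params.chromosomes].append(_Copy(new_uid(), sign, node, f))

    genomes: dict[str, GenomeTable] = {}
    ancestors: dict[str, GenomeTable] = {}
    truth_nodes: dict[str, dict[str, _SimNode]] = {}
    events: list[tuple[str, str, str]] = []

    def snapshot(name: str, chroms: list[list[_Copy]], extant: bool) -> None:
        records = []
        nodes: dict[str, _SimNode] = {}
        for ci, chrom in enumerate(chroms):
            cname = f"chr{ci + 1}"
            for pos, copy in enumerate(chrom):
                gene_id = f"{name}_{copy.uid}"
                start = (pos + 1) * 1000
                records.append(GeneRecord(
                    species=name, chromosome=cname, start=start,
                    end=start + 500, strand=copy.sign, gene_id=gene_id,
                    family_id=f"fam{copy.family}"))
                nodes[gene_id] = copy.node
                if extant:
                    copy.node.gene_id = gene_id
                    copy.node.species = name
        table = GenomeTable(name, records)
        if extant:
            genomes[name] = table
        else:
            ancestors[name] = table
            truth_nodes[name] = nodes

    def visit(snode, chroms: list[list[_Copy]]) -> None:
        snapshot(snode.name, chroms, extant=snode.is_leaf)
        if snode.is_leaf:
            return
        # speciation: every live copy's pending leaf becomes a SPEC node
        for chrom in chroms:
            for copy in chrom:
                copy.node.event = SPEC
                copy.node.species = snode.name
        for child in snode.children:
            child_state = []
            for chrom in chroms:
                new_chrom = []
                for copy in chrom:
                    leaf = _SimNode()
                    copy.node.add_child(leaf)
                    new_chrom.append(_Copy(new_uid(), copy.sign, leaf, copy.family))
                child_state.append(new_chrom)
            _apply_branch_events(child_state, child.name, params, rng, events,
                                 family_roots, new_uid)
            visit(child, child_state)

    visit(stree.root, state)

    forest = _finalize_forest(family_roots)
    event_frame = pd.DataFrame(events, columns=["branch", "event", "detail"])
    return SyntheticDataset(stree=stree, params=params, genomes=genomes,
                            ancestors=ancestors, forest=forest,
                            events=event_frame, truth_nodes=truth_nodes)


def _apply_branch_events(state, branch, params, rng, events, family_roots, new_uid):
    def log(event, **detail):
        events.append((branch, event, json.dumps(detail, sort_keys=True)))

    def skip(event, reason):
        logger.info("branch %s: %s skipped (%s)", branch, event, reason)
        log(event + "_skipped", reason=reason)

    def n_genes():
        return sum(len(c) for c in state)

    def drop_empty():
        state[:] = [c for c in state if c]

    # --- whole-genome duplication -----------------------------------------
    retention = params.wgd.get(branch)
    if retention is not None:
        new_chroms = []
        kept = 0
        for chrom in state:
            dup = []
            for copy in chrom:
                if rng.random() < retention:
                    dnode = copy.node
                    dnode.event = DUP
                    dnode.species = branch
                    left = dnode.add_child(_SimNode())
                    right = dnode.add_child(_SimNode())
                    copy.node = left
                    dup.append(_Copy(new_uid(), copy.sign, right, copy.family))
                    kept += 1
            if dup:
                new_chroms.append(dup)
        state.extend(new_chroms)
        log("wgd", retention=retention, retained=kept)

    # --- structural rearrangements ----------------------------------------
    for _ in range(params.inversions):
        eligible = [i for i, c in enumerate(state) if len(c) >= 2]
        if not eligible:
            skip("inversion", "no chromosome with >= 2 genes")
            continue
        ci = eligible[rng.integers(len(eligible))]
        chrom = state[ci]
        length = int(rng.integers(2, len(chrom) + 1))
        start = int(rng.integers(0, len(chrom) - length + 1))
        segment = chrom[start:start + length][::-1]
        for copy in segment:
            copy.sign = -copy.sign
        chrom[start:start + length] = segment
        log("inversion", chromosome=ci, start=start, length=length)

    for _ in range(params.translocations):
        if len(state) < 2:
            skip("translocation", "fewer than two chromosomes")
            continue
        i, j = map(int, rng.choice(len(state), size=2, replace=False))
        c1, c2 = state[i], state[j]
        if len(c1) < 1 or len(c2) < 1:
            skip("translocation", "empty chromosome")
            continue
        cut1 = int(rng.integers(1, len(c1) + 1))
        cut2 = int(rng.integers(1, len(c2) + 1))
        state[i], state[j] = c1[:cut1] + c2[cut2:], c2[:cut2] + c1[cut1:]
        drop_empty()
        log("translocation", chromosomes=[i, j], cuts=[cut1, cut2])

    for _ in range(params.fusions):
        if len(state) < 2:
            skip("fusion", "fewer than two chromosomes")
            continue
        i, j = map(int, rng.choice(len(state), size=2, replace=False))
        flip = bool(rng.random() < 0.5)
        second = state[j]
        if flip:
            second = second[::-1]
            for copy in second:
                copy.sign = -copy.sign
        state[i] = state[i] + second
        del state[j]
        log("fusion", chromosomes=[i, j], flipped=flip)

    for _ in range(params.fissions):
        eligible = [i for i, c in enumerate(state) if len(c) >= 2]
        if not eligible:
            skip("fission", "no chromosome with >= 2 genes")
            continue
        ci = eligible[rng.integers(len(eligible))]
        chrom = state[ci]
        cut = int(rng.integers(1, len(chrom)))
        state[ci] = chrom[:cut]
        state.append(chrom[cut:])
        log("fission", chromosome=ci, cut=cut)

    # --- tandem duplications and gains -------------------------------------
    if params.tandem > 0 and n_genes() > 0:
        count = int(rng.binomial(n_genes(), params.tandem))
        for _ in range(count):
            ci = int(rng.integers(len(state)))
            if not state[ci]:
                continue
            pos = int(rng.integers(len(state[ci])))
            copy = state[ci][pos]
            dnode = copy.node
            dnode.event = DUP
            dnode.species = branch
            left = dnode.add_child(_SimNode())
            right = dnode.add_child(_SimNode())
            copy.node = left
            state[ci].insert(pos + 1,
                             _Copy(new_uid(), copy.sign, right, copy.family))
            log("tandem_duplication", chromosome=ci, position=pos)

    if params.gain > 0 and n_genes() > 0:
        count = int(rng.binomial(n_genes(), params.gain))
        for _ in range(count):
            root = _SimNode()
            family = len(family_roots)
            family_roots.append(root)
            ci = int(rng.integers(len(state)))
            pos = int(rng.integers(len(state[ci]) + 1))
            sign = 1 if rng.random() < 0.5 else -1
            state[ci].insert(pos, _Copy(new_uid(), sign, root, family))
            log("gain", chromosome=ci, position=pos, family=family)

    # --- losses last --------------------------------------------------------
    if params.loss > 0 and n_genes() > 0:
        count = int(rng.binomial(n_genes(), params.loss))
        count = min(count, n_genes() - 1)  # never erase the whole genome
        for _ in range(count):
            ci = int(rng.integers(len(state)))
            if not state[ci]:
                continue
            pos = int(rng.integers(len(state[ci])))
            copy = state[ci].pop(pos)
            copy.node.alive = False
            log("loss", chromosome=ci, position=pos, family=copy.family)
        drop_empty()


def _finalize_forest(family_roots: list[_SimNode]) -> GeneForest:
    """Prune dead lineages, suppress unifurcations and convert to
    reconciled gene trees; fully extinct families disappear."""

    def prune(node: _SimNode) -> GeneTreeNode | None:
        if not node.children:
            if not node.alive or node.gene_id is None:
                return None
            return GeneTreeNode(gene_id=node.gene_id, species=node.species)
        kept = [prune(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = GeneTreeNode(species=node.species, event=node.event)
        for child in kept:
            out.add_child(child)
        return out

    trees = []
    for root in family_roots:
        pruned = prune(root)
        if pruned is not None:
            trees.append(ReconciledGeneTree(pruned))
    return GeneForest(trees)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionMetrics:
    """Adjacency-level agreement between a reconstruction and the truth."""

    precision: float
    recall: float
    f1: float
    precision_unoriented: float
    recall_unoriented: float
    n_true_adjacencies: int
    n_reconstructed_adjacencies: int
    block_count: int
    genes_placed: int
    true_content_size: int
    oriented_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def match_content(dataset: SyntheticDataset, ancestor: str,
                  content: list[AncestralGene]) -> dict[str, str]:
    """Map reconstructed ancestral gene ids to true ancestral gene ids.

    Matching is by extant descendant sets, which coincide exactly when the
    reconciled forest is consistent with the logged events; a best-overlap
    fallback covers partial disagreements.  Unmatched genes are absent
    from the map.
    """
    truth = dataset.observable_truth(ancestor)
    by_desc = {desc: gid for gid, desc in truth.items()}
    taken: set[str] = set()
    out: dict[str, str] = {}
    unresolved = []
    for gene in content:
        hit = by_desc.get(gene.all_descendants())
        if hit is not None and hit not in taken:
            out[gene.id] = hit
            taken.add(hit)
        else:
            unresolved.append(gene)
    for gene in unresolved:
        desc = gene.all_descendants()
        best, best_overlap = None, 0
        for gid, tdesc in truth.items():
            if gid in taken:
                continue
            overlap = len(desc & tdesc)
            if overlap > best_overlap:
                best, best_overlap = gid, overlap
        if best is not None:
            out[gene.id] = best
            taken.add(best)
    return out


def _truth_adjacencies(truth_table: GenomeTable, observable: set[str]):
    oriented = set()
    unoriented = set()
    for chrom in truth_table.chromosomes.values():
        row = [(r.gene_id, r.strand) for r in chrom if r.gene_id in observable]
        for (x, sx), (y, sy) in zip(row, row[1:]):
            if x == y:
                continue
            oriented.add(canonical_adjacency(x, sx, y, sy))
            unoriented.add(frozenset((x, y)))
    return oriented, unoriented


def evaluate_reconstruction(blocks: BlockTable, truth: GenomeTable,
                            mapping: dict[str, str]) -> ReconstructionMetrics:
    """Score a reconstruction against the true ancestral gene order.

    Adjacencies are compared as canonical oriented pairs over the true gene
    ids (via ``mapping``); the truth is restricted to genes any observer
    could reconstruct (those in the mapping's image).  With zero
    reconstructed adjacencies precision is reported as 1.0.
    """
    if truth.species != blocks.ancestor:
        raise ValueError(
            f"blocks are for {blocks.ancestor!r} but truth is {truth.species!r}")
    observable = set(mapping.values())
    true_oriented, true_unoriented = _truth_adjacencies(truth, observable)

    rec_oriented = set()
    rec_unoriented = set()
    positions = 0
    oriented_positions = 0
    for block in blocks.blocks:
        mapped = [(mapping[g], s) for g, s in block if g in mapping]
        positions += len(block)
        oriented_positions += sum(1 for _g, s in block if s != 0)
        for (x, sx), (y, sy) in zip(mapped, mapped[1:]):
            if x == y:
                continue
            rec_oriented.add(canonical_adjacency(x, sx, y, sy))
            rec_unoriented.add(frozenset((x, y)))

    tp = len(rec_oriented & true_oriented)
    precision = tp / len(rec_oriented) if rec_oriented else 1.0
    recall = tp / len(true_oriented) if true_oriented else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    tpu = len(rec_unoriented & true_unoriented)
    precision_u = tpu / len(rec_unoriented) if rec_unoriented else 1.0
    recall_u = tpu / len(true_unoriented) if true_unoriented else 1.0

    return ReconstructionMetrics(
        precision=precision, recall=recall, f1=f1,
        precision_unoriented=precision_u, recall_unoriented=recall_u,
        n_true_adjacencies=len(true_oriented),
        n_reconstructed_adjacencies=len(rec_oriented),
        block_count=len(blocks.blocks),
        genes_placed=positions,
        true_content_size=len(observable),
        oriented_fraction=oriented_positions / positions if positions else 0.0,
    )
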