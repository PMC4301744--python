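"""Species trees, reconciled gene trees, and the queries built on them.

The reconstruction of an ancestral genome starts from a species tree whose
internal nodes are the named ancestors, and a forest of reconciled gene
trees in which every node carries a species assignment (the species-tree
node the gene existed in) and an event label (speciation or duplication).
This module provides:

* :class:`SpeciesTree` — a rooted species tree with named ancestors,
  clade/LCA queries and the *informative pair* computation (the extant
  species pairs whose tree path passes through a given ancestor);
* :class:`ReconciledGeneTree` — a rooted binary gene tree with per-node
  species assignments and SPEC/DUP labels;
* LCA reconciliation (:func:`reconcile`) for trees lacking labels;
* ancestral gene content inference (:func:`ancestral_content`) and the
  gene-to-ancestor mapping that powers lineage-specific filtering;
* orthology/paralogy extraction (:func:`homology_pairs`).
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field

logger = logging.getLogger("paleorder")

SPEC = "SPEC"
DUP = "DUP"


class ReconciliationError(ValueError):
    """Raised when a gene tree cannot be reconciled with the species tree."""


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class SpeciesTreeNode:
    __slots__ = ("name", "parent", "children", "depth", "_tin", "_tout")

    def __init__(self, name: str, parent: "SpeciesTreeNode | None" = None):
        self.name = name
        self.parent = parent
        self.children: list[SpeciesTreeNode] = []
        self.depth = 0
        self._tin = -1
        self._tout = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SpeciesTreeNode({self.name!r})"


class SpeciesTree:
    """Rooted species tree with unique node names; internals are ancestors."""

    def __init__(self, root: SpeciesTreeNode):
        self.root = root
        self._nodes: dict[str, SpeciesTreeNode] = {}
        self._index()

    def _index(self) -> None:
        counter = itertools.count()
        def walk(node: SpeciesTreeNode, depth: int) -> None:
            if node.name in self._nodes:
                raise ReconciliationError(f"duplicate node name {node.name!r}")
            self._nodes[node.name] = node
            node.depth = depth
            node._tin = next(counter)
            for child in node.children:
                walk(child, depth + 1)
            node._tout = next(counter)
        walk(self.root, 0)
        self._clade_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def node(self, name: str) -> SpeciesTreeNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise ReconciliationError(f"unknown species-tree node {name!r}") from None

    def is_leaf(self, name: str) -> bool:
        return self.node(name).is_leaf

    @property
    def leaves(self) -> list[str]:
        return [n.name for n in self._nodes.values() if n.is_leaf]

    @property
    def ancestors(self) -> list[str]:
        return [n.name for n in self._nodes.values() if not n.is_leaf]

    def clade_leaves(self, name: str) -> frozenset[str]:
        """Extant species names in the clade rooted at ``name``."""
        cached = self._clade_cache.get(name)
        if cached is None:
            node = self.node(name)
            out = []
            stack = [node]
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    out.append(n.name)
                else:
                    stack.extend(n.children)
            cached = self._clade_cache[name] = frozenset(out)
        return cached

    def at_or_above(self, a: str, b: str) -> bool:
        """True if node ``a`` equals ``b`` or is an ancestor of ``b``."""
        na, nb = self.node(a), self.node(b)
        return na._tin <= nb._tin and nb._tout <= na._tout

    def lca(self, a: str, b: str) -> str:
        na, nb = self.node(a), self.node(b)
        while na.depth > nb.depth:
            na = na.parent
        while nb.depth > na.depth:
            nb = nb.parent
        while na is not nb:
            na, nb = na.parent, nb.parent
        return na.name

    def lca_many(self, names) -> str:
        it = iter(names)
        acc = next(it)
        for name in it:
            acc = self.lca(acc, name)
        return acc

    # -- informative pairs --------------------------------------------------

    def informative_pairs(self, ancestor: str) -> set[tuple[str, str]]:
        """Extant species pairs whose tree path passes through ``ancestor``.

        A pair {S1, S2} is informative for an ancestor A when A lies on the
        path between the two leaves: either exactly one of the species is in
        A's clade, or both are and their LCA is A itself.  Only such pairs
        contribute gene-adjacency evidence for A.
        """
        node = self.node(ancestor)
        if node.is_leaf:
            raise ReconciliationError(f"{ancestor!r} is an extant species, not an ancestor")
        inside = self.clade_leaves(ancestor)
        outside = [s for s in self.leaves if s not in inside]
        pairs: set[tuple[str, str]] = set()
        for s1 in inside:
            for s2 in outside:
                pairs.add(tuple(sorted((s1, s2))))
        for s1, s2 in itertools.combinations(sorted(inside), 2):
            if self.lca(s1, s2) == ancestor:
                pairs.add((s1, s2))
        return pairs


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


class GeneTreeNode:
    __slots__ = ("children", "parent", "gene_id", "species", "event", "index")

    def __init__(self, gene_id: str | None = None, species: str | None = None,
                 event: str | None = None):
        self.children: list[GeneTreeNode] = []
        self.parent: GeneTreeNode | None = None
        self.gene_id = gene_id
        self.species = species  # sigma: species-tree node name
        self.event = event      # SPEC | DUP | None (leaves stay None)
        self.index = -1         # preorder index, assigned by the tree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "GeneTreeNode") -> "GeneTreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        tag = self.gene_id if self.is_leaf else self.event
        return f"GeneTreeNode({tag!r}@{self.species!r})"


class ReconciledGeneTree:
    """Rooted binary gene tree; one per gene family."""

    def __init__(self, root: GeneTreeNode):
        self.root = root
        self.reindex()

    def reindex(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.index = i

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self):
        return (n for n in self.preorder() if n.is_leaf)

    def validate_binary(self) -> None:
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise ReconciliationError(
                    f"gene-tree node with {len(node.children)} children; trees must be binary")


class GeneForest:
    """A forest of reconciled gene trees with a gene-id lookup index."""

    def __init__(self, trees: list[ReconciledGeneTree]):
        self.trees = trees
        self._leaf_index: dict[str, tuple[int, GeneTreeNode]] | None = None
        self._content_cache: dict[str, "AncestorContent"] = {}

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def leaf(self, gene_id: str) -> tuple[int, GeneTreeNode]:
        if self._leaf_index is None:
            self._leaf_index = {}
            for i, tree in enumerate(self.trees):
                for node in tree.leaves():
                    if node.gene_id in self._leaf_index:
                        raise ReconciliationError(
                            f"gene id {node.gene_id!r} appears in two trees")
                    self._leaf_index[node.gene_id] = (i, node)
        try:
            return self._leaf_index[gene_id]
        except KeyError:
            raise ReconciliationError(f"unknown gene {gene_id!r}") from None

    def invalidate_caches(self) -> None:
        self._leaf_index = None
        self._content_cache = {}


# ---------------------------------------------------------------------------
# reconciliation
# ---------------------------------------------------------------------------


def reconcile(tree: ReconciledGeneTree, stree: SpeciesTree) -> ReconciledGeneTree:
    """Fill species assignments and SPEC/DUP labels by LCA reconciliation.

    The species assignment of a leaf is its species; the assignment of an
    internal node is the species-tree LCA of its children's assignments.  A
    node is a duplication when it maps to the same species-tree node as one
    of its children, otherwise a speciation.  Pre-existing S/D annotations
    (e.g. from a TreeBest-style pipeline) take precedence over the inferred
    values; disagreements on the event label are logged.  Idempotent.
    """
    tree.validate_binary()
    for node in _postorder(tree.root):
        if node.is_leaf:
            if node.species is None:
                raise ReconciliationError(f"leaf {node.gene_id!r} lacks a species")
            if node.species not in stree:
                raise ReconciliationError(
                    f"leaf {node.gene_id!r} assigned to unknown species {node.species!r}")
            continue
        child_sigma = [c.species for c in node.children]
        inferred_sigma = stree.lca_many(child_sigma)
        if node.species is None:
            node.species = inferred_sigma
        elif node.species not in stree:
            raise ReconciliationError(f"unknown species annotation {node.species!r}")
        inferred_event = DUP if any(
            c.species == node.species for c in node.children) else SPEC
        if node.event is None:
            node.event = inferred_event
        elif node.event != inferred_event:
            logger.debug(
                "event annotation %s at node mapped to %s disagrees with inferred %s; "
                "keeping annotation", node.event, node.species, inferred_event)
    return tree


def reconcile_forest(forest: GeneForest, stree: SpeciesTree) -> GeneForest:
    for tree in forest:
        reconcile(tree, stree)
    forest.invalidate_caches()
    return forest


def _postorder(root: GeneTreeNode):
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            yield node
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


# ---------------------------------------------------------------------------
# ancestral gene content
# ---------------------------------------------------------------------------


@dataclass(eq=False)  # identity semantics: each inferred gene is unique
class AncestralGene:
    """A gene inferred to exist in an ancestral genome.

    ``id`` is deterministic ("<tree index>:<node preorder index>"); ``node``
    is the gene-tree node that represents the gene at the ancestor;
    ``descendants`` maps extant species (inside the ancestor's clade) to the
    extant gene ids descending from this ancestral gene.
    """

    id: str
    ancestor: str
    tree_index: int
    node: GeneTreeNode
    descendants: dict[str, list[str]] = field(default_factory=dict)

    def all_descendants(self) -> frozenset[str]:
        return frozenset(g for genes in self.descendants.values() for g in genes)


class AncestorContent:
    """Inferred gene content of one ancestor, with lookup structures."""

    def __init__(self, ancestor: str):
        self.ancestor = ancestor
        self.genes: list[AncestralGene] = []
        self.by_id: dict[str, AncestralGene] = {}
        self.leaf_image: dict[str, AncestralGene] = {}   # in-clade extant gene -> image
        self._by_tree: dict[int, list[AncestralGene]] = defaultdict(list)

    def add(self, gene: AncestralGene) -> None:
        self.genes.append(gene)
        self.by_id[gene.id] = gene
        self._by_tree[gene.tree_index].append(gene)
        for ids in gene.descendants.values():
            for g in ids:
                self.leaf_image[g] = gene

    def genes_in_tree(self, tree_index: int) -> list[AncestralGene]:
        return self._by_tree.get(tree_index, [])


def _image_node(leaf: GeneTreeNode, stree: SpeciesTree, ancestor: str) -> GeneTreeNode | None:
    """Representative node of an in-clade leaf's gene at ``ancestor``.

    Walk leaf-to-root past every node whose species assignment is strictly
    below the ancestor (events postdating the ancestor collapse).  At the
    first node at-or-above the ancestor: a speciation mapped exactly to the
    ancestor *is* the ancestral gene; any other stopping node (a duplication
    at the ancestor, or any node strictly above it) predates the ancestor,
    so the copy we arrived through — the previous node on the walk — is the
    ancestral gene.  Returns None when the family postdates the ancestor
    (the gene is lineage-specific with respect to it).
    """
    prev = leaf
    node = leaf.parent
    while node is not None and not stree.at_or_above(node.species, ancestor):
        prev = node
        node = node.parent
    if node is None:
        return None
    if node.species == ancestor and node.event == SPEC:
        return node
    return prev


def ancestral_content(forest: GeneForest, stree: SpeciesTree,
                      ancestor: str) -> list[AncestralGene]:
    """Infer the gene content of ``ancestor`` from the reconciled forest.

    Each ancestral gene is an equivalence class of in-clade extant genes
    under the mapping of :func:`_image_node`; a family whose root postdates
    the ancestor contributes nothing.  Results are cached on the forest.
    """
    return _content(forest, stree, ancestor).genes


def _content(forest: GeneForest, stree: SpeciesTree, ancestor: str) -> AncestorContent:
    cached = forest._content_cache.get(ancestor)
    if cached is not None:
        return cached
    if ancestor not in stree:
        raise ReconciliationError(f"unknown ancestor {ancestor!r}")
    if stree.is_leaf(ancestor):
        raise ReconciliationError(
            f"{ancestor!r} is extant; its gene content is its gene list")
    clade = stree.clade_leaves(ancestor)
    content = AncestorContent(ancestor)
    for tree_index, tree in enumerate(forest):
        groups: dict[int, tuple[GeneTreeNode, dict[str, list[str]]]] = {}
        for leaf in tree.leaves():
            if leaf.species not in clade:
                continue
            image = _image_node(leaf, stree, ancestor)
            if image is None:
                continue
            entry = groups.get(image.index)
            if entry is None:
                entry = groups[image.index] = (image, defaultdict(list))
            entry[1][leaf.species].append(leaf.gene_id)
        for index in sorted(groups):
            node, desc = groups[index]
            content.add(AncestralGene(
                id=f"{tree_index}:{index}",
                ancestor=ancestor,
                tree_index=tree_index,
                node=node,
                descendants={sp: sorted(ids) for sp, ids in sorted(desc.items())},
            ))
    forest._content_cache[ancestor] = content
    return content


def map_gene_to_ancestor(forest: GeneForest, stree: SpeciesTree,
                         gene_id: str, ancestor: str) -> set[AncestralGene]:
    """Ancestral genes of ``ancestor`` homologous to one extant gene.

    For a gene of a species inside the ancestor's clade the result is the
    unique content image (empty when the family postdates the ancestor).
    For an outgroup gene the result is every content gene of the ancestor
    found in the gene subtree rooted at the first node at-or-above the
    ancestor on the leaf's root path — possibly several, e.g. after a
    whole-genome duplication on the ancestor's side.
    """
    content = _content(forest, stree, ancestor)
    tree_index, leaf = forest.leaf(gene_id)
    if leaf.species in stree.clade_leaves(ancestor):
        image = content.leaf_image.get(gene_id)
        return {image} if image is not None else set()
    node = leaf.parent
    while node is not None and not stree.at_or_above(node.species, ancestor):
        node = node.parent
    if node is None:
        return set()
    span = _subtree_span(forest.trees[tree_index], node)
    return {g for g in content.genes_in_tree(tree_index)
            if span[0] <= g.node.index <= span[1]}


def _subtree_span(tree: ReconciledGeneTree, node: GeneTreeNode) -> tuple[int, int]:
    # preorder indices of a subtree form a contiguous interval
    lo = node.index
    hi = lo
    stack = [node]
    while stack:
        n = stack.pop()
        if n.index > hi:
            hi = n.index
        stack.extend(n.children)
    return lo, hi


# ---------------------------------------------------------------------------
# homology extraction
# ---------------------------------------------------------------------------


def homology_pairs(forest: GeneForest, stree: SpeciesTree, g1: str, g2: str,
                   mode: str = "all") -> list[tuple[str, str, str]]:
    """Homologous element pairs between two genomes (extant or ancestral).

    For two extant genomes, leaf pairs are classified by the event at their
    gene-tree LCA: speciation gives orthologs, duplication gives paralogs
    (``g1 == g2`` with mode ``paralogs`` lists within-genome paralogs).  An
    ancestor paired with an extant genome yields (ancestral gene, extant
    gene) pairs of type ``ancestral`` via the gene-to-ancestor mapping; two
    ancestors are comparable only when one is at-or-above the other.
    """
    if mode not in ("orthologs", "paralogs", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    e1 = stree.is_leaf(g1)
    e2 = stree.is_leaf(g2)
    if e1 and e2:
        return _extant_pairs(forest, g1, g2, mode)
    if mode == "paralogs":
        raise ReconciliationError("paralog mode requires two extant genomes")
    if e1 != e2:
        anc, ext = (g2, g1) if e1 else (g1, g2)
        pairs = _ancestor_extant_pairs(forest, stree, anc, ext)
        if e1:  # keep argument order: element1 from g1
            pairs = [(b, a, t) for a, b, t in pairs]
        return sorted(pairs)
    return sorted(_ancestor_ancestor_pairs(forest, stree, g1, g2))


def _extant_pairs(forest: GeneForest, s1: str, s2: str, mode: str):
    out: list[tuple[str, str, str]] = []
    same = s1 == s2
    for tree in forest:
        for node in _postorder(tree.root):
            if node.is_leaf:
                continue
            kind = "paralog" if node.event == DUP else "ortholog"
            if mode == "orthologs" and kind != "ortholog":
                continue
            if mode == "paralogs" and kind != "paralog":
                continue
            left, right = node.children
            l1 = [l.gene_id for l in _leaves_below(left) if l.species == s1]
            r2 = [l.gene_id for l in _leaves_below(right) if l.species == s2]
            for a in l1:
                for b in r2:
                    pair = (b, a) if same and b < a else (a, b)
                    out.append((*pair, kind))
            if not same:
                l2 = [l.gene_id for l in _leaves_below(left) if l.species == s2]
                r1 = [l.gene_id for l in _leaves_below(right) if l.species == s1]
                for a in r1:
                    for b in l2:
                        out.append((a, b, kind))
    return sorted(out)


def _leaves_below(node: GeneTreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _ancestor_extant_pairs(forest: GeneForest, stree: SpeciesTree,
                           ancestor: str, species: str):
    content = _content(forest, stree, ancestor)
    out = []
    if species in stree.clade_leaves(ancestor):
        for gene in content.genes:
            for ext in gene.descendants.get(species, ()):
                out.append((gene.id, ext, "ancestral"))
    else:
        seen_trees = {g.tree_index for g in content.genes}
        for tree_index, tree in enumerate(forest):
            if tree_index not in seen_trees:
                continue
            for leaf in tree.leaves():
                if leaf.species != species:
                    continue
                for gene in map_gene_to_ancestor(forest, stree, leaf.gene_id, ancestor):
                    out.append((gene.id, leaf.gene_id, "ancestral"))
    return out


def _ancestor_ancestor_pairs(forest: GeneForest, stree: SpeciesTree,
                             a1: str, a2: str):
    if a1 == a2:
        return [(g.id, g.id, "ancestral") for g in _content(forest, stree, a1).genes]
    if stree.at_or_above(a1, a2):
        high, low, swap = a1, a2, False
    elif stree.at_or_above(a2, a1):
        high, low, swap = a2, a1, True
    else:
        raise ReconciliationError(
            f"ancestors {a1!r} and {a2!r} are not in an ancestor-descendant "
            "relation; their homology is undefined")
    high_content = _content(forest, stree, high)
    out = []
    for gene in _content(forest, stree, low).genes:
        # any extant descendant of the lower gene identifies the higher image
        witness = next(iter(next(iter(gene.descendants.values()))))
        image = high_content.leaf_image.get(witness)
        if image is None:
            continue
        pair = (image.id, gene.id) if not swap else (gene.id, image.id)
        out.append((pair[0], pair[1], "ancestral"))
    return out
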