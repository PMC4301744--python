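"""Reconciliation, ancestral content, gene-to-ancestor mapping, informative
pairs and homology extraction, each checked against an independent oracle."""

import itertools
import json
import random

import pytest

from paleorder.formats_io import parse_gene_forest, parse_species_tree
from paleorder.simulator import SimulationParams, simulate_dataset
from paleorder.trees_reconciliation import (
    DUP,
    SPEC,
    ReconciliationError,
    ancestral_content,
    homology_pairs,
    map_gene_to_ancestor,
    reconcile,
    reconcile_forest,
)


def forest_of(text, stree, reconciled=True):
    forest = parse_gene_forest(text, stree)
    if reconciled:
        reconcile_forest(forest, stree)
    return forest


# ---------------------------------------------------------------------------
# reconcile
# ---------------------------------------------------------------------------


def test_reconcile_speciation(stree3):
    forest = parse_gene_forest("(a1[&&NHX:S=s1],b1[&&NHX:S=s2]);", stree3)
    tree = reconcile(forest.trees[0], stree3)
    assert tree.root.species == "anc1" and tree.root.event == SPEC


def test_reconcile_duplication(stree3):
    forest = parse_gene_forest("(a1[&&NHX:S=s1],a2[&&NHX:S=s1]);", stree3)
    tree = reconcile(forest.trees[0], stree3)
    assert tree.root.species == "s1" and tree.root.event == DUP


def test_reconcile_idempotent(stree3):
    forest = parse_gene_forest(
        "((a1[&&NHX:S=s1],b1[&&NHX:S=s2]),c1[&&NHX:S=s3]);", stree3)
    tree = reconcile(forest.trees[0], stree3)
    labels = [(n.species, n.event) for n in tree.preorder()]
    reconcile(tree, stree3)
    assert labels == [(n.species, n.event) for n in tree.preorder()]


def test_reconcile_unknown_species(stree3):
    forest = parse_gene_forest("(a1[&&NHX:S=s1],b1[&&NHX:S=s2]);", None)
    forest.trees[0].root.children[1].species = "mystery"
    with pytest.raises(ReconciliationError):
        reconcile(forest.trees[0], stree3)


def test_reconcile_matches_simulated_events(stree5):
    """LCA reconciliation of a loss-free simulated forest recovers the true
    species assignments and event labels the simulator logged."""
    params = SimulationParams(genes=40, chromosomes=2, inversions=1,
                              tandem=0.05, wgd={"anc2": 0.6}, seed=3)
    dataset = simulate_dataset(stree5, params)
    n_dup_events = int((dataset.events["event"] == "tandem_duplication").sum()
                       + sum(json.loads(d)["retained"]
                             for d in dataset.events.query("event == 'wgd'")["detail"]))
    truth, n_dups = [], 0
    for tree in dataset.forest:
        truth.append([(n.species, n.event) for n in tree.preorder()])
        n_dups += sum(1 for n in tree.preorder() if n.event == DUP)
    assert n_dups == n_dup_events  # no losses: every logged duplication survives
    # strip labels and re-infer
    for tree in dataset.forest:
        for node in tree.preorder():
            if not node.is_leaf:
                node.species = None
                node.event = None
    reconcile_forest(dataset.forest, stree5)
    inferred = [[(n.species, n.event) for n in t.preorder()] for t in dataset.forest]
    assert inferred == truth


# ---------------------------------------------------------------------------
# ancestral content and gene mapping
# ---------------------------------------------------------------------------


def test_content_collapses_duplication_below_ancestor(stree3):
    forest = forest_of(
        "(a1[&&NHX:S=s1],(b1[&&NHX:S=s2],b2[&&NHX:S=s2]));", stree3)
    content = ancestral_content(forest, stree3, "anc1")
    assert len(content) == 1
    assert content[0].descendants == {"s1": ["a1"], "s2": ["b1", "b2"]}


def test_content_skips_postdating_family(stree3):
    forest = forest_of("(b1[&&NHX:S=s2],b2[&&NHX:S=s2]);", stree3)
    assert ancestral_content(forest, stree3, "anc1") == []


def test_duplication_at_ancestor_gives_two_genes(stree3):
    """A duplication mapped exactly to the ancestor is resolved as having
    happened above it: both copies are part of the ancestor's content."""
    forest = forest_of(
        "((a1[&&NHX:S=s1],b1[&&NHX:S=s2]),(a2[&&NHX:S=s1],b2[&&NHX:S=s2]))"
        "[&&NHX:D=Y];", stree3)
    assert forest.trees[0].root.event == DUP
    assert forest.trees[0].root.species == "anc1"
    content = ancestral_content(forest, stree3, "anc1")
    assert len(content) == 2
    assert sorted((g.all_descendants() for g in content), key=sorted) == [
        frozenset({"a1", "b1"}), frozenset({"a2", "b2"})]


def test_content_of_extant_species_is_error(stree3):
    forest = forest_of("(a1[&&NHX:S=s1],b1[&&NHX:S=s2]);", stree3)
    with pytest.raises(ReconciliationError):
        ancestral_content(forest, stree3, "s1")


def test_map_in_clade_gene(stree3):
    forest = forest_of("(a1[&&NHX:S=s1],b1[&&NHX:S=s2]);", stree3)
    images = map_gene_to_ancestor(forest, stree3, "a1", "anc1")
    assert len(images) == 1
    assert next(iter(images)).all_descendants() == frozenset({"a1", "b1"})


def test_map_lineage_specific_gene_is_empty(stree3):
    forest = forest_of("(b1[&&NHX:S=s2],b2[&&NHX:S=s2]);", stree3)
    assert map_gene_to_ancestor(forest, stree3, "b1", "anc1") == set()


def test_map_outgroup_gene_after_duplication(stree3):
    """An outgroup gene maps to *all* ancestral copies created by a
    post-split duplication — here 2, as after a WGD."""
    forest = forest_of(
        "(((a1[&&NHX:S=s1],b1[&&NHX:S=s2]),(a2[&&NHX:S=s1],b2[&&NHX:S=s2]))"
        "[&&NHX:D=Y],c1[&&NHX:S=s3]);", stree3)
    images = map_gene_to_ancestor(forest, stree3, "c1", "anc1")
    assert len(images) == 2
    assert {g.all_descendants() for g in images} == {
        frozenset({"a1", "b1"}), frozenset({"a2", "b2"})}


def test_images_partition_in_clade_leaves(stree5):
    params = SimulationParams(genes=30, chromosomes=2, tandem=0.05,
                              loss=0.05, gain=0.05, wgd={"anc1": 0.5}, seed=5)
    dataset = simulate_dataset(stree5, params)
    for ancestor in ("root", "anc1", "anc2", "anc3"):
        content = ancestral_content(dataset.forest, stree5, ancestor)
        clade = stree5.clade_leaves(ancestor)
        covered = [g for c in content for g in c.all_descendants()]
        assert len(covered) == len(set(covered))  # disjoint classes
        for tree in dataset.forest:
            for leaf in tree.leaves():
                if leaf.species not in clade:
                    continue
                images = map_gene_to_ancestor(dataset.forest, stree5,
                                              leaf.gene_id, ancestor)
                assert len(images) <= 1
                assert (leaf.gene_id in set(covered)) == bool(images)


def test_content_matches_simulated_truth(stree5):
    params = SimulationParams(genes=40, chromosomes=3, inversions=2,
                              tandem=0.03, loss=0.03, gain=0.03,
                              wgd={"anc3": 0.5}, seed=8)
    dataset = simulate_dataset(stree5, params)
    for ancestor in ("root", "anc1", "anc2", "anc3"):
        content = ancestral_content(dataset.forest, stree5, ancestor)
        truth = dataset.observable_truth(ancestor)
        assert (sorted((g.all_descendants() for g in content), key=sorted)
                == sorted(truth.values(), key=sorted))


# ---------------------------------------------------------------------------
# informative pairs
# ---------------------------------------------------------------------------


def test_informative_pairs_examples(stree3):
    assert stree3.informative_pairs("anc1") == {
        ("s1", "s2"), ("s1", "s3"), ("s2", "s3")}
    assert stree3.informative_pairs("root") == {("s1", "s3"), ("s2", "s3")}


def _random_species_tree(rng, n_leaves):
    names = [f"L{i}" for i in range(n_leaves)]
    counter = itertools.count()

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = rng.randint(1, len(leaves) - 1)
        left, right = leaves[:k], leaves[k:]
        return f"({build(left)},{build(right)})N{next(counter)}"

    rng.shuffle(names)
    return parse_species_tree(build(names) + ";")


def _path_nodes(stree, a, b):
    """Node names on the tree path between two leaves (oracle)."""
    up_a, node = [], stree.node(a)
    while node is not None:
        up_a.append(node.name)
        node = node.parent
    up_b, node = [], stree.node(b)
    while node is not None:
        up_b.append(node.name)
        node = node.parent
    lca = next(n for n in up_a if n in set(up_b))
    path = up_a[:up_a.index(lca) + 1] + up_b[:up_b.index(lca)]
    return set(path)


def test_informative_pairs_match_path_walk_oracle():
    rng = random.Random(17)
    for _ in range(25):
        stree = _random_species_tree(rng, rng.randint(3, 9))
        leaves = sorted(stree.leaves)
        for ancestor in stree.ancestors:
            expected = {tuple(sorted((a, b)))
                        for a, b in itertools.combinations(leaves, 2)
                        if ancestor in _path_nodes(stree, a, b)}
            got = stree.informative_pairs(ancestor)
            assert got == expected
            assert got, "every ancestor of a >=2 leaf tree has informative pairs"


# ---------------------------------------------------------------------------
# homology pairs
# ---------------------------------------------------------------------------


def test_orthologs_simple(stree3):
    forest = forest_of("(a1[&&NHX:S=s1],b1[&&NHX:S=s2]);", stree3)
    assert homology_pairs(forest, stree3, "s1", "s2", "orthologs") == [
        ("a1", "b1", "ortholog")]


def test_paralogs_within_genome(stree3):
    forest = forest_of("(a1[&&NHX:S=s1],a2[&&NHX:S=s1]);", stree3)
    assert homology_pairs(forest, stree3, "s1", "s1", "paralogs") == [
        ("a1", "a2", "paralog")]


def _lca_oracle(forest, s1, s2, mode):
    """Quadratic all-leaf-pairs LCA-event classification."""
    out = []
    for tree in forest:
        leaves = list(tree.leaves())
        for l1 in leaves:
            for l2 in leaves:
                if l1 is l2 or l1.species != s1 or l2.species != s2:
                    continue
                if s1 == s2 and l1.gene_id > l2.gene_id:
                    continue
                anc1, node = set(), l1
                while node is not None:
                    anc1.add(id(node))
                    node = node.parent
                node = l2
                while id(node) not in anc1:
                    node = node.parent
                kind = "paralog" if node.event == DUP else "ortholog"
                if mode == "orthologs" and kind != "ortholog":
                    continue
                if mode == "paralogs" and kind != "paralog":
                    continue
                pair = tuple(sorted((l1.gene_id, l2.gene_id))) if s1 == s2 \
                    else (l1.gene_id, l2.gene_id)
                out.append((pair[0], pair[1], kind))
    return sorted(set(out))


@pytest.mark.parametrize("mode", ["orthologs", "paralogs", "all"])
def test_homology_matches_quadratic_oracle(stree5, mode):
    params = SimulationParams(genes=25, chromosomes=2, tandem=0.08,
                              loss=0.05, wgd={"anc2": 0.5}, seed=23)
    dataset = simulate_dataset(stree5, params)
    for s1, s2 in [("s1", "s3"), ("s3", "s4"), ("s3", "s3")]:
        if mode == "orthologs" and s1 == s2:
            continue
        got = sorted(set(homology_pairs(dataset.forest, stree5, s1, s2, mode)))
        assert got == _lca_oracle(dataset.forest, s1, s2, mode)


def test_ancestor_extant_homology(stree3):
    forest = forest_of(
        "(a1[&&NHX:S=s1],(b1[&&NHX:S=s2],b2[&&NHX:S=s2]));", stree3)
    pairs = homology_pairs(forest, stree3, "anc1", "s2")
    gene_id = ancestral_content(forest, stree3, "anc1")[0].id
    assert pairs == [(gene_id, "b1", "ancestral"), (gene_id, "b2", "ancestral")]
    flipped = homology_pairs(forest, stree3, "s2", "anc1")
    assert flipped == [("b1", gene_id, "ancestral"), ("b2", gene_id, "ancestral")]


def test_incomparable_ancestors_error(stree5):
    forest = forest_of("(a1[&&NHX:S=s1],c1[&&NHX:S=s3]);", stree5)
    with pytest.raises(ReconciliationError):
        homology_pairs(forest, stree5, "anc1", "anc2")
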