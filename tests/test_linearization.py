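"""Greedy path cover: worked examples, invariants, and an independent
step-by-step replay oracle; two-round reconstruction behaviour."""

import random

import pytest

from paleorder.adjacencies import AdjacencyGraph, canonical_adjacency
from paleorder.linearization import (
    contig_adjacency_graph,
    greedy_path_cover,
    reconstruct_ancestor,
)
from paleorder.simulator import SimulationParams, simulate_dataset
from paleorder.trees_reconciliation import ancestral_content

from conftest import make_genome


def graph_of(nodes, edges):
    weights = {}
    for x, sx, y, sy, w in edges:
        weights[canonical_adjacency(x, sx, y, sy)] = w
    return AdjacencyGraph(nodes=set(nodes), weights=weights)


def canonical_path(genes):
    rc = [(g, -s) for g, s in reversed(genes)]
    return tuple(min(genes, rc))


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


def test_chain_with_cycle_edge_rejected():
    graph = graph_of("xyz", [("x", 1, "y", 1, 3), ("y", 1, "z", 1, 2),
                             ("z", 1, "x", 1, 1)])
    contigs = greedy_path_cover(graph)
    assert len(contigs) == 1
    assert canonical_path(contigs[0].genes) == canonical_path(
        [("x", 1), ("y", 1), ("z", 1)])


def test_no_edges_gives_singletons():
    graph = graph_of(["a", "b", "c", "d"], [])
    contigs = greedy_path_cover(graph)
    assert [c.genes for c in contigs] == [[("a", 0)], [("b", 0)], [("c", 0)],
                                          [("d", 0)]]


def test_heavier_edge_wins_side_conflict():
    # both edges want the downstream side of x; only the heavier survives
    graph = graph_of("xyz", [("x", 1, "y", 1, 5), ("x", 1, "z", 1, 2)])
    contigs = greedy_path_cover(graph)
    paths = sorted(canonical_path(c.genes) for c in contigs)
    assert paths == sorted([canonical_path([("x", 1), ("y", 1)]),
                            canonical_path([("z", 0)])])


def test_opposite_sides_both_kept():
    # x+->y+ uses x's head; z+->x+ uses x's tail: a 3-gene path
    graph = graph_of("xyz", [("x", 1, "y", 1, 5), ("z", 1, "x", 1, 2)])
    contigs = greedy_path_cover(graph)
    assert len(contigs) == 1
    assert canonical_path(contigs[0].genes) == canonical_path(
        [("z", 1), ("x", 1), ("y", 1)])


def test_equal_weight_ties_broken_by_canonical_key():
    graph = graph_of("abc", [("b", 1, "a", 1, 1), ("b", -1, "c", 1, 1)])
    # keys: ('a',-1,'b',-1) < ('b',-1,'c',1); both are selectable (different
    # sides of b) so the tie-break only fixes provenance order
    contigs = greedy_path_cover(graph)
    assert len(contigs) == 1 and len(contigs[0].genes) == 3


# ---------------------------------------------------------------------------
# replay oracle
# ---------------------------------------------------------------------------


def replay_path_cover(graph):
    """Independent re-implementation: explicit signed fragments, edges
    applied in (weight desc, key asc) order when both genes sit on a free,
    sign-compatible fragment end and the fragments differ."""
    fragments = {g: [(g, None)] for g in sorted(graph.nodes)}
    frag_of = {g: g for g in graph.nodes}

    def oriented(fragment, gene, sign, want_right):
        """Orient a fragment so `gene` sits with `sign` at the right (or
        left) end; None = cannot."""
        seq = fragment
        for candidate in (seq, [(g, -s if s is not None else None)
                                for g, s in reversed(seq)]):
            end = candidate[-1] if want_right else candidate[0]
            if end[0] == gene and end[1] in (sign, None):
                out = [(g, s) for g, s in candidate]
                idx = len(out) - 1 if want_right else 0
                out[idx] = (gene, sign)
                return out
        return None

    for adj in sorted(graph.weights, key=lambda a: (-graph.weights[a], a)):
        x, sx, y, sy = adj
        fx, fy = frag_of[x], frag_of[y]
        if fx == fy:
            continue
        left = oriented(fragments[fx], x, sx, want_right=True)
        right = oriented(fragments[fy], y, sy, want_right=False)
        if left is None or right is None:
            continue
        merged = left + right
        del fragments[fy]
        fragments[fx] = merged
        for g, _s in merged:
            frag_of[g] = fx

    out = []
    for fragment in fragments.values():
        genes = [(g, 0 if s is None else s) for g, s in fragment]
        rc = [(g, -s) for g, s in reversed(genes)]
        out.append(min(genes, rc))
    return sorted(out)


def random_graph(rng, max_nodes=12):
    n = rng.randint(1, max_nodes)
    nodes = [f"n{i:02d}" for i in range(n)]
    weights = {}
    for _ in range(rng.randint(0, 2 * n)):
        x, y = rng.sample(nodes, 2) if n > 1 else (nodes[0], nodes[0])
        if x == y:
            continue
        adj = canonical_adjacency(x, rng.choice([1, -1]), y, rng.choice([1, -1]))
        weights[adj] = rng.randint(1, 5)
    return AdjacencyGraph(nodes=set(nodes), weights=weights)


def assert_valid_cover(graph, contigs):
    """Degree <= 2, sign consistency, acyclicity, partition, maximality."""
    placed = [g for c in contigs for g, _s in c.genes]
    assert sorted(placed) == sorted(graph.nodes)          # partition
    used_ends = set()
    for contig in contigs:
        assert len(contig.genes) >= 1
        for (x, sx), (y, sy), adj in zip(contig.genes, contig.genes[1:],
                                         contig.edges):
            assert canonical_adjacency(x, sx, y, sy) == adj  # consistent signs
            assert adj in graph.weights
        for i, (g, s) in enumerate(contig.genes):
            if s == 0:
                continue
            if i > 0:
                used_ends.add((g, "t" if s == 1 else "h"))
            if i < len(contig.genes) - 1:
                used_ends.add((g, "h" if s == 1 else "t"))
    # maximality: no unused edge is addable at the end state
    selected = {adj for c in contigs for adj in c.edges}
    frag_of = {}
    for ci, contig in enumerate(contigs):
        for g, _s in contig.genes:
            frag_of[g] = ci
    for adj in graph.weights:
        if adj in selected:
            continue
        x, sx, y, sy = adj
        ex = (x, "h" if sx > 0 else "t")
        ey = (y, "t" if sy > 0 else "h")
        addable = (ex not in used_ends and ey not in used_ends
                   and frag_of[x] != frag_of[y])
        assert not addable, f"rejected edge {adj} is still addable"


def test_greedy_matches_replay_oracle_on_random_graphs():
    rng = random.Random(101)
    for _ in range(300):
        graph = random_graph(rng)
        contigs = greedy_path_cover(graph)
        assert_valid_cover(graph, contigs)
        got = sorted(min(c.genes, [(g, -s) for g, s in reversed(c.genes)])
                     for c in contigs)
        assert got == replay_path_cover(graph)


# ---------------------------------------------------------------------------
# round 2 and the full pipeline
# ---------------------------------------------------------------------------


def test_round2_reconnects_contigs(stree5):
    """Without rearrangements, the contig-level round relinks round-1
    contigs into the true chromosomes."""
    params = SimulationParams(genes=30, chromosomes=3, seed=4)
    dataset = simulate_dataset(stree5, params)
    from paleorder.adjacencies import weighted_adjacencies
    graph = weighted_adjacencies("root", dataset.genomes, dataset.forest, stree5)
    # cripple round 1 by dropping half the edges: contigs fragment
    weak = AdjacencyGraph(nodes=set(graph.nodes),
                          weights={a: w for i, (a, w) in
                                   enumerate(sorted(graph.weights.items()))
                                   if i % 2 == 0})
    contigs = greedy_path_cover(weak)
    assert len(contigs) > 3
    cgraph, by_id = contig_adjacency_graph(contigs, "root", dataset.genomes,
                                           dataset.forest, stree5)
    relinked = greedy_path_cover(cgraph)
    total = [sum(len(by_id[cid]) for cid, _ in path.genes) for path in relinked]
    assert sorted(total) == [10, 10, 10]  # 3 chromosomes of 10 genes


def test_single_contig_round2_graph(stree5):
    params = SimulationParams(genes=8, chromosomes=1, seed=6)
    dataset = simulate_dataset(stree5, params)
    from paleorder.adjacencies import weighted_adjacencies
    graph = weighted_adjacencies("root", dataset.genomes, dataset.forest, stree5)
    contigs = greedy_path_cover(graph)
    assert len(contigs) == 1
    cgraph, _ = contig_adjacency_graph(contigs, "root", dataset.genomes,
                                       dataset.forest, stree5)
    assert len(cgraph.nodes) == 1 and cgraph.weights == {}


def test_contig_partition_enforced(stree5):
    params = SimulationParams(genes=10, chromosomes=1, seed=6)
    dataset = simulate_dataset(stree5, params)
    from paleorder.adjacencies import weighted_adjacencies
    graph = weighted_adjacencies("root", dataset.genomes, dataset.forest, stree5)
    contigs = greedy_path_cover(graph)
    with pytest.raises(ValueError):
        contig_adjacency_graph(contigs[:-1] if len(contigs) > 1 else [],
                               "root", dataset.genomes, dataset.forest, stree5)


def test_reconstruction_invariant_under_species_order(stree5):
    params = SimulationParams(genes=40, chromosomes=3, inversions=2,
                              loss=0.02, gain=0.02, seed=19)
    dataset = simulate_dataset(stree5, params)
    blocks1 = reconstruct_ancestor("root", dataset.genomes, dataset.forest, stree5)
    reordered = dict(sorted(dataset.genomes.items(), reverse=True))
    blocks2 = reconstruct_ancestor("root", reordered, dataset.forest, stree5)
    assert blocks1.blocks == blocks2.blocks


def test_reconstruction_invariant_under_chromosome_renaming(stree5):
    params = SimulationParams(genes=40, chromosomes=3, inversions=2, seed=20)
    dataset = simulate_dataset(stree5, params)
    blocks1 = reconstruct_ancestor("root", dataset.genomes, dataset.forest, stree5)
    renamed = dict(dataset.genomes)
    g = renamed["s1"]
    renamed["s1"] = make_genome(
        "s1", {f"Z_{c}": [(r.gene_id, r.strand) for r in recs]
               for c, recs in g.chromosomes.items()})
    blocks2 = reconstruct_ancestor("root", renamed, dataset.forest, stree5)
    assert blocks1.blocks == blocks2.blocks


def test_every_content_gene_placed_once(stree5):
    params = SimulationParams(genes=35, chromosomes=3, inversions=2,
                              translocations=1, loss=0.05, gain=0.05,
                              tandem=0.03, wgd={"anc3": 0.4}, seed=29)
    dataset = simulate_dataset(stree5, params)
    for ancestor in ("root", "anc2", "anc3"):
        blocks = reconstruct_ancestor(ancestor, dataset.genomes,
                                      dataset.forest, stree5)
        content = ancestral_content(dataset.forest, stree5, ancestor)
        placed = list(blocks.genes())
        assert sorted(placed) == sorted(g.id for g in content)
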