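"""Comparative-synteny computations: dotplots, karyotype painting and
orthologous-region alignment.

All three views are order-based: a gene's coordinate is its 0-based rank
within its chromosome, so extant genomes and reconstructed ancestral block
tables (viewed as genomes via
:meth:`~paleorder.formats_io.BlockTable.as_genome_table`) are treated
identically.  TSV tables are the contract; SVG renderings are a secondary
convenience.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .formats_io import GenomeTable
from .trees_reconciliation import GeneForest, SpeciesTree, homology_pairs

DOTPLOT_COLUMNS = ["chrom1", "index1", "chrom2", "index2",
                   "element1", "element2", "type"]


def dotplot(g1: str, g2: str, forest: GeneForest, stree: SpeciesTree,
            orders: dict[str, GenomeTable]) -> pd.DataFrame:
    """Dotplot table of genome ``g1`` against genome ``g2``.

    One row per homologous pair with both elements placed; for ``g1 == g2``
    the plot shows within-genome paralogs.  Coordinates are gene ranks.
    """
    mode = "paralogs" if g1 == g2 else "all"
    pos1 = orders[g1].positions()
    pos2 = orders[g2].positions()
    rows = []
    for e1, e2, kind in homology_pairs(forest, stree, g1, g2, mode=mode):
        p1 = pos1.get(e1)
        p2 = pos2.get(e2)
        if p1 is None or p2 is None:
            continue
        rows.append((p1[0], p1[1], p2[0], p2[1], e1, e2, kind))
    rows.sort()
    return pd.DataFrame(rows, columns=DOTPLOT_COLUMNS)


def collinear_runs(table: pd.DataFrame) -> list[dict]:
    """Maximal collinear runs in a dotplot table.

    Within each chromosome pair, rows sorted by index1 are scanned for
    maximal stretches whose index2 is strictly monotone (rising for a
    direct segment, falling for an inverted one), with no gap limit —
    interleaved losses merely shorten a run, they do not break it.  Used
    to detect duplicated collinear segments, the classic whole-genome
    duplication signature in a paralog dotplot.
    """
    runs = []
    if table.empty:
        return runs
    for (c1, c2), grp in table.groupby(["chrom1", "chrom2"], sort=True):
        pts = sorted(zip(grp["index1"], grp["index2"]))
        start = 0
        direction = 0
        for i in range(1, len(pts) + 1):
            if i < len(pts):
                step = pts[i][1] - pts[i - 1][1]
                d = 1 if step > 0 else (-1 if step < 0 else 0)
            else:
                d = None
            if d is not None and d != 0 and (direction == 0 or d == direction):
                direction = d
                continue
            runs.append({"chrom1": c1, "chrom2": c2,
                         "length": i - start,
                         "direction": direction or 1,
                         "start1": pts[start][0], "end1": pts[i - 1][0]})
            start = i
            direction = 0
        # reset bookkeeping handled by loop; last run appended at i == len(pts)
    runs.sort(key=lambda r: (-r["length"], r["chrom1"], r["chrom2"], r["start1"]))
    return runs


PAINT_COLUMNS = ["chrom1", "index1", "gene", "color"]


def karyopaint(g1: str, g2: str, forest: GeneForest, stree: SpeciesTree,
               orders: dict[str, GenomeTable]) -> pd.DataFrame:
    """Karyotype of ``g1`` painted with the chromosome labels of ``g2``.

    Each gene of ``g1`` is labelled with the chromosome of its homolog in
    ``g2``; with several homologs the modal chromosome wins (ties broken
    lexicographically), and genes without a homolog are labelled NA.
    """
    pos2 = orders[g2].positions()
    homologs: dict[str, list[str]] = {}
    if g1 == g2:
        for gene, (chrom, _idx) in orders[g1].positions().items():
            homologs[gene] = [chrom]
    else:
        for e1, e2, _kind in homology_pairs(forest, stree, g1, g2, mode="all"):
            p2 = pos2.get(e2)
            if p2 is not None:
                homologs.setdefault(e1, []).append(p2[0])
    rows = []
    for chrom, recs in orders[g1].chromosomes.items():
        for idx, rec in enumerate(recs):
            labels = homologs.get(rec.gene_id)
            if not labels:
                color = "NA"
            else:
                counts = Counter(labels)
                top = max(counts.values())
                color = min(c for c, n in counts.items() if n == top)
            rows.append((chrom, idx, rec.gene_id, color))
    return pd.DataFrame(rows, columns=PAINT_COLUMNS)


@dataclass
class AlignRow:
    """One target region matching the reference region: the target genome,
    the target chromosome, and the matched genes with their offsets (in
    genes) from the reference gene."""

    genome: str
    chromosome: str
    matches: list[tuple[int, str, str, int]] = field(default_factory=list)
    # (reference offset, reference gene, target gene, target rank)


def align_view(ref_gene: str, forest: GeneForest, stree: SpeciesTree,
               orders: dict[str, GenomeTable], genomes: list[str] | None = None,
               window: int = 15, cap: int = 200) -> list[AlignRow]:
    """Project the region around ``ref_gene`` onto other genomes.

    The reference region covers up to ``window`` genes on each side of the
    reference gene (truncated at chromosome ends).  For every target
    genome, homologs of the region's genes are grouped by target
    chromosome; a group qualifies as a row when it contains at least two
    matched genes, so a genome lacking a direct homolog of the reference
    gene can still appear through its neighbours.  Several rows per genome
    indicate the region is split — or, after a whole-genome duplication,
    duplicated — across chromosomes.  At most ``cap`` homologs are
    reported per call, nearest to the reference first.
    """
    ref_genome = None
    for name, table in orders.items():
        if ref_gene in table.positions():
            ref_genome = name
            break
    if ref_genome is None:
        raise ValueError(f"unknown reference gene {ref_gene!r}")
    chrom, rank = orders[ref_genome].positions()[ref_gene]
    recs = orders[ref_genome].chromosomes[chrom]
    lo = max(0, rank - window)
    hi = min(len(recs), rank + window + 1)
    region = {recs[i].gene_id: i - rank for i in range(lo, hi)}

    if genomes is None:
        genomes = sorted(orders)
    candidates = []  # (|offset|, offset, genome, target chrom, ref gene, target gene, target rank)
    for target in genomes:
        pos_t = orders[target].positions()
        if target == ref_genome:
            pairs = [(g, g, "self") for g in region]
        else:
            pairs = homology_pairs(forest, stree, ref_genome, target, mode="all")
        for e1, e2, _kind in pairs:
            off = region.get(e1)
            if off is None:
                continue
            pt = pos_t.get(e2)
            if pt is None:
                continue
            candidates.append((abs(off), off, target, pt[0], e1, e2, pt[1]))
    candidates.sort()
    kept = candidates[:cap]

    groups: dict[tuple[str, str], list[tuple[int, str, str, int]]] = {}
    for _a, off, target, tchrom, e1, e2, trank in kept:
        groups.setdefault((target, tchrom), []).append((off, e1, e2, trank))
    rows = []
    for (target, tchrom) in sorted(groups):
        matches = sorted(groups[(target, tchrom)], key=lambda m: (m[3], m[0]))
        if len(matches) < 2:
            continue
        rows.append(AlignRow(genome=target, chromosome=tchrom, matches=matches))
    return rows


def align_view_frame(rows: list[AlignRow]) -> pd.DataFrame:
    out = []
    for i, row in enumerate(rows):
        for off, ref, tgt, trank in row.matches:
            out.append((i, row.genome, row.chromosome, off, ref, tgt, trank))
    return pd.DataFrame(out, columns=["row", "genome", "chromosome",
                                      "offset", "ref_gene", "target_gene",
                                      "target_rank"])


# ---------------------------------------------------------------------------
# SVG renderings (non-normative)
# ---------------------------------------------------------------------------


def dotplot_svg(table: pd.DataFrame, path, title: str = "") -> None:
    """Scatter rendering of a dotplot table; one panel, rank coordinates
    offset by cumulative chromosome lengths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if not table.empty:
        off1 = _chrom_offsets(table, "chrom1", "index1")
        off2 = _chrom_offsets(table, "chrom2", "index2")
        xs = table["index1"] + table["chrom1"].map(off1)
        ys = table["index2"] + table["chrom2"].map(off2)
        ax.scatter(xs, ys, s=4, c="black")
        for v in off1.values():
            ax.axvline(v, lw=0.3, c="grey")
        for v in off2.values():
            ax.axhline(v, lw=0.3, c="grey")
    ax.set_xlabel("genome 1 (gene rank)")
    ax.set_ylabel("genome 2 (gene rank)")
    if title:
        ax.set_title(title)
    fig.savefig(path, format="svg")
    plt.close(fig)


def karyopaint_svg(table: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    chroms = sorted(table["chrom1"].unique())
    colors = sorted(c for c in table["color"].unique() if c != "NA")
    cmap = matplotlib.colormaps["tab20"].resampled(max(len(colors), 1))
    color_of = {c: cmap(i) for i, c in enumerate(colors)}
    color_of["NA"] = (0.8, 0.8, 0.8, 1.0)
    for y, chrom in enumerate(chroms):
        sub = table[table["chrom1"] == chrom]
        ax.bar(sub["index1"], 0.8, bottom=y, width=1.0,
               color=[color_of[c] for c in sub["color"]], align="edge")
        ax.text(-1, y + 0.4, chrom, ha="right", va="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("gene rank")
    if title:
        ax.set_title(title)
    fig.savefig(path, format="svg")
    plt.close(fig)


def _chrom_offsets(table, chrom_col, index_col):
    sizes = table.groupby(chrom_col)[index_col].max() + 1
    offsets = {}
    total = 0
    for chrom in sorted(sizes.index):
        offsets[chrom] = total
        total += int(sizes[chrom]) + 1
    return offsets
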