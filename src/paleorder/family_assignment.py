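"""Assign proteins of a new species to pre-existing gene families.

Protein similarity search hits (query, target, bitscore, e-value) are
filtered at an e-value cutoff (default 1e-4, inclusive), and each query is
assigned to the candidate family with the highest *average family
bitscore*: the mean of the query's per-target scores over that family's
members it hits.  Multiple hits to the same target (separate HSPs) are
averaged into one per-target score first, so long proteins do not dominate
the family mean.  Ties go to the lexicographically smallest family id,
with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .formats_io import FormatError, ValidationError

logger = logging.getLogger("paleorder")

DEFAULT_EVALUE_CUTOFF = 1e-4


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    target: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore for {self.query}->{self.target}")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value for {self.query}->{self.target}")


def filter_hits(hits: list[SimilarityHit],
                cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[SimilarityHit]:
    """Keep hits with e-value <= cutoff (inclusive), preserving order."""
    if cutoff < 0:
        raise ValueError("e-value cutoff must be non-negative")
    return [h for h in hits if h.evalue <= cutoff]


def assign_families(hits: list[SimilarityHit],
                    catalog: dict[str, set[str]]) -> dict[str, tuple[str, float]]:
    """Map each query to (best family id, average family bitscore).

    ``catalog`` maps family id to member protein ids; a protein may belong
    to at most one family.  Hits to proteins in no family are ignored, and
    queries with no resolvable hit are absent from the result.
    """
    if not catalog:
        raise ValueError("empty family catalog")
    member_to_family: dict[str, str] = {}
    for family, members in catalog.items():
        for protein in members:
            if protein in member_to_family and member_to_family[protein] != family:
                raise ValidationError(
                    f"protein {protein!r} belongs to families "
                    f"{member_to_family[protein]!r} and {family!r}")
            member_to_family[protein] = family

    # per (query, target): mean over HSPs
    per_target: dict[tuple[str, str], list[float]] = {}
    for hit in hits:
        if hit.target not in member_to_family:
            continue
        per_target.setdefault((hit.query, hit.target), []).append(hit.bitscore)

    per_family: dict[str, dict[str, list[float]]] = {}
    for (query, target), scores in per_target.items():
        family = member_to_family[target]
        per_family.setdefault(query, {}).setdefault(family, []).append(
            sum(scores) / len(scores))

    out: dict[str, tuple[str, float]] = {}
    for query in sorted(per_family):
        means = {fam: sum(v) / len(v) for fam, v in per_family[query].items()}
        best_score = max(means.values())
        best = sorted(fam for fam, m in means.items() if m == best_score)
        if len(best) > 1:
            logger.warning("query %s: families %s tie at average bitscore %.6g; "
                           "keeping %s", query, best, best_score, best[0])
        out[query] = (best[0], best_score)
    return out


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def read_hits(path, columns: tuple[int, int, int, int] = (0, 1, 2, 3)) -> list[SimilarityHit]:
    """Read a tab-separated hits table.

    ``columns`` gives the 0-based positions of (query, target, bitscore,
    evalue); pass ``(0, 1, 11, 10)`` for standard 12-column tabular search
    output.
    """
    path = Path(path)
    qi, ti, bi, ei = columns
    width = max(columns) + 1
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < width:
                raise FormatError(f"expected at least {width} columns, got "
                                  f"{len(cols)}", path, lineno)
            try:
                hits.append(SimilarityHit(cols[qi], cols[ti],
                                          float(cols[bi]), float(cols[ei])))
            except (ValueError, ValidationError) as exc:
                raise FormatError(str(exc), path, lineno) from None
    return hits


def read_catalog(path) -> dict[str, set[str]]:
    """Read a tab-separated family catalog: family_id, protein_id."""
    path = Path(path)
    catalog: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"expected 2 columns, got {len(cols)}", path, lineno)
            catalog.setdefault(cols[0], set()).add(cols[1])
    return catalog


def write_assignments(assignments: dict[str, tuple[str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("#query\tfamily\taverage_bitscore\n")
        for query in sorted(assignments):
            family, score = assignments[query]
            fh.write(f"{query}\t{family}\t{score:.6g}\n")
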