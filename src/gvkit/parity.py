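"""Orthology by reciprocal best hit and gene parity (synteny) statistics.

A gene parity plot places each ORF of genome A at x = its ORF number and
y = the ORF number of its orthologue in genome B; orthologues are assigned
by reciprocal best hit (RBH) between the two proteomes.  ORFs present in
only one genome sit on the corresponding axis.  Conserved gene order shows
up as points along the diagonal; the breakpoint statistic quantifies the
departure as the number of adjacent orthologue pairs in A whose partners
are not adjacent in B (a single inverted block of two or more genes
therefore contributes two breakpoints).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import AlignmentParams, PRESETS, make_null_calibration, search_best_hits

__all__ = [
    "OrthologyMap",
    "ParityTable",
    "reciprocal_best_hits",
    "gene_parity_table",
    "synteny_breakpoints",
]


@dataclass
class OrthologyMap:
    """Reciprocal-best-hit pairs of (index in A, index in B) with scores."""

    pairs: list[tuple[int, int]]
    scores: dict[tuple[int, int], float]
    identities: dict[tuple[int, int], float]
    method: str = "reciprocal-best-hit"


@dataclass
class ParityTable:
    """Plot-ready parity points.

    ``points`` holds (x, y, category) with 1-based ORF numbers; axis markers
    use 0 on the missing side and category "A-only"/"B-only".
    """

    points: list[tuple[int, int, str]]

    @property
    def paired(self) -> list[tuple[int, int]]:
        return [(x, y) for x, y, c in self.points if c == "pair"]


def _best_hits_one_way(
    queries: Sequence[tuple[str, str]],
    db: Sequence[tuple[str, str]],
    params: AlignmentParams,
    evalue_cutoff: float,
    seed: int,
) -> dict[int, tuple[int, float, float]]:
    null = make_null_calibration(db, params, seed)
    out = {}
    for qi, (_, qseq) in enumerate(queries):
        hits = search_best_hits(qseq, db, params, evalue_cutoff, seed=seed, _null=null)
        if hits:
            top = hits[0]
            out[qi] = (top.target_index, top.score, top.identity)
    return out


def reciprocal_best_hits(
    proteome_a: Sequence[tuple[str, str]],
    proteome_b: Sequence[tuple[str, str]],
    params: AlignmentParams | None = None,
    evalue_cutoff: float = 0.010,
    seed: int = 0,
) -> OrthologyMap:
    """RBH orthology between two (id, sequence) proteomes.

    A pair (a, b) is kept iff b is a's best hit and a is b's best hit, both
    below the e-value cutoff.  Each ORF appears in at most one pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    params = params or PRESETS["default"]
    ab = _best_hits_one_way(proteome_a, proteome_b, params, evalue_cutoff, seed)
    ba = _best_hits_one_way(proteome_b, proteome_a, params, evalue_cutoff, seed)
    pairs = []
    scores = {}
    idents = {}
    for ai, (bi, score, ident) in sorted(ab.items()):
        back = ba.get(bi)
        if back is not None and back[0] == ai:
            pairs.append((ai, bi))
            scores[(ai, bi)] = score
            idents[(ai, bi)] = ident
    return OrthologyMap(pairs, scores, idents)


def gene_parity_table(
    orthology: OrthologyMap, order_a: Sequence[int], order_b: Sequence[int]
) -> ParityTable:
    """One parity point per ORF.

    ``order_a``/``order_b`` give the ORF numbers of the two annotations, in
    proteome index order (``order_a[i]`` is the ORF number of proteome A
    entry i).
    """
    paired_a = {a for a, _ in orthology.pairs}
    paired_b = {b for _, b in orthology.pairs}
    points: list[tuple[int, int, str]] = []
    for a, b in orthology.pairs:
        points.append((order_a[a], order_b[b], "pair"))
    for i, num in enumerate(order_a):
        if i not in paired_a:
            points.append((num, 0, "A-only"))
    for j, num in enumerate(order_b):
        if j not in paired_b:
            points.append((0, num, "B-only"))
    points.sort(key=lambda p: (p[0], p[1]))
    return ParityTable(points)


def synteny_breakpoints(table: ParityTable) -> int:
    """Adjacent orthologue pairs in A whose partners are not adjacent in B.

    Orthologue pairs are ranked by position in each genome; neighbours in
    the A ranking whose B ranks differ by other than +/-1 count as one
    breakpoint.  Perfect colinearity gives 0; an inverted block of k >= 2
    genes gives 2.  The count is symmetric in A and B.
    """
    pairs = table.paired
    if len(pairs) < 2:
        raise ValueError("need at least 2 orthologue pairs")
    pairs.sort(key=lambda p: p[0])
    b_order = sorted(y for _, y in pairs)
    rank_b = {y: r for r, y in enumerate(b_order)}
    ranks = [rank_b[y] for _, y in pairs]
    return sum(1 for r1, r2 in zip(ranks, ranks[1:]) if abs(r2 - r1) != 1)
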