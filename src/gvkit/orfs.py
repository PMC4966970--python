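"""ORF finding, classification, and anchor-based numbering on circular genomes.

An ORF here is a maximal ATG-to-stop reading frame (the first in-frame ATG
after the previous in-frame stop) on either strand of the circle, including
frames that run across the origin.  Candidates longer than a codon cutoff
(default: strictly more than 50 codons, stop excluded) are annotated when

* they are evolutionarily conserved — a similarity search against a
  reference proteome returns a hit with e-value < 0.010 ("conserved"); or
* they do not overlap a longer kept ORF by more than 75 bp and two
  independent coding-potential scores both call them coding
  ("predicted-coding").

The two coding scores stand in for the two independent gene predictors
commonly used for small viral genomes: a per-codon codon-usage
log-likelihood ratio, and a linear discriminant on phase-specific Z-curve
composition features.  Both are trained per genome on its conserved ORFs
against nucleotide-shuffled (frame-recut) decoys and thresholded at 0.

Numbering follows the granulovirus convention: the genome is rotated so the
adenine of the anchor (granulin) start codon is position 1 with the anchor
reading on the plus strand, and kept ORFs are numbered 1..n by start
position from there.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .align import AlignmentParams, Hit, PRESETS, make_null_calibration, search_best_hits
from .genome import CircularGenome, GenomeInterval, remap_interval, revcomp, rotate_to_anchor

__all__ = [
    "OrfRecord",
    "CodingScore",
    "CodingModel",
    "find_orfs",
    "classify_orfs",
    "number_orfs",
    "annotate_genome",
    "AnnotatedGenome",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfRecord:
    interval: GenomeInterval
    length_codons: int  # stop codon excluded
    seq: str = ""  # nucleotide sequence in reading orientation, incl. stop
    number: int | None = None
    orf_class: str | None = None  # "conserved" | "predicted-coding"
    product: str = ""
    best_hit: Hit | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def aa(self) -> str:
        return str(Seq(self.seq[:-3]).translate())

    def span_bp(self, genome_length: int) -> int:
        return self.interval.length(genome_length)


@dataclass(frozen=True)
class CodingScore:
    llr_codon_usage: float
    zcurve_score: float

    @property
    def calls(self) -> tuple[bool, bool]:
        return self.llr_codon_usage > 0.0, self.zcurve_score > 0.0


def _scan_strand(seq: str, min_codons: int, strand: str, n: int) -> list[tuple[int, int]]:
    """Maximal ORFs on one strand of a circular sequence.

    ``seq`` is the working-orientation sequence; returns 0-based
    (start, span) pairs on the working orientation, deduplicated modulo n.
    """
    tripled = seq + seq + seq
    found: dict[int, int] = {}
    for frame in range(3):
        # an ORF start is only trusted once an in-frame stop has been seen,
        # so frames that begin mid-ORF are picked up on a later copy
        seen_stop = False
        pending_atg: int | None = None
        i = frame
        while i + 3 <= len(tripled):
            codon = tripled[i : i + 3]
            if codon in _STOPS:
                if pending_atg is not None:
                    span = i + 3 - pending_atg
                    ncodons = span // 3 - 1
                    if ncodons > min_codons and span <= n:
                        found.setdefault(pending_atg % n, span)
                    pending_atg = None
                seen_stop = True
            elif codon == "ATG" and pending_atg is None and seen_stop:
                pending_atg = i
            i += 3
    return sorted(found.items())


def find_orfs(genome: CircularGenome, min_codons: int = 50) -> list[OrfRecord]:
    """All maximal ATG-to-stop ORFs strictly longer than ``min_codons`` codons.

    Both strands are scanned and origin-spanning ORFs are reported with
    ``wraps_origin`` set.  Records are unclassified and unnumbered.
    """
    n = genome.length
    if n < 6:
        return []
    out: list[OrfRecord] = []
    for strand in "+-":
        working = genome.seq if strand == "+" else revcomp(genome.seq)
        for start0, span in _scan_strand(working, min_codons, strand, n):
            orf_seq = (working + working)[start0 : start0 + span]
            if strand == "+":
                s = start0 + 1
                e = ((start0 + span - 1) % n) + 1
            else:
                # map working coordinates back to genome coordinates
                ws, we = start0 + 1, ((start0 + span - 1) % n) + 1
                s, e = n + 1 - we, n + 1 - ws
            wraps = s > e
            out.append(
                OrfRecord(
                    GenomeInterval(s, e, strand, wraps_origin=wraps),
                    length_codons=span // 3 - 1,
                    seq=orf_seq,
                )
            )
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return out


# ---------------------------------------------------------------------------
# coding potential


def _codon_counts(seqs: Sequence[str]) -> np.ndarray:
    from itertools import product

    codons = ["".join(c) for c in product("ACGT", repeat=3)]
    index = {c: i for i, c in enumerate(codons)}
    counts = np.ones(64)  # +1 pseudocount
    for s in seqs:
        body = s[: len(s) - len(s) % 3]
        for i in range(0, len(body) - 3, 3):  # exclude terminal stop region
            c = body[i : i + 3]
            if c in index and c not in _STOPS:
                counts[index[c]] += 1
    return counts


def _zcurve_features(seq: str) -> np.ndarray:
    """9 phase-specific Z-curve components (x, y, z per codon position)."""
    body = seq[: len(seq) - len(seq) % 3]
    feats = []
    for phase in range(3):
        sub = body[phase::3]
        L = max(len(sub), 1)
        a, c, g, t = (sub.count(b) / L for b in "ACGT")
        feats.extend([(a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)])
    return np.asarray(feats)


def _shuffle_decoy(seq: str, rng: random.Random) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


@dataclass
class CodingModel:
    """Two independent coding-potential scores trained on one genome.

    Positives are the genome's conserved-class ORFs; decoys are
    nucleotide-shuffled copies recut in frame.  Scores are length-normalized
    so duplicating a sequence leaves them unchanged.
    """

    log_ratio: np.ndarray  # 64-vector of log(coding/null) codon frequencies
    z_weights: np.ndarray
    z_bias: float

    @classmethod
    def train(cls, positive_seqs: Sequence[str], seed: int = 0, decoys_per: int = 3) -> "CodingModel":
        if not positive_seqs:
            raise ValueError("need at least one positive training ORF")
        rng = random.Random(seed)
        decoys = [
            _shuffle_decoy(s, rng) for s in positive_seqs for _ in range(decoys_per)
        ]
        pos_counts = _codon_counts(positive_seqs)
        null_counts = _codon_counts(decoys)
        log_ratio = np.log(pos_counts / pos_counts.sum()) - np.log(
            null_counts / null_counts.sum()
        )
        zp = np.array([_zcurve_features(s) for s in positive_seqs])
        zn = np.array([_zcurve_features(s) for s in decoys])
        mp, mn = zp.mean(axis=0), zn.mean(axis=0)
        cov = np.cov(np.vstack([zp - mp, zn - mn]).T) + 1e-4 * np.eye(9)
        w = np.linalg.solve(cov, mp - mn)
        bias = -0.5 * float(w @ (mp + mn))
        return cls(log_ratio, w, bias)

    def score(self, orf_seq: str) -> CodingScore:
        from itertools import product

        codons = ["".join(c) for c in product("ACGT", repeat=3)]
        index = {c: i for i, c in enumerate(codons)}
        body = orf_seq[: len(orf_seq) - len(orf_seq) % 3]
        total = 0.0
        ncod = 0
        for i in range(0, len(body) - 3, 3):
            c = body[i : i + 3]
            if c in index and c not in _STOPS:
                total += self.log_ratio[index[c]]
                ncod += 1
        llr = total / ncod if ncod else 0.0
        z = float(self.z_weights @ _zcurve_features(orf_seq) + self.z_bias)
        return CodingScore(llr, z)


# ---------------------------------------------------------------------------
# classification


def _circular_positions(iv: GenomeInterval, n: int) -> set[int]:
    out: set[int] = set()
    for s, e in iv.segments(n):
        out.update(range(s, e + 1))
    return out


def _overlap_bp(a: GenomeInterval, b: GenomeInterval, n: int) -> int:
    return len(_circular_positions(a, n) & _circular_positions(b, n))


def classify_orfs(
    candidates: Sequence[OrfRecord],
    ref_db: Sequence[tuple[str, str]],
    genome_length: int,
    params: AlignmentParams | None = None,
    overlap_limit: int = 75,
    evalue_cutoff: float = 0.010,
    seed: int = 0,
    coding_model: CodingModel | None = None,
) -> tuple[list[OrfRecord], list[OrfRecord]]:
    """Apply the conservation / overlap / coding-potential decision rule.

    Candidates are processed longest-first.  A candidate is kept as
    "conserved" when the reference-proteome search yields a hit below the
    e-value cutoff.  Otherwise it is kept as "predicted-coding" only when
    its overlap with every longer *kept* ORF is at most ``overlap_limit``
    bp (76+ bp triggers rejection) and both coding calls are positive.
    Returns (kept, dropped).
    """
    params = params or PRESETS["default"]
    null = make_null_calibration(ref_db, params, seed) if ref_db else None
    ordered = sorted(
        candidates, key=lambda o: (-o.length_codons, o.interval.start, o.strand)
    )
    hits: dict[int, Hit | None] = {}
    conserved: list[OrfRecord] = []
    unresolved: list[OrfRecord] = []
    for orf in ordered:
        best = None
        if ref_db:
            found = search_best_hits(
                orf.aa, ref_db, params, evalue_cutoff, seed=seed, _null=null
            )
            best = found[0] if found else None
        hits[id(orf)] = best
        if best is not None:
            conserved.append(replace_orf(orf, orf_class="conserved", best_hit=best))
        else:
            unresolved.append(orf)
    model = coding_model
    if model is None and conserved:
        model = CodingModel.train([o.seq for o in conserved], seed=seed)
    kept = list(conserved)
    dropped: list[OrfRecord] = []
    for orf in unresolved:
        longer_kept = [k for k in kept if k.length_codons > orf.length_codons]
        max_ov = max(
            (_overlap_bp(orf.interval, k.interval, genome_length) for k in longer_kept),
            default=0,
        )
        calls = model.score(orf.seq).calls if model is not None else (False, False)
        if max_ov <= overlap_limit and all(calls):
            kept.append(replace_orf(orf, orf_class="predicted-coding"))
        else:
            dropped.append(orf)
    kept.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return kept, dropped


def replace_orf(orf: OrfRecord, **kw) -> OrfRecord:
    return replace(orf, **kw)


# ---------------------------------------------------------------------------
# numbering


@dataclass
class AnnotatedGenome:
    genome: CircularGenome
    orfs: list[OrfRecord]
    hrs: list = field(default_factory=list)

    @property
    def proteome(self) -> list[tuple[str, str]]:
        return [(f"ORF{o.number}", o.aa) for o in self.orfs]


def number_orfs(
    genome: CircularGenome, kept: Sequence[OrfRecord], anchor: OrfRecord
) -> AnnotatedGenome:
    """Rotate the genome to the anchor ORF start and number ORFs 1..n.

    The anchor's start-codon adenine becomes position 1 and the anchor reads
    on the plus strand; remaining ORFs are numbered by ascending start.
    """
    if anchor not in kept:
        raise ValueError("anchor ORF must be among the kept ORFs")
    iv = anchor.interval
    anchor_pos = iv.start if iv.strand == "+" else iv.end
    rotated, remap = rotate_to_anchor(genome, anchor_pos, iv.strand)
    n = genome.length
    new_orfs = [
        replace_orf(o, interval=remap_interval(o.interval, remap, n)) for o in kept
    ]
    new_orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    for i, o in enumerate(new_orfs, start=1):
        o.number = i
    return AnnotatedGenome(rotated, new_orfs)


def annotate_genome(
    genome: CircularGenome,
    ref_db: Sequence[tuple[str, str]],
    min_codons: int = 50,
    overlap_limit: int = 75,
    evalue_cutoff: float = 0.010,
    seed: int = 0,
    params: AlignmentParams | None = None,
    anchor_product: str | None = None,
) -> tuple[AnnotatedGenome, list[OrfRecord]]:
    """Full annotation pipeline: find, classify, anchor, number.

    The anchor is the kept conserved ORF whose best hit id contains
    ``anchor_product`` (default: the highest-scoring conserved ORF).
    Returns the annotated (rotated) genome and the dropped candidates in
    original coordinates.
    """
    candidates = find_orfs(genome, min_codons)
    kept, dropped = classify_orfs(
        candidates, ref_db, genome.length, params, overlap_limit, evalue_cutoff, seed
    )
    conserved = [o for o in kept if o.orf_class == "conserved"]
    if not conserved:
        raise ValueError("no conserved ORF available to anchor the numbering")
    if anchor_product:
        anchored = [o for o in conserved if anchor_product in (o.best_hit.target_id if o.best_hit else "")]
        anchor = anchored[0] if anchored else max(conserved, key=lambda o: o.best_hit.score)
    else:
        anchor = max(conserved, key=lambda o: o.best_hit.score)
    return number_orfs(genome, kept, anchor), dropped
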