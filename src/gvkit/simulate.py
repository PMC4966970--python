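"""Seeded synthetic genomes, proteomes and transcriptome contigs with truth.

The generator emulates the inputs of a granulovirus genome study so that
every pipeline stage can be exercised without downloads: a circular dsDNA
genome densely packed with protein-coding ORFs on both strands, a handful
of homologous repeat regions (clusters of imperfect palindromes whose arms
begin with an inverted terminal-repeat consensus), a diverged reference
proteome standing in for related-virus databases, and transcriptome
contigs carrying substitutions, in-frame and frameshift indels, one
homopolymer-slippage indel (8A -> 9A style) and one inverted-duplication
chimera contig — the characteristic assembly artifact in which a contig is
a sequence followed by its own reverse complement.

Coding sequence is sampled from a biased codon model (a preferred wobble
codon per amino acid, with GC pressure solved numerically so realized
genome GC hits the requested value); intergenic background is an order-0
model at the same GC.  Everything downstream of the spec + seed is
deterministic, and every planted feature is recorded in a TruthSet.

The "paper-like" preset mirrors a published granulovirus study design:
112,536 bp, 44.2% GC, 123 ORFs (64 sense / 59 antisense), 7 hrs with 1-3
palindromes of 49-83 bp bounded by TGATGACGAA-type inverted repeats, and
eight transcriptome contig intervals totalling ~45.6% of the genome with
~1.3 substitutions per covered kbp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _product
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .genome import CircularGenome, GenomeInterval, revcomp
from .transcripts import (
    VariantRecord,
    _homopolymer_context,
    left_normalize_deletion,
    left_normalize_insertion,
)

__all__ = ["SyntheticSpec", "TruthSet", "PRESETS", "generate_genome", "generate_proteome", "mutate_to_contigs", "generate_study"]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = ["".join(c) for c in _product("ACGT", repeat=3)]
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
# typical proteome amino-acid weights (roughly empirical composition)
_AA_WEIGHTS = {
    "A": 7.9, "C": 1.9, "D": 5.4, "E": 6.3, "F": 4.0, "G": 6.9, "H": 2.3,
    "I": 5.5, "K": 5.9, "L": 9.7, "M": 2.4, "N": 4.3, "P": 4.7, "Q": 3.9,
    "R": 5.2, "S": 6.9, "T": 5.6, "V": 6.7, "W": 1.1, "Y": 3.0,
}


@dataclass(frozen=True)
class SyntheticSpec:
    genome_length: int = 112_536
    gc: float = 0.442
    n_orfs: int = 123
    n_sense: int = 64
    orf_codon_range: tuple[int, int] = (60, 450)
    n_hrs: int = 7
    palindromes_per_hr: tuple[int, int] = (1, 3)
    palindrome_len_range: tuple[int, int] = (49, 83)
    terminal_consensus: str = "TGATGACGAA"
    terminal_mismatch_rate: float = 0.05
    proteome_divergence: float = 0.30
    homolog_fraction: float = 0.90
    n_decoys: int = 30
    contig_intervals: tuple[tuple[int, int], ...] | None = None
    substitution_rate: float = 1.29e-3
    indel_rate: float = 2.0e-4
    slippage_count: int = 1
    chimera_count: int = 1

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate, self.proteome_divergence,
                  self.homolog_fraction, self.terminal_mismatch_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.genome_length <= 0 or self.n_orfs <= 0:
            raise ValueError("lengths and counts must be positive")


# The eight transcriptome alignment intervals of the reference study design.
PAPER_CONTIG_INTERVALS = (
    (2841, 7436), (10664, 13710), (18056, 27589), (29803, 34735),
    (64189, 69653), (70348, 71408), (72086, 77471), (79003, 96283),
)

PRESETS: dict[str, SyntheticSpec] = {
    "easy": SyntheticSpec(
        genome_length=30_000, gc=0.45, n_orfs=18, n_sense=10,
        orf_codon_range=(60, 220), n_hrs=3, proteome_divergence=0.25,
        homolog_fraction=1.0, n_decoys=10,
        contig_intervals=((2001, 6500), (9001, 13500), (16001, 20500), (23001, 27000)),
        substitution_rate=2.0e-3, indel_rate=4.0e-4,
    ),
    "paper-like": SyntheticSpec(contig_intervals=PAPER_CONTIG_INTERVALS),
    "hard": SyntheticSpec(
        contig_intervals=PAPER_CONTIG_INTERVALS,
        proteome_divergence=0.45, homolog_fraction=0.8,
        substitution_rate=4.0e-3, indel_rate=6.0e-4,
    ),
}


@dataclass
class PlantedOrf:
    index: int  # 1-based, in genome order (== expected ORF number)
    interval: GenomeInterval
    body: str  # nucleotide sequence in reading orientation incl. stop codon
    has_homolog: bool

    @property
    def aa(self) -> str:
        return str(Seq(self.body[:-3]).translate())


@dataclass
class PlantedHr:
    name: str
    span: GenomeInterval
    palindrome_intervals: list[GenomeInterval]


@dataclass
class TruthSet:
    orfs: list[PlantedOrf] = field(default_factory=list)
    hrs: list[PlantedHr] = field(default_factory=list)
    spacers: list[tuple[int, int]] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    contig_intervals: list[tuple[int, int]] = field(default_factory=list)
    chimera_junctions: dict[str, int] = field(default_factory=dict)
    slippage_runs: list[tuple[str, int, int]] = field(default_factory=list)  # (base, start, run_len)


# ---------------------------------------------------------------------------
# codon model


def _codon_table() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for c in _CODONS:
        if c in _STOPS:
            continue
        aa = str(Seq(c).translate())
        table.setdefault(aa, []).append(c)
    return table


_SYN = _codon_table()


def _codon_probs(q: float) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities: preferred wobble codon x GC pressure q."""
    probs = {}
    for aa, codons in _SYN.items():
        w = []
        for k, c in enumerate(codons):
            pref = 2.0 if k == 0 else 1.0  # deterministic preferred codon
            gc = c.count("G") + c.count("C")
            w.append(pref * q**gc)
        w = np.asarray(w)
        probs[aa] = w / w.sum()
    return probs


def _aa_probs() -> tuple[list[str], np.ndarray]:
    aas = list(_AA_WEIGHTS)
    w = np.array([_AA_WEIGHTS[a] for a in aas])
    return aas, w / w.sum()


def _expected_coding_gc(q: float) -> float:
    aas, pw = _aa_probs()
    cp = _codon_probs(q)
    total = 0.0
    for aa, p in zip(aas, pw):
        codons = _SYN[aa]
        gcs = np.array([c.count("G") + c.count("C") for c in codons])
        total += p * float(cp[aa] @ gcs)
    return total / 3.0


def _solve_gc_pressure(target: float) -> float:
    lo, hi = 0.02, 50.0
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if _expected_coding_gc(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _random_coding(n_codons: int, rng: np.random.Generator, cp, aas, aap) -> str:
    picks = rng.choice(len(aas), size=n_codons, p=aap)
    out = []
    for k in picks:
        aa = aas[k]
        codons = _SYN[aa]
        out.append(codons[rng.choice(len(codons), p=cp[aa])])
    return "".join(out)


def _random_background(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# genome assembly


def _make_palindrome(length: int, consensus: str, gc: float, rng: np.random.Generator) -> str:
    """Imperfect palindrome whose arms start with the terminal consensus.

    Because the second arm is the reverse complement of the first, the
    reverse complement of the consensus automatically closes the window,
    giving the inverted terminal-repeat pair.
    """
    arm_len = length // 2
    arm = consensus + _random_background(arm_len - len(consensus), gc, rng)
    center = _random_background(length - 2 * arm_len, gc, rng)
    return arm + center + revcomp(arm)


def generate_genome(spec: SyntheticSpec, seed: int = 0) -> tuple[CircularGenome, TruthSet]:
    """Assemble a circular genome with planted ORFs and hrs, plus its truth.

    The genome is already in anchor orientation: the designated anchor ORF
    (a granulin stand-in, the first and most conserved ORF) starts at
    position 1 on the plus strand, with its upstream in-frame stop placed
    at the end of the circle.
    """
    rng = np.random.default_rng(seed)
    q = _solve_gc_pressure(spec.gc)
    cp = _codon_probs(q)
    aas, aap = _aa_probs()

    lo, hi = spec.orf_codon_range
    n_codons = rng.integers(lo, hi + 1, size=spec.n_orfs)
    strands = np.array(["+"] * spec.n_sense + ["-"] * (spec.n_orfs - spec.n_sense))
    rng.shuffle(strands)
    if strands[0] != "+":  # anchor ORF must read on the plus strand at nt 1
        k = int(np.argmax(strands == "+"))
        strands[0], strands[k] = "+", "-"

    # hr cassettes, distributed evenly among the ORF cassettes
    hr_plans = []
    for _ in range(spec.n_hrs):
        k = int(rng.integers(spec.palindromes_per_hr[0], spec.palindromes_per_hr[1] + 1))
        pals = [
            _make_palindrome(
                int(rng.integers(spec.palindrome_len_range[0], spec.palindrome_len_range[1] + 1)),
                spec.terminal_consensus, spec.gc, rng,
            )
            for _ in range(k)
        ]
        gaps = [int(rng.integers(60, 140)) for _ in range(k - 1)]
        hr_plans.append((pals, gaps))
    hr_after: dict[int, int] = {}
    for i in range(spec.n_hrs):
        slot = int(round((i + 1) * spec.n_orfs / (spec.n_hrs + 1)))
        while slot in hr_after:  # keep hr cassettes in distinct slots
            slot += 1
        hr_after[min(slot, spec.n_orfs - 1)] = i

    bodies = []
    for i in range(spec.n_orfs):
        nc = int(n_codons[i])
        stop = _STOPS[rng.integers(0, 3)]
        bodies.append("ATG" + _random_coding(nc - 1, rng, cp, aas, aap) + stop)
    cassette_len = sum(len(b) + 3 for b in bodies)  # +3 for each upstream guard stop
    hr_len = sum(sum(map(len, pals)) + sum(gaps) for pals, gaps in hr_plans)
    n_slots = spec.n_orfs + spec.n_hrs  # spacer after every cassette (last wraps to start)
    budget = spec.genome_length - cassette_len - hr_len
    min_spacer = 25
    if budget < min_spacer * n_slots:
        raise ValueError("spec leaves no room for spacers; reduce ORF sizes or counts")
    w = rng.random(n_slots) + 0.3
    spacer_lens = np.floor(w / w.sum() * (budget - min_spacer * n_slots)).astype(int) + min_spacer
    spacer_lens[-1] += budget - int(spacer_lens.sum())

    truth = TruthSet()
    parts: list[str] = []
    pos = 0  # 0-based length so far
    spacer_i = 0

    def add_spacer():
        nonlocal pos, spacer_i
        n = int(spacer_lens[spacer_i])
        spacer_i += 1
        seg = _random_background(n, spec.gc, rng)
        parts.append(seg)
        truth.spacers.append((pos + 1, pos + n))
        pos += n

    hom = rng.random(spec.n_orfs) < spec.homolog_fraction
    hom[0] = True  # the anchor must be identifiable by homology
    for i in range(spec.n_orfs):
        body = bodies[i]
        strand = str(strands[i])
        if i == 0:
            # anchor cassette opens the genome: ORF body first, guard stop
            # is appended at the very end of the circle
            parts.append(body)
            truth.orfs.append(
                PlantedOrf(1, GenomeInterval(1, len(body), "+"), body, True)
            )
            pos += len(body)
        else:
            cassette = "TAA" + body
            if strand == "-":
                cassette = revcomp(cassette)
                iv = GenomeInterval(pos + 1, pos + len(body), "-")
            else:
                iv = GenomeInterval(pos + 4, pos + 3 + len(body), "+")
            parts.append(cassette)
            truth.orfs.append(PlantedOrf(i + 1, iv, body, bool(hom[i])))
            pos += len(cassette)
        add_spacer()
        if i in hr_after:
            pals, gaps = hr_plans[hr_after[i]]
            pal_ivs = []
            for k, pal in enumerate(pals):
                parts.append(pal)
                pal_ivs.append(GenomeInterval(pos + 1, pos + len(pal)))
                pos += len(pal)
                if k < len(gaps):
                    seg = _random_background(gaps[k], spec.gc, rng)
                    parts.append(seg)
                    pos += gaps[k]
            truth.hrs.append(
                PlantedHr(
                    f"hr{hr_after[i] + 1}",
                    GenomeInterval(pal_ivs[0].start, pal_ivs[-1].end),
                    pal_ivs,
                )
            )
            add_spacer()
    parts.append("TAA")  # in-frame guard stop just upstream of the anchor ATG
    pos += 3
    seq = "".join(parts)
    assert len(seq) == spec.genome_length, (len(seq), spec.genome_length)
    genome = CircularGenome(f"synthetic_gv_seed{seed}", seq)

    # plant homopolymer tracts for slippage events inside covered spacers
    intervals = list(spec.contig_intervals or ())
    if spec.slippage_count and intervals:
        planted = 0
        seq_list = list(seq)
        for s, e in truth.spacers:
            if planted >= spec.slippage_count:
                break
            inside = any(cs + 50 <= s and e <= ce - 50 for cs, ce in intervals)
            if not inside or e - s + 1 < 16:
                continue
            mid = (s + e) // 2 - 5
            tract = "C" + "A" * 8 + "G"
            seq_list[mid - 1 : mid - 1 + len(tract)] = tract
            truth.slippage_runs.append(("A", mid + 1, 8))
            planted += 1
        genome = CircularGenome(genome.id, "".join(seq_list))
    truth.contig_intervals = [tuple(iv) for iv in intervals]
    return genome, truth


# ---------------------------------------------------------------------------
# proteome


_AA20 = list(_AA_ORDER)


def _mutate_protein(aa: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(aa)
    hits = np.nonzero(rng.random(len(out)) < divergence)[0]
    for i in hits:
        choices = [a for a in _AA20 if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def generate_proteome(
    truth: TruthSet, divergence: float, seed: int = 0, n_decoys: int = 20
) -> list[tuple[str, str]]:
    """Reference proteins: diverged copies of planted ORFs plus decoys.

    The anchor ORF's homologue is kept highly conserved (one fifth of the
    requested divergence, emulating granulin) and named ``granulin_ref``.
    Decoy entries are random sequences carrying no planted label.
    """
    rng = np.random.default_rng(seed + 101)
    db: list[tuple[str, str]] = []
    for orf in truth.orfs:
        if not orf.has_homolog:
            continue
        div = divergence * 0.2 if orf.index == 1 else divergence
        name = "granulin_ref" if orf.index == 1 else f"ref_{orf.index:03d}"
        db.append((name, _mutate_protein(orf.aa, div, rng)))
    for d in range(n_decoys):
        length = int(rng.integers(80, 400))
        seq = "".join(_AA20[k] for k in rng.integers(0, 20, size=length))
        db.append((f"decoy_{d:03d}", seq))
    order = rng.permutation(len(db))
    return [db[i] for i in order]


# ---------------------------------------------------------------------------
# transcriptome contigs with planted variants


def _orf_at(truth: TruthSet, pos: int) -> PlantedOrf | None:
    for orf in truth.orfs:
        if orf.interval.start <= pos <= orf.interval.end:
            return orf
    return None


def _substitution_effect(orf: PlantedOrf, pos: int, alt_fwd: str) -> str:
    iv = orf.interval
    off = pos - iv.start if iv.strand == "+" else iv.end - pos
    codon_i = off // 3
    codon = orf.body[codon_i * 3 : codon_i * 3 + 3]
    within = off % 3
    alt = alt_fwd if iv.strand == "+" else revcomp(alt_fwd)
    new = codon[:within] + alt + codon[within + 1 :]
    return "synonymous" if str(Seq(codon).translate()) == str(Seq(new).translate()) else "nonsynonymous"


def mutate_to_contigs(
    genome: CircularGenome, spec: SyntheticSpec, truth: TruthSet, seed: int = 0
) -> list[tuple[str, str]]:
    """Extract contigs from the planned intervals and plant variants.

    Substitutions and indels are planted at the spec rates with spacing
    constraints that keep each event unambiguous under edit-distance
    alignment; truth records (genome-anchored, left-normalized, with
    effects) are appended to ``truth.variants``.  Odd-numbered contigs are
    emitted reverse-complemented; one chimera contig S + revcomp(S) is
    appended when requested.
    """
    rng = np.random.default_rng(seed + 202)
    intervals = truth.contig_intervals
    if not intervals:
        raise ValueError("spec defines no contig intervals")
    gseq = genome.seq
    contigs: list[tuple[str, str]] = []
    edits_by_iv: list[list[tuple[int, str, str]]] = []
    blocked: list[tuple[int, int]] = [
        (s - 20, s + 20) for _, s, _ in truth.slippage_runs
    ]

    def free(pos: int, margin: int = 15) -> bool:
        return not any(lo - margin <= pos <= hi + margin for lo, hi in blocked)

    def block(lo: int, hi: int):
        blocked.append((lo, hi))

    frameshift_left = 1 if spec.indel_rate > 0 else 0
    for ci, (cs, ce) in enumerate(intervals):
        length = ce - cs + 1
        edits: list[tuple[int, str, str]] = []  # (genome pos, kind, payload)
        n_sub = int(round(length * spec.substitution_rate))
        n_ind = int(round(length * spec.indel_rate))
        # --- indels first (they claim more space)
        placed = 0
        attempts = 0
        while placed < n_ind and attempts < 200 * (n_ind + 1):
            attempts += 1
            pos = int(rng.integers(cs + 60, ce - 90))
            orf = _orf_at(truth, pos)
            if orf is not None and not (
                orf.interval.start + 6 <= pos <= orf.interval.end - 40
            ):
                continue
            if not free(pos, margin=40):
                continue
            kind = "deletion" if rng.random() < 0.6 else "insertion"
            if orf is not None:
                if frameshift_left > 0:
                    ln = 1
                else:
                    ln = int(rng.choice([3, 6, 9, 12]))
            else:
                ln = int(rng.choice([1, 2, 3, 5, 8]))
            if kind == "deletion":
                npos, allele = left_normalize_deletion(gseq, pos, ln)
                if npos != pos:  # keep planted events un-shiftable
                    continue
                if gseq[pos + ln - 1] == allele[-1] or gseq[pos - 1] == gseq[pos - 2]:
                    continue
                v = VariantRecord("deletion", pos, pos + ln - 1, allele, "")
            else:
                allele = _random_background(ln, 0.5, rng)
                if allele[-1] == gseq[pos - 1] or allele[0] == gseq[pos]:
                    continue
                npos, nallele = left_normalize_insertion(gseq, pos, allele)
                if npos != pos:
                    continue
                v = VariantRecord("insertion", pos, pos, "", allele)
            ctx = _homopolymer_context(gseq, v.kind, v.position, allele)
            if orf is not None:
                effect = "in-frame" if ln % 3 == 0 else "frameshift"
                if effect == "frameshift":
                    if frameshift_left <= 0:
                        continue
                    frameshift_left -= 1
                off = (pos - orf.interval.start if orf.interval.strand == "+"
                       else orf.interval.end - pos)
                v = VariantRecord(v.kind, v.position, v.end, v.ref, v.alt,
                                  region=f"ORF{orf.index}", effect=effect,
                                  codon_index=off // 3 + 1, homopolymer_context=ctx)
            else:
                v = VariantRecord(v.kind, v.position, v.end, v.ref, v.alt,
                                  region="intergenic", effect="intergenic",
                                  homopolymer_context=ctx)
            truth.variants.append(v)
            edits.append((pos, v.kind, allele))
            block(pos - 5, v.end + 5)
            placed += 1
        # --- substitutions
        placed = 0
        attempts = 0
        while placed < n_sub and attempts < 200 * (n_sub + 1):
            attempts += 1
            pos = int(rng.integers(cs + 50, ce - 50 + 1))
            if not free(pos):
                continue
            ref = gseq[pos - 1]
            if ref not in "ACGT":
                continue
            orf = _orf_at(truth, pos)
            if orf is not None and not (
                orf.interval.start + 3 <= pos <= orf.interval.end - 3
            ):
                continue
            alt = "ACGT"[rng.integers(0, 4)]
            while alt == ref:
                alt = "ACGT"[rng.integers(0, 4)]
            if orf is not None:
                region, effect = f"ORF{orf.index}", _substitution_effect(orf, pos, alt)
            else:
                hr = next((h for h in truth.hrs if h.span.start <= pos <= h.span.end), None)
                region, effect = (hr.name if hr else "intergenic"), "intergenic"
            truth.variants.append(
                VariantRecord("substitution", pos, pos, ref, alt, region=region, effect=effect)
            )
            edits.append((pos, "substitution", alt))
            block(pos, pos)
            placed += 1
        edits_by_iv.append(edits)

    # slippage insertions at the planted homopolymer tracts
    for base, start, run in truth.slippage_runs[: spec.slippage_count]:
        pos, allele = left_normalize_insertion(gseq, start + run - 1, base)
        truth.variants.append(
            VariantRecord(
                "insertion", pos, pos, "", allele,
                region="intergenic", effect="intergenic",
                homopolymer_context=(base, run, run + 1),
            )
        )
        for i, (cs, ce) in enumerate(intervals):
            if cs <= start <= ce:
                edits_by_iv[i].append((start + run - 1, "insertion", allele))
                break

    for ci, ((cs, ce), edits) in enumerate(zip(intervals, edits_by_iv)):
        s = list(gseq[cs - 1 : ce])
        for pos, kind, payload in sorted(edits, reverse=True):
            rel = pos - cs  # 0-based index into s
            if kind == "substitution":
                s[rel] = payload
            elif kind == "deletion":
                del s[rel : rel + len(payload)]
            else:  # insertion after pos
                s[rel + 1 : rel + 1] = list(payload)
        contig = "".join(s)
        if ci % 2 == 1:
            contig = revcomp(contig)
        contigs.append((f"contig_{ci + 1:02d}", contig))

    if spec.chimera_count and intervals:
        cs, ce = max(intervals, key=lambda iv: iv[1] - iv[0])
        mid = (cs + ce) // 2
        half = min(2500, (ce - cs) // 3)
        s_seq = gseq[mid - half : mid]
        chimera = s_seq + revcomp(s_seq)
        cid = "contig_chimera"
        contigs.append((cid, chimera))
        truth.chimera_junctions[cid] = len(s_seq)

    truth.variants.sort(key=lambda v: v.position)
    return contigs


def truth_annotation(genome: CircularGenome, truth: TruthSet):
    """AnnotatedGenome built directly from the planted truth.

    Useful for exercising variant classification against known gene
    structure, independent of the annotator's own false-positive rate.
    """
    from .hrs import HrRegion
    from .orfs import AnnotatedGenome, OrfRecord

    orfs = []
    for p in truth.orfs:
        rec = OrfRecord(p.interval, len(p.body) // 3 - 1, seq=p.body, number=p.index)
        orfs.append(rec)
    hrs = [HrRegion(h.name, h.span, []) for h in truth.hrs]
    return AnnotatedGenome(genome, orfs, hrs)


def generate_study(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[CircularGenome, TruthSet, list[tuple[str, str]], list[tuple[str, str]]]:
    """One-call bundle: genome, truth, reference proteome, contigs."""
    genome, truth = generate_genome(spec, seed)
    proteome = generate_proteome(truth, spec.proteome_divergence, seed, spec.n_decoys)
    contigs = mutate_to_contigs(genome, spec, truth, seed)
    return genome, truth, proteome, contigs
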