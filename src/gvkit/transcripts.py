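"""Transcriptome-contig mapping, variant calling and classification.

Assembled transcriptome contigs are mapped back onto the consensus genome
(edit-distance infix alignment via edlib; contigs that do not align as one
piece are bisected recursively, which also resolves chimeric contigs whose
halves map to opposite strands of the same locus — a classic assembly
artifact of inverted-duplication contigs).  Differences between a mapped
contig and the genome become variant records: substitutions, insertions
and deletions, with indels left-aligned inside homopolymer runs and
reported "inserted after position X" in the style of published variant
tables (e.g. ``(A) inserted after 12508 (8A->9A)``).

Classification is strand-aware against an ORF annotation: substitutions in
ORFs are synonymous or nonsynonymous by codon lookup under the standard
genetic code; ORF indels are in-frame iff their length is a multiple of
three, otherwise frameshift (with the affected codon index); everything
else is intergenic (hr spans are tracked but summarized with intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import edlib
from Bio.Seq import Seq

from .genome import (
    CircularGenome,
    GenomeInterval,
    interval_union_length,
    revcomp,
    round_half_away,
)
from .orfs import AnnotatedGenome, OrfRecord

__all__ = [
    "ContigAlignment",
    "VariantRecord",
    "ComparisonSummary",
    "map_contigs",
    "detect_inversion_artifact",
    "call_variants",
    "classify_variant",
    "summarize_comparison",
    "load_table1_fixture",
    "write_vcf",
    "compare_transcriptome",
]


@dataclass
class ContigAlignment:
    contig_id: str
    contig_span: tuple[int, int]  # 1-based inclusive in the contig
    genome_interval: GenomeInterval
    identity: float  # percent
    aligned_contig: str = ""  # gapped, genome-forward orientation
    aligned_genome: str = ""


@dataclass
class VariantRecord:
    kind: str  # substitution | insertion | deletion
    position: int  # 1-based; insertions are anchored after this position
    end: int  # = position for substitutions/insertions
    ref: str
    alt: str
    region: str = ""  # "ORF<n>" | "intergenic" | "hr<n>"
    effect: str = ""  # synonymous | nonsynonymous | intergenic | in-frame | frameshift | no-aa-impact
    codon_index: int | None = None  # 1-based affected codon for ORF variants
    minority: bool = False
    homopolymer_context: tuple[str, int, int] | None = None  # (base, run_before, run_after)

    @property
    def length(self) -> int:
        if self.kind == "substitution":
            return 1
        return len(self.alt) if self.kind == "insertion" else self.end - self.position + 1


@dataclass
class ComparisonSummary:
    aligned_intervals: list[GenomeInterval]
    aligned_bp: int
    genome_fraction_pct: float
    substitutions: dict[str, int]  # synonymous / nonsynonymous / intergenic
    substitutions_total: int
    indels_total: int
    indels_intergenic: int
    indels_in_orfs: int
    orf_indels_in_frame: int
    orf_indels_frameshift: int
    substitutions_per_kbp: float


# ---------------------------------------------------------------------------
# mapping


def _align_piece(piece: str, genome_seq: str) -> tuple[float, str, str, str, tuple[int, int]]:
    """Best infix alignment of a contig piece against either strand.

    Returns (identity_fraction, strand, gapped_piece, gapped_genome,
    (genome_start0, genome_end0)); the piece is reverse-complemented for
    minus-strand placements so rows are always genome-forward.
    """
    best = None
    for strand, q in (("+", piece), ("-", revcomp(piece))):
        res = edlib.align(q, genome_seq, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        nice = edlib.getNiceAlignment(res, q, genome_seq)
        aq, ag = nice["query_aligned"], nice["target_aligned"]
        matches = sum(1 for a, b in zip(aq, ag) if a == b)
        ident = matches / len(aq)
        cand = (ident, strand, aq, ag, (loc[0], loc[1]))
        if best is None or cand[0] > best[0]:
            best = cand
    assert best is not None
    return best


def map_contigs(
    contigs: Sequence[tuple[str, str]],
    genome: CircularGenome,
    min_identity: float = 0.80,
    min_length: int = 100,
) -> list[ContigAlignment]:
    """Map each contig onto the genome, splitting where one placement fails.

    A contig (or piece) is accepted when its best whole-piece placement on
    either strand reaches ``min_identity``; otherwise it is bisected and
    the halves mapped independently (pieces shorter than ``min_length`` are
    discarded).  Chimeric inverted-duplication contigs therefore yield two
    segments on opposite strands.
    """
    out: list[ContigAlignment] = []

    def place(cid: str, piece: str, offset: int) -> None:
        if len(piece) < min_length:
            return
        ident, strand, aq, ag, (g0, g1) = _align_piece(piece, genome.seq)
        if ident >= min_identity:
            iv = GenomeInterval(g0 + 1, g1 + 1, strand)
            out.append(
                ContigAlignment(
                    cid,
                    (offset + 1, offset + len(piece)),
                    iv,
                    100.0 * ident,
                    aq,
                    ag,
                )
            )
            return
        mid = len(piece) // 2
        if mid < min_length or len(piece) - mid < min_length:
            return
        place(cid, piece[:mid], offset)
        place(cid, piece[mid:], offset + mid)

    for cid, seq in contigs:
        place(cid, seq, 0)
    out.sort(key=lambda a: (a.contig_id, a.contig_span))
    return out


def detect_inversion_artifact(
    contig_id: str, alignments: Sequence[ContigAlignment], min_reciprocal_overlap: float = 0.90
) -> tuple[bool, int | None]:
    """Flag contigs whose segments map to the same locus on opposite strands.

    Returns (flag, junction) where the junction is the contig coordinate at
    the boundary between the two inverted copies.
    """
    segs = [a for a in alignments if a.contig_id == contig_id]
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            if a.genome_interval.strand == b.genome_interval.strand:
                continue
            s = max(a.genome_interval.start, b.genome_interval.start)
            e = min(a.genome_interval.end, b.genome_interval.end)
            ov = max(0, e - s + 1)
            la = a.genome_interval.end - a.genome_interval.start + 1
            lb = b.genome_interval.end - b.genome_interval.start + 1
            if ov / la >= min_reciprocal_overlap and ov / lb >= min_reciprocal_overlap:
                first = a if a.contig_span < b.contig_span else b
                return True, first.contig_span[1]
    return False, None


# ---------------------------------------------------------------------------
# variant calling


def left_normalize_insertion(genome_seq: str, pos: int, allele: str) -> tuple[int, str]:
    """Leftmost equivalent representation of an insertion anchored after ``pos``."""
    while pos >= 1 and genome_seq[pos - 1] == allele[-1]:
        allele = allele[-1] + allele[:-1]
        pos -= 1
    return pos, allele


def left_normalize_deletion(genome_seq: str, pos: int, length: int) -> tuple[int, str]:
    """Leftmost equivalent representation of a deletion starting at ``pos``."""
    allele = genome_seq[pos - 1 : pos - 1 + length]
    while pos > 1 and genome_seq[pos - 2] == allele[-1]:
        pos -= 1
        allele = genome_seq[pos - 1 : pos - 1 + length]
    return pos, allele


def _homopolymer_context(
    genome_seq: str, kind: str, pos: int, allele: str
) -> tuple[str, int, int] | None:
    """Reference run context (base, run_before, run_after) for runs >= 4."""
    if not allele or len(set(allele)) != 1:
        return None
    base = allele[0]
    first = pos if kind == "deletion" else pos + 1  # first run position
    if first > len(genome_seq) or genome_seq[first - 1] != base:
        return None
    lo = first
    while lo > 1 and genome_seq[lo - 2] == base:
        lo -= 1
    hi = first
    while hi < len(genome_seq) and genome_seq[hi] == base:
        hi += 1
    run_before = hi - lo + 1
    if run_before < 4:
        return None
    run_after = run_before + (len(allele) if kind == "insertion" else -len(allele))
    return (base, run_before, run_after)


def _polish_alignment(aq: str, ag: str) -> tuple[str, str]:
    """Re-align gap clusters with affine penalties so indels stay contiguous.

    Unit-cost (edit-distance) alignment may split one indel into pieces
    separated by coincidentally matching bases; windows around clustered
    gap columns are re-aligned with gap-open scoring and spliced back.
    """
    from .align import PRESETS, pairwise_align

    ncol = len(aq)
    gap_cols = [i for i in range(ncol) if aq[i] == "-" or ag[i] == "-"]
    if len(gap_cols) < 2:
        return aq, ag
    clusters: list[list[int]] = [[gap_cols[0]]]
    for c in gap_cols[1:]:
        if c - clusters[-1][-1] <= 8:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    out_q, out_g = list(aq), list(ag)
    for cl in reversed(clusters):  # right-to-left keeps earlier indices valid
        runs = sum(
            1 for k, c in enumerate(cl) if k == 0 or c != cl[k - 1] + 1
        )
        if runs < 2:
            continue
        lo = max(cl[0] - 12, 0)
        hi = min(cl[-1] + 12, ncol - 1)
        qsub = "".join(out_q[lo : hi + 1]).replace("-", "")
        gsub = "".join(out_g[lo : hi + 1]).replace("-", "")
        if not qsub or not gsub:
            continue
        aln = pairwise_align(qsub, gsub, PRESETS["dna"].with_mode("global"))
        out_q[lo : hi + 1] = list(aln.aligned_query)
        out_g[lo : hi + 1] = list(aln.aligned_target)
    return "".join(out_q), "".join(out_g)


def call_variants(alignment: ContigAlignment, genome: CircularGenome) -> list[VariantRecord]:
    """Substitutions and (merged, left-aligned) indels from one alignment."""
    aq, ag = alignment.aligned_contig, alignment.aligned_genome
    if not aq:
        raise ValueError("alignment carries no detail rows")
    aq, ag = _polish_alignment(aq, ag)
    gpos = alignment.genome_interval.start - 1  # last consumed genome position
    out: list[VariantRecord] = []
    i = 0
    ncol = len(aq)
    while i < ncol:
        qc, gc = aq[i], ag[i]
        if gc == "-":  # insertion relative to the genome
            j = i
            ins = []
            while j < ncol and ag[j] == "-":
                ins.append(aq[j])
                j += 1
            pos, allele = left_normalize_insertion(genome.seq, gpos, "".join(ins))
            out.append(
                VariantRecord(
                    "insertion",
                    pos,
                    pos,
                    "",
                    allele,
                    homopolymer_context=_homopolymer_context(genome.seq, "insertion", pos, allele),
                )
            )
            i = j
        elif qc == "-":  # deletion relative to the genome
            j = i
            ndel = 0
            while j < ncol and aq[j] == "-":
                ndel += 1
                j += 1
            start, allele = left_normalize_deletion(genome.seq, gpos + 1, ndel)
            out.append(
                VariantRecord(
                    "deletion",
                    start,
                    start + ndel - 1,
                    allele,
                    "",
                    homopolymer_context=_homopolymer_context(genome.seq, "deletion", start, allele),
                )
            )
            gpos += ndel
            i = j
        else:
            gpos += 1
            if qc != gc:
                out.append(VariantRecord("substitution", gpos, gpos, gc, qc))
            i += 1
    return out


# ---------------------------------------------------------------------------
# classification


def _orf_offset(orf: OrfRecord, pos: int, genome_length: int) -> int | None:
    """0-based offset of genome position ``pos`` within the ORF reading frame."""
    positions: list[int] = []
    for s, e in orf.interval.segments(genome_length):
        positions.extend(range(s, e + 1))
    if orf.interval.strand == "-":
        positions.reverse()
    try:
        return positions.index(pos)
    except ValueError:
        return None


def classify_variant(
    v: VariantRecord, annotation: AnnotatedGenome
) -> VariantRecord:
    """Attach region and effect to a variant given an ORF (+hr) annotation."""
    genome = annotation.genome
    n = genome.length
    if not 1 <= v.position <= n or not 1 <= v.end <= n:
        raise ValueError(f"variant at {v.position} outside genome of {n} bp")
    probe = v.position if v.kind != "insertion" else v.position  # anchor base
    host: OrfRecord | None = None
    best_ov = 0
    for orf in annotation.orfs:
        off = _orf_offset(orf, probe, n)
        if off is None:
            continue
        ov = orf.interval.length(n)
        if host is None or ov > best_ov:
            host, best_ov = orf, ov
    if host is None:
        region = "intergenic"
        for hr in annotation.hrs:
            if hr.span.start <= v.position <= hr.span.end:
                region = hr.name
                break
        return replace(v, region=region, effect="intergenic")
    region = f"ORF{host.number}" if host.number is not None else "ORF?"
    if v.kind == "substitution":
        off = _orf_offset(host, v.position, n)
        codon_i = off // 3
        codon = host.seq[codon_i * 3 : codon_i * 3 + 3]
        within = off % 3
        alt_base = v.alt if host.strand == "+" else revcomp(v.alt)
        new_codon = codon[:within] + alt_base + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(new_codon).translate())
        effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
        return replace(v, region=region, effect=effect, codon_index=codon_i + 1)
    # indel
    off = _orf_offset(host, v.position, n)
    if off is None:  # insertion anchored just upstream of a minus-strand ORF end
        off = _orf_offset(host, min(v.position + 1, n), n) or 0
    codon_i = off // 3 + 1
    if v.length % 3 == 0:
        return replace(v, region=region, effect="in-frame", codon_index=codon_i)
    return replace(v, region=region, effect="frameshift", codon_index=codon_i)


# ---------------------------------------------------------------------------
# summary


_INTERGENIC_EFFECTS = {"intergenic"}
_ORF_INFRAME_EFFECTS = {"in-frame", "no-aa-impact"}


def summarize_comparison(
    variants: Sequence[VariantRecord],
    alignments: Sequence[ContigAlignment] | Sequence[GenomeInterval],
    genome_length: int,
) -> ComparisonSummary:
    """Coverage, per-class counts and the substitution rate per aligned kbp.

    The rate denominator is the union of aligned bases (in kbp); counts are
    conservative: every class tally sums to the corresponding total.
    Indels in hr regions are summarized with the intergenic class.
    """
    intervals = [
        a.genome_interval if isinstance(a, ContigAlignment) else a for a in alignments
    ]
    covered = interval_union_length(intervals, genome_length)
    subs = [v for v in variants if v.kind == "substitution"]
    indels = [v for v in variants if v.kind != "substitution"]
    sub_counts = {"synonymous": 0, "nonsynonymous": 0, "intergenic": 0}
    for v in subs:
        key = v.effect if v.effect in sub_counts else "intergenic"
        sub_counts[key] += 1
    in_orf = [v for v in indels if v.region.startswith("ORF")]
    inter = [v for v in indels if not v.region.startswith("ORF")]
    in_frame = sum(1 for v in in_orf if v.effect in _ORF_INFRAME_EFFECTS)
    frameshift = sum(1 for v in in_orf if v.effect == "frameshift")
    rate = len(subs) / (covered / 1000.0) if covered else 0.0
    return ComparisonSummary(
        aligned_intervals=intervals,
        aligned_bp=covered,
        genome_fraction_pct=round_half_away(100.0 * covered / genome_length, 1),
        substitutions=sub_counts,
        substitutions_total=len(subs),
        indels_total=len(indels),
        indels_intergenic=len(inter),
        indels_in_orfs=len(in_orf),
        orf_indels_in_frame=in_frame,
        orf_indels_frameshift=frameshift,
        substitutions_per_kbp=round_half_away(rate, 1),
    )


# ---------------------------------------------------------------------------
# shipped variant-table fixture


def load_table1_fixture(path=None) -> list[VariantRecord]:
    """Load the shipped genome-vs-transcriptome variant table (TSV).

    One record per substitution or indel, with region, effect, minority-read
    flag and homopolymer context where annotated.  Malformed rows raise a
    ValueError naming the line number.
    """
    if path is None:
        from importlib.resources import files

        path = files("gvkit.data") / "pigv_table1_variants.tsv"
    records = []
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["kind", "position", "end", "ref", "alt", "region", "effect", "codon", "minority", "context"]
        if header != expected:
            raise ValueError(f"unexpected fixture header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(expected):
                raise ValueError(f"line {lineno}: expected {len(expected)} columns, got {len(cols)}")
            kind, pos, end, ref, alt, region, effect, codon, minority, context = cols
            try:
                position, endpos = int(pos), int(end)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: bad coordinates {pos!r}/{end!r}") from exc
            if kind not in {"substitution", "insertion", "deletion"}:
                raise ValueError(f"line {lineno}: unknown kind {kind!r}")
            ctx = None
            if context and context != ".":
                base, runs = context.split(":")
                before, after = runs.split(">")
                ctx = (base, int(before), int(after))
            records.append(
                VariantRecord(
                    kind,
                    position,
                    endpos,
                    "" if ref == "." else ref,
                    "" if alt == "." else alt,
                    region,
                    effect,
                    codon_index=None if codon == "." else int(codon),
                    minority=minority == "1",
                    homopolymer_context=ctx,
                )
            )
    return records


def write_vcf(path, genome_id: str, genome_length: int, variants: Sequence[VariantRecord], genome: CircularGenome | None = None) -> None:
    """Minimal single-sample VCF export (effect and region in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome_id},length={genome_length}>\n")
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Variant effect">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda x: x.position):
            if v.kind == "substitution":
                pos, ref, alt = v.position, v.ref or "N", v.alt or "N"
            elif v.kind == "insertion":
                anchor = genome.base(v.position) if genome else "N"
                pos, ref, alt = v.position, anchor, anchor + v.alt
            else:
                prev = genome.base(v.position - 1) if genome and v.position > 1 else "N"
                ref_allele = v.ref or (genome.fetch(v.position, v.end) if genome else "N" * v.length)
                pos, ref, alt = max(v.position - 1, 1), prev + ref_allele, prev
            info = f"EFFECT={v.effect or '.'};REGION={v.region or '.'}"
            fh.write(f"{genome_id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def compare_transcriptome(
    contigs: Sequence[tuple[str, str]],
    annotation: AnnotatedGenome,
    min_identity: float = 0.80,
    min_length: int = 100,
) -> tuple[list[ContigAlignment], list[VariantRecord], ComparisonSummary, dict[str, int]]:
    """Map contigs, drop inverted-duplication artifacts, call and classify.

    Returns (alignments, classified variants, summary, chimera junctions by
    contig id).  For flagged chimeric contigs only the first segment
    contributes to variant calling and coverage, so the duplicated copy is
    not double-counted.
    """
    genome = annotation.genome
    alignments = map_contigs(contigs, genome, min_identity, min_length)
    chimeras: dict[str, int] = {}
    keep: list[ContigAlignment] = []
    seen_chimera_primary: set[str] = set()
    for aln in alignments:
        flag, junction = detect_inversion_artifact(aln.contig_id, alignments)
        if flag:
            chimeras[aln.contig_id] = junction
            if aln.contig_id in seen_chimera_primary:
                continue
            seen_chimera_primary.add(aln.contig_id)
        keep.append(aln)
    variants: list[VariantRecord] = []
    for aln in keep:
        for v in call_variants(aln, genome):
            variants.append(classify_variant(v, annotation))
    variants.sort(key=lambda v: v.position)
    summary = summarize_comparison(variants, keep, genome.length)
    return keep, variants, summary, chimeras
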