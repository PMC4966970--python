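"""Sequences, circular coordinates, and interval arithmetic.

Granulovirus genomes are circular double-stranded DNA molecules of roughly
80-180 kbp.  By convention the adenine of the granulin start codon is
position 1 and the granulin ORF reads on the plus strand, so every other
annotation is expressed relative to that rotation.  All coordinates in this
package are 1-based and inclusive, matching the style used in published
annotation tables (``5169→5594`` for a plus-strand feature, ``8421←10262``
for a minus-strand one).  Features that cross the origin of the circle are
represented with ``wraps_origin=True`` rather than with coordinates beyond
the genome length, which keeps interval invariants checkable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "GenomeInterval",
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "gc_content",
    "rotate_to_anchor",
    "interval_union_length",
    "find_homopolymers",
    "write_gff3",
    "read_gff3",
    "write_tsv",
    "round_half_away",
]

_DNA_OK = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files or sequences."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (reporting convention for all printed numbers)."""
    import decimal

    d = decimal.Decimal(repr(x)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        bad = set(self.seq) - _DNA_OK
        if bad:
            raise FormatError(f"non-IUPAC/unsupported characters in genome: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """1-based base access with circular wrap."""
        return self.seq[(pos - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; wraps the origin when start > end."""
        if start <= end:
            return self.seq[start - 1 : end]
        return self.seq[start - 1 :] + self.seq[:end]

    def reverse_complement(self) -> "CircularGenome":
        return replace(self, seq=revcomp(self.seq))


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive span on a circular genome.

    ``wraps_origin`` marks features crossing the origin; for those,
    ``start > end`` is permitted and the length runs through position 1.
    """

    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based positive")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError("start > end requires wraps_origin")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("genome_length required for origin-wrapping interval")
        return genome_length - self.start + 1 + self.end

    def segments(self, genome_length: int | None = None) -> list[tuple[int, int]]:
        """Linear (start, end) pieces covering the interval."""
        if not self.wraps_origin:
            return [(self.start, self.end)]
        if genome_length is None:
            raise ValueError("genome_length required for origin-wrapping interval")
        return [(self.start, genome_length), (1, self.end)]

    def extract(self, genome: CircularGenome) -> str:
        """Feature sequence in reading orientation."""
        s = genome.fetch(self.start, self.end)
        return s if self.strand == "+" else revcomp(s)


def read_fasta(path, alphabet: str = "dna") -> list[FastaRecord]:
    """Read a FASTA file; DNA records are uppercased with U mapped to T.

    Raises :class:`FormatError` on an empty file or (for DNA) characters
    outside {A,C,G,T,N,U}.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
            bad = set(seq) - _DNA_OK
            if bad:
                raise FormatError(
                    f"record {rec.id!r}: unsupported characters {sorted(bad)}"
                )
        records.append(FastaRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str] | FastaRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, FastaRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from both numerator and denominator."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def rotate_to_anchor(
    genome: CircularGenome, anchor_pos: int, anchor_strand: str = "+"
) -> tuple[CircularGenome, Callable[[int, str], tuple[int, str]]]:
    """Rotate (and possibly flip) the genome so the anchor base is position 1.

    When ``anchor_strand`` is ``-`` the genome is reverse-complemented first,
    so that a minus-strand anchor ORF reads on the plus strand of the result.
    Returns the rotated genome and a remapping function
    ``remap(pos, strand) -> (new_pos, new_strand)``.
    """
    n = genome.length
    if not 1 <= anchor_pos <= n:
        raise ValueError(f"anchor position {anchor_pos} out of range 1..{n}")
    if anchor_strand == "+":
        k = anchor_pos - 1
        new_seq = genome.seq[k:] + genome.seq[:k]

        def remap(pos: int, strand: str = "+") -> tuple[int, str]:
            return ((pos - anchor_pos) % n) + 1, strand

    elif anchor_strand == "-":
        rc = revcomp(genome.seq)
        # position p maps to n+1-p on the flipped sequence
        k = (n - anchor_pos) % n
        new_seq = rc[k:] + rc[:k]

        def remap(pos: int, strand: str = "+") -> tuple[int, str]:
            flipped = n + 1 - pos
            return ((flipped - (n + 1 - anchor_pos)) % n) + 1, ("-" if strand == "+" else "+")

    else:
        raise ValueError("anchor_strand must be + or -")
    return replace(genome, seq=new_seq), remap


def remap_interval(
    iv: GenomeInterval, remap: Callable[[int, str], tuple[int, str]], genome_length: int
) -> GenomeInterval:
    """Apply a coordinate remapping to a whole interval, preserving reading frame."""
    length = iv.length(genome_length)
    if iv.strand == "+":
        first, last = iv.start, iv.end
    else:
        first, last = iv.end, iv.start
    nf, ns = remap(first, iv.strand)
    nl, _ = remap(last, iv.strand)
    if ns == "+":
        start, end = nf, nl
    else:
        start, end = nl, nf
    wraps = ((end - start) % genome_length) + 1 != length or (start > end)
    # normalize: wraps only when the linear span does not fit
    wraps = start > end
    if not wraps and end - start + 1 != length:
        raise AssertionError("interval remapping lost length")
    return GenomeInterval(start, end, ns, wraps_origin=wraps)


def interval_union_length(
    intervals: Sequence[GenomeInterval], genome_length: int | None = None
) -> int:
    """Total bases covered by a union of inclusive intervals (overlaps once)."""
    pieces: list[tuple[int, int]] = []
    for iv in intervals:
        pieces.extend(iv.segments(genome_length))
    if not pieces:
        return 0
    pieces.sort()
    total = 0
    cur_s, cur_e = pieces[0]
    for s, e in pieces[1:]:
        if s <= cur_e + 1 and e > cur_e:
            cur_e = e
        elif s > cur_e:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def find_homopolymers(seq: str, min_run: int) -> list[tuple[str, int, int]]:
    """Maximal single-base runs of length >= min_run as (base, start, run_length)."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    out = []
    pos = 1
    for base, group in itertools.groupby(seq):
        n = sum(1 for _ in group)
        if n >= min_run and base in "ACGT":
            out.append((base, pos, n))
        pos += n
    return out


# ---------------------------------------------------------------------------
# annotation export

def _gff3_feature_lines(seqid, source, ftype, iv: GenomeInterval, fid, attrs, genome_length):
    parts = iv.segments(genome_length) if iv.wraps_origin else [(iv.start, iv.end)]
    attr_str = ";".join([f"ID={fid}"] + [f"{k}={v}" for k, v in attrs.items()])
    for s, e in parts:
        yield "\t".join(
            [seqid, source, ftype, str(s), str(e), ".", iv.strand, ".", attr_str]
        )


def write_gff3(path, seqid: str, features, genome_length: int, source: str = "gvkit") -> None:
    """Write features as GFF3 (1-based inclusive, same convention as internal).

    ``features`` is an iterable of (type, GenomeInterval, id, attr-dict).
    Origin-spanning features are emitted as two lines sharing one ID.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {genome_length}\n")
        for ftype, iv, fid, attrs in features:
            for line in _gff3_feature_lines(seqid, source, ftype, iv, fid, attrs, genome_length):
                fh.write(line + "\n")


def read_gff3(path) -> list[tuple[str, GenomeInterval, str, dict]]:
    """Read back features written by :func:`write_gff3` (two-part wraps re-joined)."""
    raw: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            fid = attrs.pop("ID")
            entry = (cols[2], int(cols[3]), int(cols[4]), cols[6], attrs)
            if fid not in raw:
                raw[fid] = []
                order.append(fid)
            raw[fid].append(entry)
    out = []
    for fid in order:
        parts = raw[fid]
        ftype, _, _, strand, attrs = parts[0]
        if len(parts) == 1:
            iv = GenomeInterval(parts[0][1], parts[0][2], strand)
        else:
            (_, s1, e1, _, _), (_, s2, e2, _, _) = sorted(parts, key=lambda p: p[1])
            # two-part origin-spanning feature: (s2..end]+(1..e1]
            iv = GenomeInterval(s2, e1, strand, wraps_origin=True)
        out.append((ftype, iv, fid, attrs))
    return out


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
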