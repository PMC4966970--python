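"""Homologous repeat region (hr) detection.

Granulovirus genomes carry several *homologous regions*: clusters of one to
three imperfect palindromes, tens of bp long, whose ends carry a short
inverted repeat (for this virus the 10-mer consensus TGATGACGAA).  hrs are
the best candidates for origins of DNA replication.

Detection proceeds in three stages: (1) enumerate imperfect palindromes —
windows whose two arms are reverse complements within a mismatch tolerance
(no indels inside arms); (2) locate matches to the terminal-repeat
consensus on both strands; (3) cluster nearby palindromes into hr regions
and attach the flanking inverted terminal-repeat pairs.  A progressive
alignment of the member repeats yields the consensus display, with
uppercase letters at fully conserved columns and lowercase at
majority-conserved ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import PRESETS, progressive_msa
from .genome import CircularGenome, GenomeInterval, revcomp

__all__ = [
    "Palindrome",
    "HrRegion",
    "ConsensusDisplay",
    "enumerate_palindromes",
    "find_palindromes",
    "match_terminal_repeats",
    "cluster_hrs",
    "hr_consensus",
    "find_hrs",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N never matches? see below


@dataclass(frozen=True)
class Palindrome:
    span: GenomeInterval
    arm_length: int
    mismatches: int

    @property
    def score(self) -> int:
        """Arm matches minus mismatches."""
        return self.arm_length - 2 * self.mismatches

    @property
    def length(self) -> int:
        return self.span.end - self.span.start + 1


@dataclass
class HrRegion:
    name: str
    span: GenomeInterval
    palindromes: list[Palindrome]
    terminal_repeat_hits: list[tuple[int, str, int]] = field(default_factory=list)


@dataclass
class ConsensusDisplay:
    rows: list[tuple[str, str]]  # (label with genome positions, gapped sequence)
    consensus: str  # case-coded: upper = 100% identical, lower = majority
    class_line: str  # R/Y where all residues share purine/pyrimidine class

    def render(self) -> str:
        width = max(len(lbl) for lbl, _ in self.rows) + 2
        lines = [f"{lbl:<{width}}{seq}" for lbl, seq in self.rows]
        lines.append(f"{'consensus':<{width}}{self.consensus}")
        lines.append(f"{'class':<{width}}{self.class_line}")
        return "\n".join(lines)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))), dtype=np.uint8)


def enumerate_palindromes(
    seq: str, min_len: int = 49, max_len: int = 83, max_mismatch_frac: float = 0.15
) -> list[tuple[int, int, int]]:
    """All windows that are imperfect palindromes, as (start0, length, mismatches).

    A window of length L has arms of A = L // 2 bases (odd-length windows
    ignore the center base); it qualifies when the number of arm positions
    whose partner is not the complementary base is at most
    ``floor(max_mismatch_frac * A)``.  Ns never match.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    n = len(seq)
    if n < min_len:
        return []
    x = _encode(seq)
    xc = _COMP_CODE[x]  # complement codes; N maps to 4 and x==4 never equals comp
    # mismatch indicator for a pair at distance m: pair (i, i+m)
    mism_by_lag: dict[int, np.ndarray] = {}

    def mism(m: int) -> np.ndarray:
        if m not in mism_by_lag:
            a = x[: n - m]
            b = xc[m:]
            arr = (a != b) | (a == 4)
            mism_by_lag[m] = arr.astype(np.int32)
        return mism_by_lag[m]

    out = []
    for L in range(min_len, max_len + 1):
        if L > n:
            break
        A = L // 2
        tol = int(max_mismatch_frac * A)
        nwin = n - L + 1
        total = np.zeros(nwin, dtype=np.int32)
        for j in range(A):
            m = L - 1 - 2 * j
            total += mism(m)[j : j + nwin]
        for i in np.nonzero(total <= tol)[0]:
            out.append((int(i), L, int(total[i])))
    return out


def find_palindromes(
    seq: str, min_len: int = 49, max_len: int = 83, max_mismatch_frac: float = 0.15
) -> list[Palindrome]:
    """Non-overlapping imperfect palindromes, best scoring first, by position.

    Overlapping candidates are resolved greedily by score (arm matches minus
    mismatches), ties broken leftmost-then-longest; the survivors are
    returned sorted by genome position.
    """
    cands = enumerate_palindromes(seq, min_len, max_len, max_mismatch_frac)
    cands.sort(key=lambda c: (-(c[1] // 2 - 2 * c[2]), c[0], -c[1]))
    taken: list[tuple[int, int]] = []
    chosen = []
    for start0, L, mm in cands:
        lo, hi = start0, start0 + L - 1
        if any(lo <= e and s <= hi for s, e in taken):
            continue
        taken.append((lo, hi))
        chosen.append(
            Palindrome(GenomeInterval(start0 + 1, start0 + L), L // 2, mm)
        )
    chosen.sort(key=lambda p: p.span.start)
    return chosen


CONSENSUS_TERMINAL_REPEAT = "TGATGACGAA"


def match_terminal_repeats(
    seq: str, consensus: str = CONSENSUS_TERMINAL_REPEAT, max_mismatch: int = 2
) -> list[tuple[int, str, int]]:
    """Positions matching the terminal-repeat consensus on either strand.

    Returns (1-based start, strand, mismatches), sorted by position.  A
    minus-strand hit means the reverse complement of the consensus occurs
    at that position of the given sequence.
    """
    k = len(consensus)
    n = len(seq)
    if n < k:
        return []
    x = _encode(seq)
    hits = []
    for strand, pat in (("+", consensus), ("-", revcomp(consensus))):
        p = _encode(pat)
        mm = np.zeros(n - k + 1, dtype=np.int32)
        for j in range(k):
            mm += (x[j : j + n - k + 1] != p[j]) | (x[j : j + n - k + 1] == 4)
        for i in np.nonzero(mm <= max_mismatch)[0]:
            hits.append((int(i) + 1, strand, int(mm[i])))
    hits.sort()
    return hits


def cluster_hrs(
    palindromes: list[Palindrome],
    terminal_hits: list[tuple[int, str, int]],
    max_gap: int = 1000,
) -> list[HrRegion]:
    """Group palindromes within ``max_gap`` bp into hr regions.

    Clusters with more than three palindromes are split at their largest
    internal gaps.  Each region is annotated with the terminal-repeat hits
    falling within (or just outside) its span; regions are named hr1..hrN
    in genome order.
    """
    if not palindromes:
        return []
    pals = sorted(palindromes, key=lambda p: p.span.start)
    clusters: list[list[Palindrome]] = [[pals[0]]]
    for p in pals[1:]:
        if p.span.start - clusters[-1][-1].span.end <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    def split(cluster: list[Palindrome]) -> list[list[Palindrome]]:
        if len(cluster) <= 3:
            return [cluster]
        gaps = [
            cluster[i + 1].span.start - cluster[i].span.end
            for i in range(len(cluster) - 1)
        ]
        cut = int(np.argmax(gaps)) + 1
        return split(cluster[:cut]) + split(cluster[cut:])

    final: list[list[Palindrome]] = []
    for c in clusters:
        final.extend(split(c))
    regions = []
    margin = 15  # terminal repeats may sit just outside the palindrome arms
    for i, c in enumerate(final, start=1):
        lo, hi = c[0].span.start, c[-1].span.end
        th = [h for h in terminal_hits if lo - margin <= h[0] <= hi + margin]
        regions.append(
            HrRegion(f"hr{i}", GenomeInterval(lo, hi), list(c), th)
        )
    return regions


_PURINES = set("AG")


def hr_consensus(repeat_seqs: list[str], labels: list[str] | None = None) -> ConsensusDisplay:
    """Align hr repeats and build the case-coded consensus display.

    Column rule: uppercase consensus letter only when every row carries the
    identical residue; lowercase when a strict majority does; ``-``
    otherwise.  The class line marks columns where all residues are purines
    (R) or all pyrimidines (Y).
    """
    if len(repeat_seqs) < 2:
        raise ValueError("need at least 2 repeats for a consensus")
    labels = labels or [f"repeat{i+1}" for i in range(len(repeat_seqs))]
    rows = (
        progressive_msa(repeat_seqs, PRESETS["dna"])
        if len(set(map(len, repeat_seqs))) > 1 or len(set(repeat_seqs)) > 1
        else list(repeat_seqs)
    )
    ncol = len(rows[0])
    cons = []
    cls = []
    nrow = len(rows)
    for j in range(ncol):
        col = [r[j] for r in rows]
        residues = [c for c in col if c != "-"]
        counts = {b: residues.count(b) for b in set(residues)}
        best = max(counts, key=lambda b: (counts[b], b)) if counts else "-"
        if residues and counts.get(best, 0) == nrow and len(residues) == nrow:
            cons.append(best.upper())
        elif counts.get(best, 0) * 2 > nrow:
            cons.append(best.lower())
        else:
            cons.append("-")
        if residues and len(residues) == nrow:
            if all(c in _PURINES for c in residues):
                cls.append("R")
            elif all(c not in _PURINES for c in residues):
                cls.append("Y")
            else:
                cls.append(" ")
        else:
            cls.append(" ")
    return ConsensusDisplay(list(zip(labels, rows)), "".join(cons), "".join(cls))


def find_hrs(
    genome: CircularGenome,
    min_len: int = 49,
    max_len: int = 83,
    max_mismatch_frac: float = 0.15,
    consensus: str = CONSENSUS_TERMINAL_REPEAT,
    terminal_max_mismatch: int = 2,
    max_gap: int = 1000,
) -> list[HrRegion]:
    """Palindrome scan + terminal-repeat matching + clustering in one call."""
    pals = find_palindromes(genome.seq, min_len, max_len, max_mismatch_frac)
    th = match_terminal_repeats(genome.seq, consensus, terminal_max_mismatch)
    return cluster_hrs(pals, th, max_gap)
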