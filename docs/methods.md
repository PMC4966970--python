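# Methods

gvkit re-implements, as a reusable library, the computational
characterization of a small circular dsDNA virus genome of the
granulovirus type: ORF annotation, homologous repeat (hr) detection, gene
parity synteny comparison, transcriptome-to-genome variant analysis, and
concatenated-alignment distance phylogeny.  This note records the models,
parameter choices, and numerical conventions, and what the synthetic
study design does and does not emulate.

## Coordinates and reporting conventions

All genome coordinates are 1-based and inclusive on a circular molecule;
minus-strand features are written `start←end` with `start < end`.
Features crossing the origin carry a `wraps_origin` flag instead of
coordinates beyond the genome length, so interval invariants stay
checkable; GFF3 export splits such features into two lines sharing one
ID.  The numbering anchor follows the granulovirus convention: the genome
is rotated so the adenine of the granulin start codon is nt 1 and the
granulin ORF (ORF1) reads on the plus strand.  Printed numbers are
rounded half away from zero, only at reporting time.

## ORF annotation

An ORF candidate is a maximal ATG-to-stop frame: the first in-frame ATG
after the previous in-frame stop, on either strand, including frames that
run across the origin (implemented by scanning a tripled copy of the
sequence and deduplicating starts modulo the genome length).  "Longer
than 50 codons" is interpreted as ≥ 51 codons excluding the stop, so a
feature span is `3 × (codons + 1)` bp, consistent with published
position/size tables.  Alternative start codons are not considered.

Candidates are kept by a two-route rule, processed longest first:

1. **conserved** — a similarity search against the user-supplied
   reference proteome returns a hit with e-value below 0.010;
2. **predicted-coding** — no such hit, but the candidate overlaps every
   longer *kept* ORF by at most 75 bp (76 bp rejects) and two
   independent coding-potential scores both call it coding.

The two coding scores replace external gene predictors with in-package
equivalents trained per genome: (a) a per-codon log-likelihood ratio of
codon usage, coding frequencies estimated from the genome's own
conserved-class ORFs and null frequencies from nucleotide-shuffled,
frame-recut copies of the same ORFs; (b) a Fisher linear discriminant on
the nine phase-specific Z-curve composition components (x, y, z per codon
position), trained on the same positives and decoys.  Both are
thresholded at 0; the LLR is per-codon, so it is invariant under sequence
duplication.  Nucleotide shuffling (rather than codon-preserving
shuffling) is the right null for a codon-usage score: it preserves base
composition while destroying codon structure, which is exactly the
contrast the score measures.

The "overlap a larger ORF" test is evaluated against longer *kept* ORFs
(conserved ORFs are kept unconditionally and are classified first), with
overlap measured as span intersection in bp on the circle, strand
ignored.

## Similarity search and significance

Pairwise alignment is exact affine-gap dynamic programming
(`Bio.Align.PairwiseAligner`): BLOSUM62 for proteins, +5/−4 for
nucleotides, gap open 10 and extension 0.5 by default.  A "divergent"
preset halves the gap opening penalty (10 → 5) and the multiple-alignment
gap length penalty (0.2 → 0.1), mirroring common practice for weakly
conserved protein families.  Where equally optimal alignments exist, the
aligner's first reported alignment is used; outputs are deterministic for
fixed inputs.

Because no external database statistics are available, search
significance is an extreme-value estimate calibrated in place: for a
given database, local alignment scores of shuffled sequence pairs (60
samples, seeded) are fitted to a Gumbel law by moments, and a hit's
e-value is the database size times the fitted tail probability, with a
logarithmic search-space correction for the actual query/target lengths.
The classical cutoff of 0.010 is then applied to this internal estimate.
A shared 4-mer prefilter (default: at least 3 shared 4-mers) skips full
alignment for unrelated pairs; it is configurable and disabled in the
tests that probe the null behaviour.  Percent similarity counts columns
whose residue pair has a positive BLOSUM62 score — the usual "positives"
convention; since the exact similarity classes used in published
percent-similarity figures are tool-specific, those figures are not
asserted anywhere.

The progressive multiple aligner computes all pairwise global alignments,
builds a UPGMA guide tree from percent-identity distances
(`scipy.cluster.hierarchy`), and merges profiles by global
profile-profile DP with a per-column gap cost derived from the preset
(open/2 + extension), so the divergent preset gaps at half the default
cost.

## hr detection

An imperfect palindrome is a window whose two arms (`L // 2` bp each; the
center base of odd windows is ignored) are reverse complements within a
mismatch tolerance of 15% of the arm length; no indels are allowed within
arms.  Default window range is 49–83 bp.  Enumeration is vectorized over
anti-diagonal match arrays; overlapping candidates are resolved greedily
by score (arm matches − mismatches), ties leftmost-then-longest, which
keeps the longest clean extension of each planted palindrome.  Terminal
repeats are matched within 2 mismatches of the 10-mer consensus
(TGATGACGAA) on both strands.  Palindromes within 1,000 bp cluster into
one hr; clusters over three palindromes split at their largest internal
gaps; regions are named hr1..hrN in genome order.  The tolerance,
clustering distance and terminal-repeat mismatch limit are declared
defaults — the original repeat-finding tools' settings are not published
— so the count of hrs on any real genome is parameterization-sensitive
and is only asserted on planted truth.

The consensus display aligns member repeats and case-codes each column:
uppercase only where all rows agree, lowercase where a strict majority
agrees, `-` otherwise; a class line marks columns that are all-purine (R)
or all-pyrimidine (Y).

## Orthology and gene parity

Orthology between two proteomes is reciprocal best hit (RBH) under the
same search machinery and the 0.010 cutoff; ties break by higher
identity, then database order.  The parity table has one point per ORF —
`(number in A, number in B)` for orthologue pairs, an axis marker for
ORFs private to one genome.  As the quantitative summary of a parity
plot, the package reports a breakpoint count: the number of adjacent
orthologue pairs in A whose partners are not adjacent (rank difference
≠ ±1) in B.  Perfect colinearity gives 0; a single inverted block of ≥ 2
genes gives 2.  Orientation is deliberately ignored so that an internally
colinear inverted block costs only its two endpoints; the count is
symmetric between the genomes.  This statistic is an extension: parity
plots are traditionally read qualitatively.

## Transcriptome comparison

Contigs are mapped by edit-distance infix alignment (edlib) against both
strands; a contig whose best single placement falls below 80% identity is
bisected recursively (pieces under 100 bp are discarded), which resolves
multi-locus contigs and the inverted-duplication chimera artifact — a
contig consisting of a sequence followed by its own reverse complement,
detected when two segments of one contig map to the same locus (≥ 90%
reciprocal overlap) on opposite strands.  Flagged chimeras contribute
only their first segment to coverage and variant calling, so the
duplicated copy is not double-counted.  The identity and length
thresholds are declared defaults.

Because edit-distance alignment has no gap-opening cost, it can split one
indel into pieces separated by coincidentally matching bases; windows
around clustered gap columns are therefore re-aligned with affine-gap
scoring before variant extraction.  Adjacent gap columns merge into one
indel; indels are left-aligned (VCF-style: shifted to their leftmost
equivalent position), and insertions are reported as "inserted after
position X".  Indels whose allele is a single repeated base and whose
reference run is ≥ 4 bp carry a homopolymer context `(base, run_before,
run_after)` — the `8A → 9A` notation of published variant tables.

Substitutions in ORFs are synonymous or nonsynonymous by strand-aware
codon lookup under the standard genetic code; ORF indels are in-frame iff
their length is divisible by three, otherwise frameshift with the
affected codon index reported.  Everything else is intergenic (hr spans
are tracked by name but summarized with intergenic).  The summary's
substitution rate is substitutions per kbp of the *union* of aligned
intervals, reported to one decimal.

### The shipped variant table

`gvkit/data/pigv_table1_variants.tsv` transcribes a published
genome-vs-transcriptome variant table for the PiGV genome: 65
substitutions (29 synonymous, 26 nonsynonymous, 10 intergenic) and 23
indels (12 intergenic including one in hr6, 11 in ORFs).  One ORF
deletion of 22 nt is annotated as having no effect on the encoded protein
(a repeat contraction at an ORF 3' end); it is counted with the in-frame
class even though 22 mod 3 ≠ 0, preserving the table's 10/1
in-frame/frameshift split.  Minority-read flags (variants also seen in a
minority of the original genome sequencing reads) are carried as fixture
metadata only — the underlying reads are not available, so read
frequencies are never recomputed.  The table's row sums disagree slightly
with the totals printed in the source's running text (65 vs 66
substitutions; 29 vs 28 synonymous; 10 vs 12 intergenic); the fixture
preserves the table, and the package reports what the rows sum to.

## Phylogeny

Supermatrices are column-wise concatenations of per-gene protein
alignments with taxa matched by label; missing taxa are gap-filled with a
warning.  Distances use pairwise deletion of gap sites under three
models: p-distance, Poisson (`−ln(1 − p)`), and gamma-corrected
(`a[(1 − p)^(−1/a) − 1]`, shape supplied by the user — no shape value is
estimated internally).  Tree construction is neighbor joining with
deterministic tie-breaking by taxon label and negative branch estimates
clamped to zero; the minimum-evolution analyses this stands in for use NJ
as their starting tree, and plain NJ is the documented default here (no
NNI refinement is applied).  Maximum-likelihood inference is out of
scope.  Bootstrap supports resample supermatrix columns with replacement
(500 replicates at study scale) and report, per internal edge of the
point-estimate tree, the percentage of replicate trees containing the
same leaf bipartition.  The protein evolution simulator used in recovery
experiments is a site-independent Poisson process with uniform exchange
over 20 states (`P(change) = (19/20)(1 − e^{−20t/19})` per site on a
branch of length t).

## Synthetic study design

The generator's defaults define the study conditions.  The "paper-like"
preset builds a 112,536 bp circular genome at 44.2% GC with 123
non-overlapping ORFs (64 sense / 59 antisense, 60–450 codons), 7 hrs of
1–3 palindromes (49–83 bp, arms opening with TGATGACGAA), a reference
proteome at 70% identity covering 90% of ORFs (the granulin stand-in at
~94%) plus 30 random decoys, and transcriptome contigs drawn from the
eight published alignment intervals (51,303 bp, 45.6% of the genome) with
substitutions at 1.29 × 10⁻³ per bp, indels at 2 × 10⁻⁴ per bp, exactly
one frameshift indel, one 8A → 9A homopolymer slippage, and one chimera
contig.  The "easy" preset is a 30 kb / 18 ORF / 3 hr scaled version used
in the unit tests; "hard" raises divergence and variant rates.

Coding sequence is sampled from a biased codon model: one preferred
wobble codon per amino acid (weight 2) multiplied by a GC-pressure term
`q^{GC(codon)}`, with `q` solved by bisection so expected coding GC
matches the target; intergenic background is order-0 at the same GC.
Each ORF cassette carries an in-frame stop immediately upstream of its
ATG so planted starts are maximal; the anchor ORF opens the genome at
nt 1 with its guard stop at the end of the circle, making the generated
genome already anchor-rotated.  Planted variants respect spacing
constraints (≥ 30–40 bp apart, away from interval edges and planted
runs) and are recorded left-normalized with the same convention the
caller uses, so recovery can be asserted as exact set equality.

What the generator does **not** emulate: overlapping genes, promoter
structure, repeat families beyond the planted palindromes, sequencing
error models, transcript abundance, and real phylogenetic signal in the
proteome (homologues are i.i.d. point mutations).  Passing the planted
recovery tests therefore demonstrates correctness of the detection and
classification logic under clean, unambiguous signals — not performance
on real, repeat-rich genomes.  Variant classification in the recovery
tests is evaluated against the planted gene structure, so that the
annotator's false-positive rate (spurious predicted-coding ORFs in
random background, which are legitimate under the decision rule) is
measured separately from variant-calling correctness.

## Problem sizes used in tests and the acceptance script

The acceptance script runs one paper-like study (112.5 kb genome, ~300
ORF candidates, 9 contigs), a 20-tree 8-taxon NJ additive-matrix battery,
and a 6-taxon / 1,000-column / 100-replicate bootstrap experiment; the
test suite additionally sweeps 200 random 5–20 kb sequences for ORF-finder
equivalence against a brute-force oracle and 50 random 500 nt sequences
for palindrome-enumeration equivalence.  These sizes give stable,
reproducible statistics at interactive runtimes.

## Known limitations

* Significance estimates are calibrated per database on shuffled decoys;
  they are comparable within a run but are not NCBI BLAST e-values.
* The contig mapper assumes contigs do not span the genome origin
  (the shipped interval plans never cross it).
* Gamma-corrected distances require a user-supplied shape parameter.
* The hr detector reports palindromes without indels inside arms; a
  bulged palindrome is found only if its arms still fit the mismatch
  tolerance.
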