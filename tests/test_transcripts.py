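import random

import pytest

from gvkit.genome import CircularGenome, GenomeInterval, revcomp
from gvkit.orfs import AnnotatedGenome, OrfRecord
from gvkit.transcripts import (
    call_variants,
    classify_variant,
    compare_transcriptome,
    detect_inversion_artifact,
    load_table1_fixture,
    map_contigs,
    summarize_comparison,
    VariantRecord,
    write_vcf,
)

BIASED = ["GCT", "GAA", "TTC", "AAA", "CTG", "GAT", "ATT", "CCA"]


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="module")
def genome():
    rng = random.Random(77)
    return CircularGenome("g", rand_seq(rng, 8000))


class TestMapContigs:
    def test_exact_extract_maps_with_full_identity(self, genome):
        contig = genome.seq[999:2000]  # genome 1000..2000
        alns = map_contigs([("c", contig)], genome)
        a = alns[0]
        assert (a.genome_interval.start, a.genome_interval.end) == (1000, 2000)
        assert a.genome_interval.strand == "+" and a.identity == 100.0

    def test_reverse_complement_maps_to_minus_strand(self, genome):
        contig = revcomp(genome.seq[2999:4000])
        a = map_contigs([("c", contig)], genome)[0]
        assert a.genome_interval.strand == "-"
        assert (a.genome_interval.start, a.genome_interval.end) == (3000, 4000)

    def test_mutated_extract_keeps_interval_with_reduced_identity(self, genome):
        rng = random.Random(5)
        s = list(genome.seq[4999:6000])
        for i in rng.sample(range(60, 940), 10):  # ~1% substitutions
            s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
        a = map_contigs([("c", "".join(s))], genome)[0]
        assert (a.genome_interval.start, a.genome_interval.end) == (5000, 6000)
        assert 98.0 < a.identity < 100.0


class TestInversionArtifact:
    def test_inverted_duplication_flagged_at_junction(self, genome):
        s = genome.seq[999:3500]
        chimera = s + revcomp(s)
        alns = map_contigs([("chim", chimera)], genome)
        flag, junction = detect_inversion_artifact("chim", alns)
        assert flag and junction == len(s)

    def test_ordinary_contig_not_flagged(self, genome):
        alns = map_contigs([("c", genome.seq[999:3000])], genome)
        assert detect_inversion_artifact("c", alns) == (False, None)

    def test_disjoint_segments_not_flagged(self, genome):
        hybrid = genome.seq[999:2000] + revcomp(genome.seq[5999:7000])
        alns = map_contigs([("h", hybrid)], genome)
        assert len(alns) == 2
        assert detect_inversion_artifact("h", alns)[0] is False


class TestCallVariants:
    def test_planted_substitution_deletion_and_slippage(self):
        rng = random.Random(21)
        left, right = rand_seq(rng, 400), rand_seq(rng, 400)
        mid = "C" + "A" * 8 + "G" + rand_seq(rng, 200)
        gseq = left + mid + right
        genome = CircularGenome("g", gseq)
        # contig: A->G substitution at 100, 9 nt deletion at 201..209,
        # one extra A inside the A8 run (slippage)
        ref100 = gseq[99]
        alt = "G" if ref100 != "G" else "C"
        contig = list(gseq)
        contig[401 + 8 : 401 + 8] = ["A"]  # insert inside the run (after pos 409... run at 402-409)
        del contig[200:209]
        contig[99] = alt
        alns = map_contigs([("c", "".join(contig))], genome)
        assert len(alns) == 1
        vs = call_variants(alns[0], genome)
        subs = [v for v in vs if v.kind == "substitution"]
        dels = [v for v in vs if v.kind == "deletion"]
        ins = [v for v in vs if v.kind == "insertion"]
        assert [(v.position, v.ref, v.alt) for v in subs] == [(100, ref100, alt)]
        assert len(dels) == 1 and dels[0].length == 9 and dels[0].position == 201
        assert len(ins) == 1 and ins[0].alt == "A"
        assert ins[0].homopolymer_context == ("A", 8, 9)
        assert ins[0].position == 401  # left-aligned: anchored before the run

    def test_adjacent_gap_columns_merge_into_one_indel(self, genome):
        contig = genome.seq[999:1500] + genome.seq[1512:2000]  # 12 nt deletion
        a = map_contigs([("c", contig)], genome)[0]
        vs = call_variants(a, genome)
        assert [v.kind for v in vs] == ["deletion"]
        assert vs[0].length == 12


def _orf_record(start, end, strand, body, number):
    return OrfRecord(GenomeInterval(start, end, strand), len(body) // 3 - 1,
                     seq=body, number=number)


@pytest.fixture(scope="module")
def annotation():
    rng = random.Random(31)
    # plus-strand ORF at 101..400, minus-strand ORF at 601..900
    body1 = "ATG" + "".join(rng.choice(BIASED) for _ in range(98)) + "TAA"
    body2 = "ATG" + "".join(rng.choice(BIASED) for _ in range(98)) + "TGA"
    seq = (rand_seq(rng, 100) + body1 + rand_seq(rng, 200) + revcomp(body2)
           + rand_seq(rng, 300))
    genome = CircularGenome("t", seq)
    orfs = [
        _orf_record(101, 400, "+", body1, 1),
        _orf_record(601, 900, "-", body2, 2),
    ]
    return AnnotatedGenome(genome, orfs)


class TestClassification:
    def test_third_position_change_synonymous(self, annotation):
        # codon 5 of ORF1 occupies 113..115; BIASED codons are 4-fold or
        # 2-fold degenerate; pick a wobble change that preserves the residue
        codon = annotation.orfs[0].seq[12:15]
        wobble = {"GCT": "GCC", "GAA": "GAG", "TTC": "TTT", "AAA": "AAG",
                  "CTG": "CTA", "GAT": "GAC", "ATT": "ATC", "CCA": "CCG"}[codon]
        v = VariantRecord("substitution", 115, 115, codon[2], wobble[2])
        out = classify_variant(v, annotation)
        assert out.region == "ORF1" and out.effect == "synonymous"
        assert out.codon_index == 5

    def test_minus_strand_codon_lookup_is_strand_aware(self, annotation):
        orf = annotation.orfs[1]
        # first codon base of the minus-strand ORF sits at genome pos 900
        v = VariantRecord("substitution", 900, 900, annotation.genome.base(900), "N")
        # replace N with a real base that changes the ATG start
        alt = "C" if annotation.genome.base(900) != "C" else "G"
        v = VariantRecord("substitution", 900, 900, annotation.genome.base(900), alt)
        out = classify_variant(v, annotation)
        assert out.region == "ORF2" and out.effect == "nonsynonymous"
        assert out.codon_index == 1

    def test_insertion_in_seventh_codon_is_frameshift_there(self, annotation):
        # codon 7 of ORF1 covers 119..121; a 1 nt insertion after 119 shifts it
        v = VariantRecord("insertion", 119, 119, "", "T")
        out = classify_variant(v, annotation)
        assert out.effect == "frameshift" and out.codon_index == 7

    def test_in_frame_deletion_in_orf(self, annotation):
        v = VariantRecord("deletion", 131, 139, "XXXXXXXXX", "")
        out = classify_variant(v, annotation)
        assert out.effect == "in-frame" and out.region == "ORF1"

    def test_between_orfs_is_intergenic(self, annotation):
        v = VariantRecord("substitution", 500, 500, "A", "G")
        out = classify_variant(v, annotation)
        assert out.region == "intergenic" and out.effect == "intergenic"

    def test_outside_genome_rejected(self, annotation):
        with pytest.raises(ValueError):
            classify_variant(VariantRecord("substitution", 99999, 99999, "A", "G"), annotation)


class TestSummary:
    def test_class_counts_sum_to_totals(self):
        vs = load_table1_fixture()
        s = summarize_comparison(vs, [], 112_536)
        assert sum(s.substitutions.values()) == s.substitutions_total
        assert s.indels_intergenic + s.indels_in_orfs == s.indels_total
        assert s.orf_indels_in_frame + s.orf_indels_frameshift == s.indels_in_orfs

    def test_zero_variants_gives_zero_rate(self):
        s = summarize_comparison([], [GenomeInterval(1, 1000)], 10_000)
        assert s.substitutions_per_kbp == 0.0

    def test_planted_rate_thirty_subs_over_twenty_kb(self):
        vs = [VariantRecord("substitution", 10 * i + 5, 10 * i + 5, "A", "G", effect="intergenic")
              for i in range(30)]
        s = summarize_comparison(vs, [GenomeInterval(1, 20_000)], 100_000)
        assert s.substitutions_per_kbp == 1.5

    def test_coverage_invariant_under_alignment_resplit(self):
        one = [GenomeInterval(1001, 3000)]
        split = [GenomeInterval(1001, 2000), GenomeInterval(2001, 3000)]
        a = summarize_comparison([], one, 50_000)
        b = summarize_comparison([], split, 50_000)
        assert a.aligned_bp == b.aligned_bp
        assert a.genome_fraction_pct == b.genome_fraction_pct


class TestTable1Fixture:
    def test_chitinase_synonymous_row(self):
        vs = load_table1_fixture()
        v = next(x for x in vs if x.position == 5697)
        assert (v.kind, v.ref, v.alt, v.region, v.effect) == (
            "substitution", "A", "G", "ORF10", "synonymous")

    def test_nine_nt_deletion_row(self):
        vs = load_table1_fixture()
        v = next(x for x in vs if x.position == 20106)
        assert v.kind == "deletion" and v.length == 9 and v.region == "ORF22"

    def test_frameshift_row_carries_codon_and_run_context(self):
        vs = load_table1_fixture()
        v = next(x for x in vs if x.position == 12508)
        assert v.kind == "insertion" and v.effect == "frameshift"
        assert v.codon_index == 7 and v.homopolymer_context == ("A", 8, 9)
        assert v.minority

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        src = load_table1_fixture.__module__  # keep import style simple
        header = "kind\tposition\tend\tref\talt\tregion\teffect\tcodon\tminority\tcontext\n"
        p.write_text(header + "substitution\tnot_a_number\t5\tA\tG\tORF1\tsynonymous\t.\t0\t.\n")
        with pytest.raises(ValueError, match="line 2"):
            load_table1_fixture(p)


def test_vcf_export_round_trips_positions(tmp_path, genome):
    vs = [
        VariantRecord("substitution", 100, 100, genome.base(100), "G", effect="synonymous"),
        VariantRecord("deletion", 201, 209, genome.fetch(201, 209), "", effect="in-frame"),
        VariantRecord("insertion", 300, 300, "", "TTG", effect="intergenic"),
    ]
    out = tmp_path / "v.vcf"
    write_vcf(out, genome.id, genome.length, vs, genome)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 3
    assert lines[0].split("\t")[1] == "100"
    assert lines[1].split("\t")[3].startswith(genome.base(200))
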