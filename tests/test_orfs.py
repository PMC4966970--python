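import random

import pytest

from gvkit.genome import CircularGenome, GenomeInterval, revcomp
from gvkit.orfs import (
    CodingModel,
    OrfRecord,
    classify_orfs,
    find_orfs,
    number_orfs,
)

STOPS = {"TAA", "TAG", "TGA"}
NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in STOPS]
BIASED = ["GCT", "GAA", "TTC", "AAA", "CTG", "GAT", "ATT", "CCA"]


def brute_force_orfs(seq: str, min_codons: int):
    """Independent oracle: per-ATG maximality scan on the doubled circle.

    An ORF is maximal when scanning backwards in frame from its ATG hits a
    stop before any other ATG.
    """
    n = len(seq)
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        d = s + s
        for i in range(n):
            if d[i : i + 3] != "ATG":
                continue
            # forward to the first in-frame stop
            j = i + 3
            while j - i < n and d[j : j + 3] not in STOPS and j + 3 <= len(d):
                j += 3
            if d[j : j + 3] not in STOPS:
                continue  # no stop reachable within one full circle
            span = j + 3 - i
            if span > n or span // 3 - 1 <= min_codons:
                continue
            # backwards: maximal iff a stop appears before any ATG
            k = i - 3
            maximal = None
            steps = 0
            while steps < n // 3 + 2:
                cod = (s * 3)[k % n + n : k % n + n + 3]
                if cod in STOPS:
                    maximal = True
                    break
                if cod == "ATG":
                    maximal = False
                    break
                k -= 3
                steps += 1
            if maximal:
                if strand == "+":
                    start = i % n + 1
                    end = (i + span - 1) % n + 1
                else:
                    ws, we = i % n + 1, (i + span - 1) % n + 1
                    start, end = n + 1 - we, n + 1 - ws
                found.add((start, end, strand))
    return found


def random_genome(rng, length):
    return CircularGenome("r", "".join(rng.choice("ACGT") for _ in range(length)))


class TestFindOrfs:
    @pytest.mark.parametrize("seed", range(12))
    def test_equals_brute_force_on_random_circles(self, seed):
        rng = random.Random(seed)
        g = random_genome(rng, rng.randint(600, 4000))
        got = {(o.interval.start, o.interval.end, o.strand) for o in find_orfs(g, 20)}
        assert got == brute_force_orfs(g.seq, 20)

    def test_planted_orf_found_exactly(self):
        rng = random.Random(1)
        body = "ATG" + "".join(rng.choice(BIASED) for _ in range(59)) + "TAA"
        bg = "".join(rng.choice("ACGT") for _ in range(1000))
        g = CircularGenome("t", bg[:500] + "TAA" + body + bg[500:])
        hits = [o for o in find_orfs(g, 50)
                if (o.interval.start, o.interval.end, o.strand) == (504, 503 + len(body), "+")]
        assert len(hits) == 1 and hits[0].length_codons == 60

    def test_origin_spanning_orf_flagged(self):
        rng = random.Random(2)
        body = "ATG" + "".join(rng.choice(BIASED) for _ in range(70)) + "TGA"
        bg = "".join(rng.choice("ACGT") for _ in range(800))
        seq = body[100:] + bg + "TAA" + body[:100]
        n = len(seq)
        start = n - 100 + 1
        wrapped = [o for o in find_orfs(CircularGenome("t", seq), 50)
                   if o.interval.wraps_origin and o.strand == "+"]
        assert [(o.interval.start, o.interval.end) for o in wrapped] == [(start, len(body) - 100)]
        o = wrapped[0]
        assert o.length_codons == 71
        assert o.seq.startswith("ATG") and o.seq[-3:] in STOPS

    def test_all_stop_codons_gives_nothing(self):
        assert find_orfs(CircularGenome("t", "TAA" * 60), 5) == []


@pytest.fixture(scope="module")
def trained():
    rng = random.Random(3)
    orfs = ["ATG" + "".join(rng.choice(BIASED) for _ in range(rng.randint(80, 200))) + "TAA"
            for _ in range(30)]
    return CodingModel.train(orfs, seed=3), orfs, rng


class TestCodingPotential:
    def test_training_orfs_score_positive_on_average(self, trained):
        model, orfs, _ = trained
        scores = [model.score(s).llr_codon_usage for s in orfs]
        assert sum(scores) / len(scores) > 0

    def test_shuffled_decoys_score_near_zero_or_negative(self, trained):
        model, orfs, rng = trained
        decoys = []
        for s in orfs[:15]:
            chars = list(s)
            rng.shuffle(chars)
            decoys.append("".join(chars))
        scores = [model.score(s).llr_codon_usage for s in decoys]
        mean = sum(scores) / len(scores)
        assert mean < 0.05

    def test_llr_is_length_normalized(self, trained):
        model, orfs, _ = trained
        s = orfs[0]
        doubled = s[:-3] + s[3:]
        one = model.score(s).llr_codon_usage
        two = model.score(doubled).llr_codon_usage
        assert two == pytest.approx(one, abs=0.02)


def _fake_orf(start, end, strand, ncodons, seq):
    return OrfRecord(GenomeInterval(start, end, strand), ncodons, seq=seq)


@pytest.fixture(scope="module")
def setting():
    rng = random.Random(9)

    def coding(nc):
        return "ATG" + "".join(rng.choice(BIASED) for _ in range(nc - 1)) + "TAA"

    big = _fake_orf(1, 900, "+", 299, coding(299))
    ref_db = [("ref_big", big.aa)]
    model = CodingModel.train([coding(200) for _ in range(25)], seed=9)
    return big, ref_db, model, coding


class TestClassification:
    def test_conserved_candidate_kept_regardless_of_overlap(self, setting):
        big, ref_db, model, coding = setting
        kept, dropped = classify_orfs([big], ref_db, 5000, seed=1, coding_model=model)
        assert kept[0].orf_class == "conserved" and kept[0].best_hit.evalue < 0.010

    @pytest.mark.parametrize("overlap,expect_kept", [(75, True), (76, False)])
    def test_overlap_boundary_on_larger_kept_orf(self, setting, overlap, expect_kept):
        big, ref_db, model, coding = setting
        # candidate with no reference hit, overlapping the conserved ORF
        start = 900 - overlap + 1
        ncod = 100
        cand = _fake_orf(start, start + 3 * (ncod + 1) - 1, "+", ncod, coding(ncod))
        kept, dropped = classify_orfs([big, cand], ref_db, 5000, seed=1, coding_model=model)
        cand_kept = [o for o in kept if o.orf_class == "predicted-coding"]
        assert bool(cand_kept) == expect_kept
        if expect_kept:
            assert cand_kept[0].interval.start == start

    def test_no_hit_candidate_with_negative_calls_dropped(self, setting):
        big, ref_db, model, coding = setting
        rng = random.Random(30)
        junk = "ATG" + "".join(rng.choice(NONSTOP) for _ in range(99)) + "TAA"
        cand = _fake_orf(2000, 2000 + len(junk) - 1, "+", 100, junk)
        kept, dropped = classify_orfs([big, cand], ref_db, 5000, seed=1, coding_model=model)
        calls = model.score(junk).calls
        assert (cand.interval.start in [o.interval.start for o in kept]) == all(calls)


class TestNumbering:
    def test_numbering_invariant_under_genome_rotation(self, easy_study, easy_annotation):
        genome, truth, proteome, contigs = easy_study
        ann, _ = easy_annotation
        assert [o.number for o in ann.orfs] == list(range(1, len(ann.orfs) + 1))
        anchor = ann.orfs[0]
        assert anchor.number == 1 and anchor.interval.start == 1 and anchor.strand == "+"
        assert ann.genome.seq[:3] == "ATG"

    def test_rotated_copy_numbers_identically(self, easy_annotation):
        from gvkit.genome import rotate_to_anchor

        ann, _ = easy_annotation
        n = ann.genome.length
        # rotate the annotated genome arbitrarily and re-anchor on the same ORF
        rotated, remap = rotate_to_anchor(ann.genome, 1234, "+")
        from gvkit.genome import remap_interval
        from gvkit.orfs import replace_orf

        moved = [replace_orf(o, interval=remap_interval(o.interval, remap, n), number=None)
                 for o in ann.orfs]
        anchor = next(o for o in moved if o.seq == ann.orfs[0].seq)
        renum = number_orfs(rotated, moved, anchor)
        assert renum.genome.seq == ann.genome.seq
        assert [(o.number, o.interval) for o in renum.orfs] == [
            (o.number, o.interval) for o in ann.orfs
        ]
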