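import math
import random

import pytest

from ontprep.autotune import CutoffSet
from ontprep.classify import (CHIMERIC, FULL_LENGTH, TRUNCATED,
                              classify_read, locate_aps, mean_quality,
                              preprocess, trim_read, trim_read_with_interval)
from ontprep.seqio import SequenceRecord, reverse_complement, revcomp
from ontprep.simulate import build_construct

from .conftest import make_record, random_dna


def strict_cutoffs(L=25, s_cut=0.9, loc=50):
    return {ap: CutoffSet(ap_id=ap, similarity_cutoff=s_cut,
                          location_cutoff=loc, ap_sub_length=L, beta=0.2,
                          precision=1.0, recall=1.0, f_beta=1.0)
            for ap in ("front", "rear")}


def full_length_read(schema, rng, insert_len=400, polya=30, strand="+",
                     read_id="fl"):
    insert = random_dna(rng, insert_len - 3) + "".join(
        rng.choice("CGT") for _ in range(3))
    seq = build_construct(insert, schema, polya, strand)
    return make_record(read_id, seq), insert


class TestLocateAndClassify:
    def test_error_free_construct_both_ends_accepted(self, schema, rng):
        read, _ = full_length_read(schema, rng)
        located = locate_aps(read, schema, strict_cutoffs())
        assert set(located.accepted) == {"front", "rear"}
        assert all(h.similarity == 1.0 for h in located.accepted.values())
        assert located.mid_hits == []
        cls = classify_read(read, located)
        assert cls.label == FULL_LENGTH
        assert cls.strand == "+"

    def test_minus_strand_full_length(self, schema, rng):
        read, _ = full_length_read(schema, rng, strand="-")
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        assert cls.label == FULL_LENGTH
        assert cls.strand == "-"

    def test_concatenated_constructs_have_mid_hits(self, schema, rng):
        a, _ = full_length_read(schema, rng, read_id="a")
        b, _ = full_length_read(schema, rng, read_id="b")
        fusion = make_record("f", a.sequence + b.sequence)
        located = locate_aps(fusion, schema, strict_cutoffs())
        assert located.mid_hits  # similarity-passing, location-failing
        cls = classify_read(fusion, located)
        assert cls.label == CHIMERIC

    def test_front_only_read_is_truncated(self, schema, rng):
        read = make_record("t", schema.front_ap + random_dna(rng, 300))
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        assert cls.label == TRUNCATED
        assert cls.strand == "+"
        assert cls.front_hit is not None and cls.rear_hit is None

    def test_mid_hit_beats_two_end_hits(self, schema, rng):
        # full construct with an extra AP copy planted mid-read
        insert = random_dna(rng, 200) + revcomp(schema.rear_ap) \
            + random_dna(rng, 197) + "CGT"
        read = make_record("c", build_construct(insert, schema, 30, "+"))
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        assert cls.label == CHIMERIC

    def test_insert_only_reads_have_no_accepted_hits(self, schema):
        """Random 500-mers essentially never reach 0.9 similarity at L=25."""
        rng = random.Random(424)
        cutoffs = strict_cutoffs(L=25, s_cut=0.9)
        accepted = 0
        for i in range(1000):
            read = make_record(f"r{i}", random_dna(rng, 500))
            located = locate_aps(read, schema, cutoffs)
            accepted += len(located.accepted) + len(located.mid_hits)
        assert accepted == 0

    def test_strand_symmetry(self, schema, rng):
        """The reverse-complemented read gets the same label, flipped strand,
        and an identical trimmed sequence."""
        read, insert = full_length_read(schema, rng)
        flipped = reverse_complement(read)
        cutoffs = strict_cutoffs()
        cls_fwd = classify_read(read, locate_aps(read, schema, cutoffs))
        cls_rev = classify_read(flipped, locate_aps(flipped, schema, cutoffs))
        assert cls_fwd.label == cls_rev.label == FULL_LENGTH
        assert {cls_fwd.strand, cls_rev.strand} == {"+", "-"}
        assert trim_read(read, cls_fwd, schema).sequence == insert
        assert trim_read(flipped, cls_rev, schema).sequence == insert


class TestTrim:
    def test_exact_recovery_plus_strand(self, schema, rng):
        read, insert = full_length_read(schema, rng)
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        out, interval = trim_read_with_interval(read, cls, schema)
        assert out.sequence == insert
        assert len(out.qualities) == len(out.sequence)
        assert interval == (len(schema.front_ap),
                            len(schema.front_ap) + len(insert))
        assert "strand=+" in out.comment

    def test_exact_recovery_minus_strand(self, schema, rng):
        read, insert = full_length_read(schema, rng, strand="-")
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        out = trim_read(read, cls, schema)
        assert out.sequence == insert  # sense orientation restored
        assert "strand=-" in out.comment

    def test_interrupted_polya_fully_trimmed(self, schema, rng):
        # polyA of A*10 G A*10: the single-base interruption is inside the
        # tolerance (run <= 2, flanked by A, window >= 80% A), so the whole
        # tail goes; the insert (ending in non-A) is untouched
        insert = random_dna(rng, 300) + "CGT"
        seq = (schema.front_ap + insert + "A" * 10 + "G" + "A" * 10
               + revcomp(schema.rear_ap))
        read = make_record("p", seq)
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        assert cls.label == FULL_LENGTH
        assert trim_read(read, cls, schema).sequence == insert

    def test_no_polya_anchor_means_no_tail_trim(self, schema, rng):
        # construct without a polyA: nothing adjacent to the rear AP to trim
        insert = random_dna(rng, 300) + "CGT"
        seq = schema.front_ap + insert + revcomp(schema.rear_ap)
        read = make_record("n", seq)
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        assert trim_read(read, cls, schema).sequence == insert

    def test_trim_requires_full_length(self, schema, rng):
        read = make_record("t", schema.front_ap + random_dna(rng, 300))
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        with pytest.raises(ValueError, match="full_length"):
            trim_read(read, cls, schema)

    def test_trim_is_contiguous_subsequence(self, schema, rng):
        read, _ = full_length_read(schema, rng, strand="-")
        cls = classify_read(read, locate_aps(read, schema, strict_cutoffs()))
        out = trim_read(read, cls, schema)
        oriented = reverse_complement(read)
        assert out.sequence in oriented.sequence


class TestMeanQuality:
    def test_constant_quality(self):
        assert mean_quality(make_record("r", "ACGT" * 5, q=20)) == \
            pytest.approx(20.0)

    def test_probability_space_average(self):
        rec = SequenceRecord("r", "AC", [10, 20])
        expected = -10 * math.log10((0.1 + 0.01) / 2)
        assert mean_quality(rec) == pytest.approx(expected)
        assert mean_quality(rec) == pytest.approx(12.59, abs=0.01)

    def test_low_quality_base_strictly_decreases_mean(self):
        base = make_record("r", "ACGTACGT", q=20)
        worse = SequenceRecord("r", "ACGTACGTA", [20] * 8 + [0])
        assert mean_quality(worse) < mean_quality(base)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            mean_quality(SequenceRecord("r", "", []))


class TestPreprocess:
    def test_perfect_inputs_all_full_length(self, schema, rng):
        reads = [full_length_read(schema, rng, read_id=f"r{i}")[0]
                 for i in range(50)]
        result = preprocess(reads, schema, strict_cutoffs(), min_q=7.0)
        assert result.counts[FULL_LENGTH] == 50
        assert sum(result.counts.values()) == 50
        assert set(result.table["label"]) == {FULL_LENGTH}

    def test_counts_conserved_on_mixed_input(self, schema, rng):
        reads = []
        for i in range(10):
            reads.append(full_length_read(schema, rng, read_id=f"fl{i}")[0])
            reads.append(make_record(f"tr{i}",
                                     schema.front_ap + random_dna(rng, 300)))
        a, _ = full_length_read(schema, rng, read_id="x")
        b, _ = full_length_read(schema, rng, read_id="y")
        reads.append(make_record("fus", a.sequence + b.sequence))
        result = preprocess(reads, schema, strict_cutoffs(), min_q=0.0)
        assert sum(result.counts.values()) == len(reads)
        assert len(result.table) == len(reads)
        assert result.counts[CHIMERIC] == 1
        assert result.counts[TRUNCATED] == 10

    def test_quality_filter_applied_after_trimming(self, schema, rng):
        # insert bases are high quality; AP/polyA bases terrible — the read
        # must pass a post-trim filter that its raw mean quality would fail
        insert = random_dna(rng, 300) + "CGT"
        seq = build_construct(insert, schema, 30, "+")
        n_insert_start = len(schema.front_ap)
        quals = [2] * len(seq)
        quals[n_insert_start:n_insert_start + len(insert)] = \
            [30] * len(insert)
        read = SequenceRecord("q", seq, quals)
        result = preprocess([read], schema, strict_cutoffs(), min_q=20.0)
        assert result.counts[FULL_LENGTH] == 1
        assert result.table.iloc[0]["mean_q"] == pytest.approx(30.0)

    def test_low_quality_full_length_diverts_to_failed(self, schema, rng):
        read, _ = full_length_read(schema, rng)
        read = SequenceRecord(read.read_id, read.sequence,
                              [3] * len(read.sequence))
        result = preprocess([read], schema, strict_cutoffs(), min_q=7.0)
        assert result.counts["failed_quality"] == 1
        # the table still records the read as classified full-length
        assert result.table.iloc[0]["label"] == FULL_LENGTH
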