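"""Alignment, edit-outcome classification and summary metrics."""

import random

import numpy as np
import pytest
from Bio import Align

from pamscreen import (
    AmpliconSimConfig,
    EditCall,
    EditClass,
    Interval,
    align_read,
    classify_read,
    classify_reads,
    simulate_amplicon_reads,
    summarize,
)


def _biopython_aligner():
    """Independent affine-gap scorer with free reference end gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    # the read must align end to end; reference ends are free (a "deletion"
    # here is Biopython's term for query letters skipped in the target axis)
    aligner.open_left_deletion_score = 0.0
    aligner.extend_left_deletion_score = 0.0
    aligner.open_right_deletion_score = 0.0
    aligner.extend_right_deletion_score = 0.0
    return aligner


class TestAlignRead:
    def test_reference_substring_has_no_events(self, amplicon_ref):
        read = amplicon_ref.sequence[30:150]
        aln = align_read(read, amplicon_ref)
        assert aln.events == []
        assert aln.substitutions == []
        assert aln.score == pytest.approx(2.0 * len(read))

    def test_internal_deletion_single_event(self, amplicon_ref):
        seq = amplicon_ref.sequence
        read = seq[:80] + seq[87:]
        aln = align_read(read, amplicon_ref)
        assert len(aln.events) == 1
        pos, net = aln.events[0]
        assert net == -7
        assert abs(pos - 80) <= 7  # left-normalised within the repeat context

    def test_gapless_rows_reproduce_inputs(self, amplicon_ref):
        read = amplicon_ref.sequence[:100] + "ACGT"
        aln = align_read(read, amplicon_ref)
        assert aln.aligned_read.replace("-", "") == read
        assert aln.aligned_ref.replace("-", "") == amplicon_ref.sequence

    def test_leftmost_gap_in_homopolymer(self):
        # distinct flanks force the indel; the gap run is co-optimal anywhere
        # inside the T homopolymer and must be reported at its 5' end
        ref = "ACGTGA" + "TTTT" + "CAGTCA"
        read = "ACGTGA" + "TTT" + "CAGTCA"
        aln = align_read(read, ref)
        assert aln.events == [(6, -1)]

    def test_leftmost_insertion_in_homopolymer(self):
        ref = "ACGTGA" + "TTT" + "CAGTCA"
        read = "ACGTGA" + "TTTT" + "CAGTCA"
        aln = align_read(read, ref)
        assert aln.events == [(6, 1)]

    def test_empty_read_rejected(self, amplicon_ref):
        with pytest.raises(ValueError):
            align_read("", amplicon_ref)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_score_matches_biopython_oracle(self, seed):
        """Dual-route check: our Gotoh DP score equals Biopython's
        PairwiseAligner on random pairs with planted indels."""
        rng = random.Random(seed)
        aligner = _biopython_aligner()
        for _ in range(100):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randrange(20, 60)))
            read = list(ref)
            for _ in range(rng.randrange(0, 4)):
                op = rng.random()
                pos = rng.randrange(max(1, len(read)))
                if op < 0.4 and len(read) > 5:
                    del read[pos : pos + rng.randrange(1, 4)]
                elif op < 0.7:
                    read.insert(pos, rng.choice("ACGT"))
                else:
                    read[pos] = rng.choice("ACGT")
            read = "".join(read)
            if not read:
                continue
            ours = align_read(read, ref).score
            theirs = aligner.score(ref, read)
            assert ours == pytest.approx(theirs), (read, ref)


class TestClassifyRead:
    def test_wild_type(self, amplicon_ref):
        aln = align_read(amplicon_ref.sequence, amplicon_ref)
        call = classify_read(aln, amplicon_ref)
        assert call.edit_class is EditClass.WT

    def test_perfect_hdr(self, amplicon_ref):
        aln = align_read(amplicon_ref.edited_sequence(), amplicon_ref)
        call = classify_read(aln, amplicon_ref)
        assert call.edit_class is EditClass.HDR_PERFECT

    def test_conversion_with_deletion_is_converted_not_perfect(self, amplicon_ref):
        edited = amplicon_ref.edited_sequence()
        # 2-nt deletion inside the HDR window but away from the TG->CA site
        pos = amplicon_ref.hdr_window.start + 3
        read = edited[:pos] + edited[pos + 2 :]
        aln = align_read(read, amplicon_ref)
        call = classify_read(aln, amplicon_ref)
        assert call.edit_class is EditClass.HDR_CONVERTED

    def test_indel_net_length(self, amplicon_ref):
        seq = amplicon_ref.sequence
        cut = amplicon_ref.cut_window
        read = seq[: cut.start + 4] + seq[cut.start + 11 :]
        aln = align_read(read, amplicon_ref)
        call = classify_read(aln, amplicon_ref)
        assert call.edit_class is EditClass.INDEL
        assert call.net_indel_length == -7

    def test_substitution_outside_hdr_window_stays_wt(self, amplicon_ref):
        seq = list(amplicon_ref.sequence)
        seq[5] = "A" if seq[5] != "A" else "C"
        aln = align_read("".join(seq), amplicon_ref)
        assert classify_read(aln, amplicon_ref).edit_class is EditClass.WT

    def test_indel_outside_cut_window_not_called_indel(self, amplicon_ref):
        seq = amplicon_ref.sequence
        read = seq[:20] + seq[22:]  # 2-nt deletion far 5' of the cut site
        aln = align_read(read, amplicon_ref)
        assert classify_read(aln, amplicon_ref).edit_class is EditClass.WT

    def test_garbage_read_is_ambiguous(self, amplicon_ref):
        read = "AT" * 90
        aln = align_read(read, amplicon_ref)
        assert classify_read(aln, amplicon_ref).edit_class is EditClass.AMBIGUOUS


class TestSummarize:
    def test_hand_counted_example(self):
        calls = [
            EditCall("a", EditClass.WT),
            EditCall("b", EditClass.INDEL, net_indel_length=-7),
            EditCall("c", EditClass.INDEL, net_indel_length=1),
            EditCall("d", EditClass.HDR_PERFECT),
        ]
        s = summarize(calls)
        assert s.indel_rate == pytest.approx(50.0)
        assert s.hdr_perfect_rate == pytest.approx(25.0)
        assert s.hdr_converted_rate == pytest.approx(25.0)
        assert s.mean_abs_indel_length == pytest.approx(4.0)
        assert s.length_histogram == {-7: 1, 1: 1}

    def test_all_wild_type(self):
        s = summarize([EditCall(str(i), EditClass.WT) for i in range(5)])
        assert s.indel_rate == 0.0
        assert s.hdr_converted_rate == 0.0
        assert s.mean_abs_indel_length is None

    def test_ambiguous_excluded_from_denominator(self):
        calls = [
            EditCall("a", EditClass.INDEL, net_indel_length=-5),
            EditCall("b", EditClass.AMBIGUOUS),
        ]
        s = summarize(calls)
        assert s.indel_rate == pytest.approx(100.0)
        assert s.n_ambiguous == 1

    def test_no_classifiable_reads_rejected(self):
        with pytest.raises(ValueError):
            summarize([EditCall("a", EditClass.AMBIGUOUS)])


class TestRecovery:
    def test_simulated_rates_recovered(self, amplicon_ref):
        """End-to-end: summarize(classify(align)) recovers the generative
        indel/HDR rates within binomial error."""
        cfg = AmpliconSimConfig(
            reference=amplicon_ref,
            indel_rate=0.25,
            hdr_rate=0.15,
            indel_length_distribution={-7: 0.5, -12: 0.5},
            seq_error_rate=0.001,
            n_reads=400,
            seed=17,
        )
        reads, truth = simulate_amplicon_reads(cfg)
        calls, n_filtered = classify_reads(reads, amplicon_ref)
        assert n_filtered == 0
        s = summarize(calls)
        truth_frame = truth.records.set_index("read_id")
        by_id = {c.read_id: c for c in calls}
        mismatches = sum(
            1
            for rid, row in truth_frame.iterrows()
            if (row["outcome"] == "INDEL") != (by_id[rid].edit_class is EditClass.INDEL)
        )
        assert mismatches <= 0.02 * len(calls)
        sd = 100 * np.sqrt(0.25 * 0.75 / 400)
        assert abs(s.indel_rate - 25.0) <= 3 * sd

    def test_classification_order_invariant(self, amplicon_ref):
        cfg = AmpliconSimConfig(
            reference=amplicon_ref, indel_rate=0.5, n_reads=40, seed=3
        )
        reads, _ = simulate_amplicon_reads(cfg)
        fwd, _ = classify_reads(reads, amplicon_ref)
        rev, _ = classify_reads(list(reversed(reads)), amplicon_ref)
        assert {c.read_id: c.edit_class for c in fwd} == {
            c.read_id: c.edit_class for c in rev
        }

    def test_short_reads_filtered(self, amplicon_ref):
        calls, n_filtered = classify_reads(
            ["ACGT", amplicon_ref.sequence], amplicon_ref, min_read_len=40
        )
        assert n_filtered == 1
        assert len(calls) == 1
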