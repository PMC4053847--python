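"""ORF extraction, frameshift flagging, and the naive single-indel corrector."""

import numpy as np
import pytest

from transannot.io_formats import Hsp, Transcript
from transannot.orf import (
    call_orf,
    correct_frameshift_naive,
    frame_statistics,
    longest_orf_in_frame,
)
from transannot.search import SearchDatabase, reverse_complement, \
    translate_frame


def _hit(qid, sid, frame, qstart, qend, bitscore=100.0):
    return Hsp(qid, sid, 95.0, (abs(qend - qstart) + 1) // 3, 1, 0,
               qstart, qend, 1, 30, 1e-20, bitscore, frame)


class TestFrameStatistics:
    def test_same_frame_consistent(self):
        hsps = [_hit("t", "g", 2, 2, 31), _hit("t", "g", 2, 35, 64)]
        frames, consistent = frame_statistics(hsps)
        assert frames == {2} and consistent

    def test_different_frames_inconsistent(self):
        hsps = [_hit("t", "g", 1, 1, 30), _hit("t", "g", 3, 36, 65)]
        frames, consistent = frame_statistics(hsps)
        assert frames == {1, 3} and not consistent

    def test_singleton_consistent(self):
        frames, consistent = frame_statistics([_hit("t", "g", -3, 60, 31)])
        assert frames == {-3} and consistent

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            frame_statistics([])

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError):
            frame_statistics([_hit("t", "g1", 1, 1, 30),
                              _hit("t", "g2", 1, 1, 30)])


class TestLongestOrf:
    def test_single_run_before_stop(self):
        call = longest_orf_in_frame("ATGAAATAA", 1)
        assert (call.orf_start, call.orf_end) == (0, 6)
        assert call.protein == "MK"
        assert call.has_start and call.has_stop

    def test_longest_run_after_stop(self):
        call = longest_orf_in_frame("TTTTAAATGCCC", 1)
        assert (call.orf_start, call.orf_end) == (6, 12)
        assert call.protein == "MP"
        assert call.has_start and not call.has_stop

    def test_minus_strand(self):
        call = longest_orf_in_frame("TTACAT", -1)
        assert call.protein == "M"
        assert call.has_start and call.has_stop
        # coordinates are on the input strand
        assert (call.orf_start, call.orf_end) == (3, 6)

    def test_tie_goes_to_five_prime_run(self):
        # runs "AAA" and (after TAA) "CCC": equal length, first one kept
        call = longest_orf_in_frame("AAATAACCC", 1)
        assert (call.orf_start, call.orf_end) == (0, 3)
        assert call.protein == "K"


class TestCallOrf:
    def test_consistent_frame_unflagged(self):
        t = Transcript("t", "ATGAAATAA")
        call = call_orf(t, [_hit("t", "g", 1, 1, 6)])
        assert call.protein == "MK" and not call.frameshift_flagged
        assert call.frame == 1

    def test_conflicting_frames_flagged_all_frame_orf(self):
        seq = "ATGAAACCCGGG" + "ATGGGGTTTAAA"
        t = Transcript("t", seq)
        hsps = [_hit("t", "g", 1, 1, 12), _hit("t", "g", 2, 14, 22, 90.0)]
        call = call_orf(t, hsps)
        assert call.frameshift_flagged
        assert call.evidence_frames == {1, 2}
        # the ORF is the longest stop-free run over all six frames
        best_len = max(
            max((len(r) for r in translate_frame(seq, f).split("*")),
                default=0)
            for f in (1, 2, 3, -1, -2, -3))
        assert len(call.protein) == best_len

    def test_hitless_transcript_gets_fallback_orf(self):
        # frame -1 of ATGAAATAA (revcomp TTATTTCAT -> LFH) is the longest
        # stop-free run over the six frames
        call = call_orf(Transcript("t", "ATGAAATAA"), [])
        assert call.frame is None and call.protein == "LFH"
        assert not call.frameshift_flagged

    def test_hitless_fallback_is_longest_over_six_frames(self, rng):
        for _ in range(10):
            n = int(rng.integers(30, 150))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            call = call_orf(Transcript("t", seq), [])
            best = max(
                max((len(r) for r in translate_frame(seq, f).split("*")),
                    default=0)
                for f in (1, 2, 3, -1, -2, -3))
            assert len(call.protein) == best

    def test_evidence_restricted_to_best_subject(self):
        t = Transcript("t", "ATGAAACCCGGGTTT")
        hsps = [_hit("t", "gBest", 1, 1, 15, bitscore=200.0),
                _hit("t", "gWorse", 2, 2, 13, bitscore=50.0)]
        call = call_orf(t, hsps)
        assert not call.frameshift_flagged
        assert call.evidence_frames == {1}

    def test_plus_minus_symmetry(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 120))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            fwd = call_orf(Transcript("t", seq), [])
            rev = call_orf(Transcript("t", reverse_complement(seq)), [])
            assert fwd.protein == rev.protein

    def test_translation_invariant_random_sequences(self, rng):
        # the OrfCall constructor path asserts region->protein identity;
        # exercise it across random sequences and all frames
        for _ in range(25):
            n = int(rng.integers(10, 200))
            seq = "".join("ACGTN"[i] for i in rng.integers(0, 5, n))
            for frame in (1, 2, 3, -1, -2, -3):
                call = longest_orf_in_frame(seq, frame)
                region = seq[call.orf_start:call.orf_end]
                if call.frame is None:
                    continue
                expected = translate_frame(
                    region if frame > 0 else reverse_complement(region), 1) \
                    if len(region) >= 3 else ""
                assert expected == call.protein
                assert "*" not in call.protein


class TestCorrector:
    def _shifted_case(self):
        """A CDS with one deletion between two cleanly separated HSPs."""
        protein = "MKVLAEHNQRWSTFYGCDIPMKVLAEHNQRWSTFYGCDIP"
        codon = {"M": "ATG", "K": "AAA", "V": "GTT", "L": "CTT", "A": "GCT",
                 "E": "GAA", "H": "CAT", "N": "AAT", "Q": "CAA", "R": "CGT",
                 "W": "TGG", "S": "TCT", "T": "ACT", "F": "TTT", "Y": "TAT",
                 "G": "GGT", "C": "TGT", "D": "GAT", "I": "ATT", "P": "CCT"}
        cds = "".join(codon[aa] for aa in protein) + "TAA"
        mutated = cds[:73] + cds[74:]  # delete 1 nt at position 73
        return protein, mutated

    def test_single_deletion_corrected(self):
        protein, mutated = self._shifted_case()
        t = Transcript("t", mutated)
        db = SearchDatabase({"src": protein})
        hits = db.search(t, evalue_cutoff=1e-3)
        call = call_orf(t, hits)
        assert call.frameshift_flagged
        corrected = correct_frameshift_naive(t, hits)
        assert corrected is not None
        assert len(corrected) in (len(mutated) + 1, len(mutated) + 2)
        # re-searching the corrected sequence gives a consistent call
        t2 = Transcript("t2", corrected)
        call2 = call_orf(t2, db.search(t2, evalue_cutoff=1e-3))
        assert not call2.frameshift_flagged
        # the corrected ORF recovers the source protein away from the edit
        assert call2.protein[:15] == protein[:15]
        assert call2.protein[-15:] == protein[-15:]

    def test_unflagged_transcript_is_error(self):
        t = Transcript("t", "ATGAAATAA")
        with pytest.raises(ValueError):
            correct_frameshift_naive(t, [_hit("t", "g", 1, 1, 6)])

    def test_three_evidence_frames_unsupported(self):
        t = Transcript("t", "A" * 90)
        hsps = [_hit("t", "g", 1, 1, 30), _hit("t", "g", 2, 32, 61),
                _hit("t", "g", 3, 63, 89)]
        assert correct_frameshift_naive(t, hsps) is None

    def test_overlapping_blocks_rejected(self):
        t = Transcript("t", "A" * 90)
        hsps = [_hit("t", "g", 1, 1, 60), _hit("t", "g", 2, 32, 88)]
        assert correct_frameshift_naive(t, hsps) is None

    def test_minus_strand_correction(self):
        protein, mutated = self._shifted_case()
        t = Transcript("t", reverse_complement(mutated))
        db = SearchDatabase({"src": protein})
        hits = db.search(t, evalue_cutoff=1e-3)
        corrected = correct_frameshift_naive(t, hits)
        assert corrected is not None
        t2 = Transcript("t2", corrected)
        call2 = call_orf(t2, db.search(t2, evalue_cutoff=1e-3))
        assert not call2.frameshift_flagged
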