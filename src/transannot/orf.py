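"""ORF calling and frameshift flagging from translated-alignment frames.

The frame evidence for a transcript comes from the HSPs of its single
best similarity hit.  If every HSP reports the same frame, the longest
open reading frame in that frame is extracted; if the best hit aligns
in two or more different frames the transcript is flagged as a putative
frameshift and the longest ORF over all six frames is kept instead.

An ORF here is the longest stop-codon-free run of codons; whether it
starts with ATG and whether it is terminated by an in-frame stop inside
the transcript are recorded separately as metadata.

A naive corrector is included for the common single-indel case: when
the two evidence frames partition the transcript into a 5' and a 3' HSP
block, inserting one or two N characters between the blocks restores a
single reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Hsp
from .search import reverse_complement, translate_frame

__all__ = [
    "OrfCall",
    "frame_statistics",
    "longest_orf_in_frame",
    "call_orf",
    "best_hit_hsps",
    "correct_frameshift_naive",
    "FRAME_ORDER",
]

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass
class OrfCall:
    """One transcript's ORF call.

    ``orf_start``/``orf_end`` are 0-based half-open on the input strand;
    for minus frames the translation reads from the reverse complement.
    """

    transcript_id: str
    frame: int | None
    orf_start: int
    orf_end: int
    protein: str
    has_start: bool
    has_stop: bool
    frameshift_flagged: bool = False
    evidence_frames: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if (self.orf_end - self.orf_start) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain stops")
        if self.frameshift_flagged != (len(self.evidence_frames) >= 2):
            raise ValueError(
                "frameshift_flagged must equal |evidence_frames| >= 2"
            )

    @property
    def orf_len_nt(self) -> int:
        return self.orf_end - self.orf_start


def frame_statistics(hsps: Sequence[Hsp]) -> tuple[frozenset[int], bool]:
    """Evidence frames of the best hit's HSPs and their consistency.

    All HSPs must belong to one (transcript, subject) pair; an empty
    list is a caller error.
    """
    if not hsps:
        raise ValueError("frame_statistics requires at least one HSP")
    pairs = {(h.qid, h.sid) for h in hsps}
    if len(pairs) > 1:
        raise ValueError(f"HSPs span multiple query/subject pairs: {sorted(pairs)}")
    frames = frozenset(h.qframe for h in hsps)
    return frames, len(frames) == 1


def longest_orf_in_frame(seq: str, frame: int,
                         transcript_id: str = "") -> OrfCall:
    """Longest stop-free codon run in one frame.

    Ties go to the 5'-most run in reading direction.  ``has_start`` is
    true when the run's first codon is ATG; ``has_stop`` when the run is
    followed by an in-frame stop codon inside the transcript.
    """
    trans = translate_frame(seq, frame)
    L = len(seq)
    if not trans:
        return OrfCall(transcript_id, None, 0, 0, "", False, False)
    # stop-delimited runs over aa indices, as [start, end) pairs
    runs: list[tuple[int, int]] = []
    start = 0
    for i, aa in enumerate(trans):
        if aa == "*":
            runs.append((start, i))
            start = i + 1
    runs.append((start, len(trans)))
    a0, a1 = max(runs, key=lambda r: r[1] - r[0])  # max() keeps 5'-most tie
    off = abs(frame) - 1
    r_start, r_end = off + 3 * a0, off + 3 * a1  # reading-strand nt coords
    if frame > 0:
        orf_start, orf_end = r_start, r_end
    else:
        orf_start, orf_end = L - r_end, L - r_start
    reading = seq if frame > 0 else reverse_complement(seq)
    has_start = reading[r_start:r_start + 3] == "ATG" and a1 > a0
    has_stop = a1 < len(trans) and trans[a1] == "*"
    return OrfCall(transcript_id, frame, orf_start, orf_end,
                   trans[a0:a1], has_start, has_stop)


def _longest_orf_all_frames(seq: str, transcript_id: str) -> OrfCall:
    # strand-symmetric tie-break: longest protein, then lexicographically
    # smallest protein, then frame order — so revcomp(seq) yields the same
    # protein even when two frames tie on length
    calls = [longest_orf_in_frame(seq, frame, transcript_id)
             for frame in FRAME_ORDER]
    return min(
        zip(calls, range(len(FRAME_ORDER))),
        key=lambda pair: (-len(pair[0].protein), pair[0].protein, pair[1]),
    )[0]


def best_hit_hsps(hsps: Iterable[Hsp]) -> list[Hsp]:
    """HSPs of the best subject: highest bit score, ties to smaller sid."""
    hsps = list(hsps)
    if not hsps:
        return []
    best_sid = min(((-h.bitscore, h.sid) for h in hsps))[1]
    return [h for h in hsps if h.sid == best_sid]


def call_orf(transcript, hsps: Sequence[Hsp]) -> OrfCall:
    """ORF call for one transcript given its similarity hits.

    ``hsps`` may contain hits to several subjects; frame evidence is
    taken from the best subject only.  With consistent evidence the ORF
    is extracted in that frame; with conflicting evidence the transcript
    is flagged and the longest ORF over all six frames is kept.
    Hitless transcripts also get the all-frame longest ORF, unflagged
    and with frame recorded as None.
    """
    best = best_hit_hsps(hsps)
    if not best:
        call = _longest_orf_all_frames(transcript.seq, transcript.id)
        call = OrfCall(transcript.id, None, call.orf_start, call.orf_end,
                       call.protein, call.has_start, call.has_stop)
        _check_translation(transcript.seq, call)
        return call
    frames, consistent = frame_statistics(best)
    if consistent:
        (frame,) = frames
        call = longest_orf_in_frame(transcript.seq, frame, transcript.id)
        call.evidence_frames = frames
    else:
        base = _longest_orf_all_frames(transcript.seq, transcript.id)
        call = OrfCall(transcript.id, base.frame, base.orf_start, base.orf_end,
                       base.protein, base.has_start, base.has_stop,
                       frameshift_flagged=True, evidence_frames=frames)
    _check_translation(transcript.seq, call)
    return call


def _check_translation(seq: str, call: OrfCall) -> None:
    # hard invariant: the reported region re-translates to the protein
    region = seq[call.orf_start:call.orf_end]
    if not region and not call.protein:
        return
    forward = translate_frame(region, 1) if len(region) >= 3 else ""
    reverse = translate_frame(region, -1) if len(region) >= 3 else ""
    if call.frame is None:
        ok = call.protein in (forward, reverse)
    else:
        ok = call.protein == (forward if call.frame > 0 else reverse)
    if not ok:
        raise AssertionError(
            f"{call.transcript_id}: ORF region does not translate to the "
            f"reported protein"
        )


def correct_frameshift_naive(transcript, hsps: Sequence[Hsp]) -> str | None:
    """Single-indel frame correction by N-padding between HSP blocks.

    Applicable when the best hit's HSPs show exactly two frames on the
    same strand and separate cleanly into a 5' and a 3' block on the
    transcript.  One or two ``N`` characters are inserted at the midpoint
    between the blocks so the downstream block's frame becomes congruent
    with the upstream one.  Returns the corrected sequence, or None when
    the evidence does not fit the single-indel model.
    """
    best = best_hit_hsps(hsps)
    if not best:
        raise ValueError("correction requires similarity hits")
    frames, consistent = frame_statistics(best)
    if consistent:
        raise ValueError("transcript is not frameshift-flagged")
    if len(frames) != 2:
        return None
    f1, f2 = sorted(frames)
    if (f1 > 0) != (f2 > 0):
        return None  # mixed strands: not a simple indel
    seq = transcript.seq
    L = len(seq)
    minus = f1 < 0

    def reading_interval(h: Hsp) -> tuple[int, int]:
        lo, hi = h.q_interval
        return (L - hi, L - lo) if minus else (lo, hi)

    groups: dict[int, list[tuple[int, int]]] = {}
    for h in best:
        groups.setdefault(abs(h.qframe), []).append(reading_interval(h))
    ga, gb = (groups[k] for k in sorted(groups))
    # order the two frame groups along the reading strand
    if max(e for _, e in ga) <= min(s for s, _ in gb):
        up, down = ga, gb
        up_frame, down_frame = sorted(groups)
    elif max(e for _, e in gb) <= min(s for s, _ in ga):
        up, down = gb, ga
        down_frame, up_frame = sorted(groups)
    else:
        return None  # blocks overlap
    o_up, o_down = up_frame - 1, down_frame - 1
    k = (o_up - o_down) % 3
    if k not in (1, 2):
        return None
    pos = (max(e for _, e in up) + min(s for s, _ in down)) // 2
    reading = seq if not minus else reverse_complement(seq)
    corrected = reading[:pos] + "N" * k + reading[pos:]
    return reverse_complement(corrected) if minus else corrected
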