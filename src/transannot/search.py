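"""Six-frame translated local search against a reference proteome.

A transcript is translated in all six reading frames and each
translation is aligned locally (Smith-Waterman, BLOSUM62, affine gaps)
against the reference proteins.  An exact-match amino-acid seed index
restricts the dynamic programming to (frame, subject) pairs that share
at least one k-mer; pairs with no shared word cannot produce a
reportable alignment at the default score floor in practice, and the
full alignment is still exact for every pair that is scored.

Scores are converted to bit scores and E-values with the standard
Karlin-Altschul statistics for gapped BLOSUM62 alignments
(lambda = 0.267, K = 0.041), so output is interchangeable with external
BLASTX/RapSearch2 tabular files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .io_formats import Hsp, Transcript

__all__ = [
    "ScoringScheme",
    "SearchDatabase",
    "six_frame_translate",
    "translate_frame",
    "reverse_complement",
    "search",
    "raw_to_bitscore",
    "raw_to_evalue",
]

KA_LAMBDA = 0.267
KA_K = 0.041

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC DNA alphabet (unknown -> N)."""
    return "".join(
        c if c in "ACGTNRYSWKMBDHV" else "N" for c in seq
    ).translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, frame: int) -> str:
    """Translate one reading frame with the standard genetic code.

    Frames +1..+3 read ``seq[frame-1:]`` codon-wise; -1..-3 read the
    reverse complement the same way.  Stop codons are rendered ``*`` and
    any codon containing a non-ACGT character becomes ``X``.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"invalid frame {frame}")
    s = seq if frame > 0 else reverse_complement(seq)
    offset = abs(frame) - 1
    aa = []
    for i in range(offset, len(s) - 2, 3):
        aa.append(_CODON_TO_AA.get(s[i:i + 3], "X"))
    return "".join(aa)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six frame translations keyed by frame."""
    return {f: translate_frame(seq, f) for f in (1, 2, 3, -1, -2, -3)}


@dataclass
class ScoringScheme:
    """Alignment scoring and reporting parameters.

    ``gap_open`` and ``gap_extend`` follow the BLAST convention: a gap of
    length g costs ``gap_open + g * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_raw_score: int = 40
    max_hsps_per_pair: int = 10
    max_subjects_per_query: int = 50
    seed_length: int = 5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        self.matrix = substitution_matrices.load(self.matrix_name)

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def raw_to_bitscore(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def raw_to_evalue(raw: float, query_len: int, db_residues: int) -> float:
    return KA_K * query_len * db_residues * math.exp(-KA_LAMBDA * raw)


def _sanitize_protein(seq: str) -> str:
    s = seq.upper()
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in s)


class SearchDatabase:
    """Reference proteins indexed for translated search.

    Parameters
    ----------
    proteins:
        Mapping of gene id to amino-acid sequence.
    scheme:
        Scoring parameters; defaults mirror common translated-search
        settings (BLOSUM62, 11/1 affine gaps).
    """

    def __init__(self, proteins: dict[str, str],
                 scheme: ScoringScheme | None = None) -> None:
        if not proteins:
            raise ValueError("search database must be non-empty")
        self.scheme = scheme or ScoringScheme()
        self.proteins = {sid: _sanitize_protein(s) for sid, s in proteins.items()}
        self.total_residues = sum(len(s) for s in self.proteins.values())
        k = self.scheme.seed_length
        index: dict[str, list[str]] = {}
        for sid in sorted(self.proteins):
            seq = self.proteins[sid]
            seen: set[str] = set()
            for i in range(len(seq) - k + 1):
                word = seq[i:i + k]
                if word not in seen:
                    index.setdefault(word, []).append(sid)
                    seen.add(word)
        self._index = index
        self._aligner = self.scheme.make_aligner()

    def _candidates(self, translation: str) -> list[str]:
        k = self.scheme.seed_length
        if len(translation) < k:
            return sorted(self.proteins)
        hit: set[str] = set()
        for i in range(len(translation) - k + 1):
            sids = self._index.get(translation[i:i + k])
            if sids:
                hit.update(sids)
        return sorted(hit)

    def raw_score(self, query_aa: str, subject_aa: str) -> int:
        """Exact Smith-Waterman raw score of two amino-acid strings."""
        if not query_aa or not subject_aa:
            return 0
        return int(self._aligner.score(_sanitize_protein(query_aa),
                                       _sanitize_protein(subject_aa)))

    def search(self, query: Transcript,
               evalue_cutoff: float | None = None) -> list[Hsp]:
        """All reportable HSPs for one transcript, best-first.

        Sorting is canonical (bitscore desc, evalue asc, subject id) and
        hit counts are capped per the scheme, so results are
        deterministic regardless of database insertion order.
        """
        hsps: list[Hsp] = []
        L = len(query.seq)
        for frame, trans in six_frame_translate(query.seq).items():
            if not trans:
                continue
            for sid in self._candidates(trans):
                subject = self.proteins[sid]
                if not subject:
                    continue
                raw = self._aligner.score(trans, subject)
                if raw < self.scheme.min_raw_score:
                    continue
                evalue = raw_to_evalue(raw, len(trans), self.total_residues)
                if evalue_cutoff is not None and evalue > evalue_cutoff:
                    continue
                aln = self._aligner.align(trans, subject)[0]
                hsps.append(self._hsp_from_alignment(
                    query.id, sid, frame, L, raw, evalue, aln))
        hsps.sort(key=lambda h: (-h.bitscore, h.evalue, h.sid, h.qstart))
        return self._apply_caps(hsps)

    def _apply_caps(self, hsps: list[Hsp]) -> list[Hsp]:
        kept: list[Hsp] = []
        per_pair: dict[tuple[str, str], int] = {}
        subjects: list[str] = []
        for h in hsps:
            if h.sid not in subjects:
                if len(subjects) >= self.scheme.max_subjects_per_query:
                    continue
                subjects.append(h.sid)
            pair = (h.qid, h.sid)
            if per_pair.get(pair, 0) >= self.scheme.max_hsps_per_pair:
                continue
            per_pair[pair] = per_pair.get(pair, 0) + 1
            kept.append(h)
        return kept

    def _hsp_from_alignment(self, qid: str, sid: str, frame: int,
                            transcript_len: int, raw: float, evalue: float,
                            aln) -> Hsp:
        qblocks, sblocks = aln.aligned
        qa_start, qa_end = int(qblocks[0][0]), int(qblocks[-1][1])
        sa_start, sa_end = int(sblocks[0][0]), int(sblocks[-1][1])
        counts = aln.counts()
        identities, mismatches = counts.identities, counts.mismatches
        gap_cols = counts.gaps
        aln_len = identities + mismatches + gap_cols
        gapopen = 0
        for i in range(1, len(qblocks)):
            if qblocks[i][0] > qblocks[i - 1][1]:
                gapopen += 1
            if sblocks[i][0] > sblocks[i - 1][1]:
                gapopen += 1
        # aa coordinates on the frame translation -> nt on the input strand
        off = abs(frame) - 1
        nt_start = off + 3 * qa_start          # 0-based inclusive
        nt_end = off + 3 * qa_end              # 0-based exclusive
        if frame > 0:
            qstart, qend = nt_start + 1, nt_end
        else:
            qstart = transcript_len - nt_start      # larger coordinate
            qend = transcript_len - nt_end + 1
        pident = 100.0 * identities / aln_len if aln_len else 0.0
        return Hsp(
            qid=qid, sid=sid, pident=round(pident, 2), length=aln_len,
            mismatch=mismatches, gapopen=gapopen,
            qstart=qstart, qend=qend, sstart=sa_start + 1, send=sa_end,
            evalue=evalue, bitscore=round(raw_to_bitscore(raw), 1),
            qframe=frame,
        )


def search(query: Transcript, proteins: dict[str, str],
           scheme: ScoringScheme | None = None,
           evalue_cutoff: float | None = None) -> list[Hsp]:
    """One-shot translated search of a single transcript (convenience)."""
    return SearchDatabase(proteins, scheme).search(query, evalue_cutoff)


def search_all(queries: Sequence[Transcript], db: SearchDatabase,
               evalue_cutoff: float | None = None) -> list[Hsp]:
    """Search every transcript; HSPs grouped by query in input order."""
    out: list[Hsp] = []
    for q in queries:
        out.extend(db.search(q, evalue_cutoff))
    return out
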