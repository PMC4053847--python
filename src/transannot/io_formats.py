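"""File formats and core domain records.

Everything the pipeline reads or writes goes through this module: FASTA
sequences, similarity-search hit tables in the 12/13-column BLAST tabular
dialect, and tab-separated tables for gene families, functional
annotations and transcript subset labels.

Conventions
-----------
* External tables use 1-based inclusive coordinates (BLAST convention);
  internal code uses 0-based half-open intervals.  Conversion happens
  only here.
* Nucleotide sequences are uppercased on read and ``U`` is mapped to
  ``T``; IUPAC ambiguity codes other than ``N`` are tolerated and treated
  as ``N`` at translation time.
* Hits failing the E-value cutoff are dropped at read time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Transcript",
    "ReferenceGene",
    "Hsp",
    "read_fasta",
    "write_fasta",
    "read_hits_table",
    "write_hits_table",
    "read_family_table",
    "write_family_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_labels",
    "write_labels",
    "derive_qframe",
]

_DNA_CANONICAL = set("ACGTN")
_IUPAC_EXTRA = set("RYSWKMBDHV")


@dataclass
class Transcript:
    """One assembled transcript of an experiment."""

    id: str
    seq: str
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        for label in self.labels:
            if "\t" in label:
                raise ValueError(f"transcript {self.id!r}: label contains a tab")


@dataclass
class ReferenceGene:
    """One reference-proteome gene with optional family and term content."""

    id: str
    species: str = ""
    family_id: str | None = None
    cds_length_nt: int = 3
    protein_seq: str | None = None
    terms: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if self.cds_length_nt < 3:
            raise ValueError(f"gene {self.id!r}: cds_length_nt must be >= 3")
        for _, term_type in self.terms:
            if term_type not in ("GO", "domain"):
                raise ValueError(
                    f"gene {self.id!r}: term_type must be 'GO' or 'domain', got {term_type!r}"
                )


@dataclass
class Hsp:
    """One local translated-alignment segment (high-scoring segment pair).

    Transcript coordinates ``qstart``/``qend`` are 1-based inclusive as in
    BLAST tabular output; for minus-strand hits ``qstart > qend``.
    """

    qid: str
    sid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qframe: int

    def __post_init__(self) -> None:
        if self.qframe not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid qframe {self.qframe}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.qstart != self.qend:
            strand_plus = self.qstart < self.qend
            if strand_plus != (self.qframe > 0):
                raise ValueError(
                    f"hsp {self.qid}->{self.sid}: qframe sign does not match "
                    f"coordinate orientation"
                )

    @property
    def q_interval(self) -> tuple[int, int]:
        """0-based half-open interval on the input transcript strand."""
        lo, hi = sorted((self.qstart, self.qend))
        return lo - 1, hi


def _normalize_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, kind: str = "dna") -> list[Transcript]:
    """Read a FASTA file into :class:`Transcript` records.

    ``kind="dna"`` normalizes the alphabet (uppercase, U->T); with
    ``kind="protein"`` sequences are only uppercased.  Duplicate or empty
    records are hard errors.
    """
    if kind not in ("dna", "protein"):
        raise ValueError("kind must be 'dna' or 'protein'")
    records: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty record {rid!r}")
        seq = _normalize_dna(seq) if kind == "dna" else seq.upper()
        records.append(Transcript(id=rid, seq=seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]] | Iterable[Transcript],
                path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, Transcript) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def derive_qframe(qstart: int, qend: int, transcript_length: int) -> int:
    """Reading frame implied by 1-based transcript alignment coordinates.

    Plus strand (``qstart < qend``): ``((qstart - 1) mod 3) + 1``.
    Minus strand (``qstart > qend``), with ``qstart`` the larger coordinate
    and ``L`` the transcript length: ``-(((L - qstart) mod 3) + 1)``.
    """
    if qstart <= qend:
        return ((qstart - 1) % 3) + 1
    return -(((transcript_length - qstart) % 3) + 1)


def read_hits_table(
    path: str | Path,
    transcript_lengths: dict[str, int] | None = None,
    evalue_cutoff: float | None = None,
) -> list[Hsp]:
    """Read a 12- or 13-column BLAST/RapSearch2 tabular hit file.

    Column order: qid sid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore [qframe].  When the explicit 13th column
    is absent the frame is derived from the coordinates, which requires
    the transcript length for minus-strand rows.
    """
    hsps: list[Hsp] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                length, mismatch, gapopen = (int(parts[i]) for i in (3, 4, 5))
                qstart, qend, sstart, send = (int(parts[i]) for i in (6, 7, 8, 9))
                evalue, bitscore = float(parts[10]), float(parts[11])
                qframe = int(parts[12]) if len(parts) == 13 else None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if qframe is None:
                if transcript_lengths is None or qid not in transcript_lengths:
                    raise ValueError(
                        f"{path}:{lineno}: no qframe column and unknown "
                        f"transcript length for {qid!r}"
                    )
                qframe = derive_qframe(qstart, qend, transcript_lengths[qid])
            if evalue_cutoff is not None and evalue > evalue_cutoff:
                continue
            hsps.append(Hsp(qid, sid, pident, length, mismatch, gapopen,
                            qstart, qend, sstart, send, evalue, bitscore, qframe))
    return hsps


def write_hits_table(hsps: Iterable[Hsp], path: str | Path,
                     with_qframe: bool = True) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            cols = [h.qid, h.sid, f"{h.pident:.2f}", h.length, h.mismatch,
                    h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                    _format_evalue(h.evalue), f"{h.bitscore:.1f}"]
            if with_qframe:
                cols.append(h.qframe)
            fh.write("\t".join(str(c) for c in cols) + "\n")


def _format_evalue(e: float) -> str:
    # repr round-trips exactly; still a plain numeric field
    return repr(e)


def _read_tsv(path: str | Path, expected_header: Sequence[str]) -> list[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != list(expected_header):
            raise ValueError(
                f"{path}: expected header {list(expected_header)}, got {header}"
            )
        rows = []
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise ValueError(f"{path}:{lineno}: ragged row ({len(row)} fields)")
            rows.append(row)
    return rows


FAMILY_HEADER = ["gene_id", "species", "family_id", "cds_length_nt"]
ANNOTATION_HEADER = ["gene_id", "term_id", "term_type"]
LABEL_HEADER = ["transcript_id", "label"]


def read_family_table(path: str | Path) -> dict[str, ReferenceGene]:
    """Read gene-family membership; returns gene id -> :class:`ReferenceGene`."""
    genes: dict[str, ReferenceGene] = {}
    for gid, species, fam, cds_len in _read_tsv(path, FAMILY_HEADER):
        if gid in genes:
            raise ValueError(f"{path}: duplicate gene id {gid!r}")
        genes[gid] = ReferenceGene(
            id=gid, species=species,
            family_id=fam if fam else None,
            cds_length_nt=int(cds_len),
        )
    return genes


def write_family_table(genes: Iterable[ReferenceGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FAMILY_HEADER) + "\n")
        for g in genes:
            fh.write(f"{g.id}\t{g.species}\t{g.family_id or ''}\t{g.cds_length_nt}\n")


def read_annotation_table(path: str | Path) -> dict[str, set[tuple[str, str]]]:
    """Read functional annotations; returns gene id -> set of (term_id, term_type)."""
    terms: dict[str, set[tuple[str, str]]] = {}
    for gid, term_id, term_type in _read_tsv(path, ANNOTATION_HEADER):
        if term_type not in ("GO", "domain"):
            raise ValueError(f"{path}: invalid term_type {term_type!r} for {gid!r}")
        terms.setdefault(gid, set()).add((term_id, term_type))
    return terms


def write_annotation_table(terms: dict[str, set[tuple[str, str]]],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for gid in sorted(terms):
            for term_id, term_type in sorted(terms[gid]):
                fh.write(f"{gid}\t{term_id}\t{term_type}\n")


def read_labels(path: str | Path) -> dict[str, set[str]]:
    """Read subset labels; returns transcript id -> set of labels."""
    labels: dict[str, set[str]] = {}
    for tid, label in _read_tsv(path, LABEL_HEADER):
        labels.setdefault(tid, set()).add(label)
    return labels


def write_labels(labels: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LABEL_HEADER) + "\n")
        for tid in sorted(labels):
            for label in sorted(labels[tid]):
                fh.write(f"{tid}\t{label}\n")
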