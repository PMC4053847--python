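"""Gap-column editing of multiple sequence alignments.

Before tree building, alignment columns dominated by gaps are removed:
stringent editing drops columns whose gap fraction is strictly above
10%, together with a configurable number of flanking columns on each
side; relaxed editing drops columns with a gap fraction of at least
25%, with no flanks.  Rows belonging to Partial transcripts or to
excluded species can additionally be dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Msa",
    "read_alignment",
    "write_alignment",
    "edit_alignment",
    "drop_partial_rows",
    "drop_species_rows",
]


@dataclass
class Msa:
    """An aligned set of amino-acid sequences ('-' for gaps)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate row ids in alignment")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(widths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)


def read_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file; '.' gap characters are normalized to '-'."""
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-"))
            for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return Msa(rows)


def write_alignment(msa: Msa, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def edit_alignment(msa: Msa, mode: str = "stringent",
                   config: PipelineConfig | None = None
                   ) -> tuple[Msa, list[int]]:
    """Remove gap-dominated columns; returns the edited alignment and the
    removed column indices (0-based, ascending).

    stringent: columns with gap fraction strictly greater than the
    stringent threshold are marked, plus ``flank_width`` columns on each
    side of every marked column.  relaxed: columns with gap fraction at
    or above the relaxed threshold; no flanks.
    """
    if mode not in ("stringent", "relaxed"):
        raise ValueError(f"invalid editing mode {mode!r}")
    config = config or PipelineConfig()
    if not msa.rows:
        raise ValueError("empty alignment")
    nrow, ncol = msa.nrow, msa.ncol
    marked: set[int] = set()
    for j in range(ncol):
        gaps = sum(1 for _, seq in msa.rows if seq[j] == "-")
        frac = gaps / nrow
        if mode == "stringent":
            if frac > config.stringent_gap_threshold:
                marked.add(j)
        elif frac >= config.relaxed_gap_threshold:
            marked.add(j)
    removed: set[int] = set(marked)
    if mode == "stringent":
        for j in marked:
            for d in range(1, config.flank_width + 1):
                if j - d >= 0:
                    removed.add(j - d)
                if j + d < ncol:
                    removed.add(j + d)
    keep = [j for j in range(ncol) if j not in removed]
    edited = Msa([(rid, "".join(seq[j] for j in keep)) for rid, seq in msa.rows])
    if ncol and not keep:
        logger.warning("editing removed every alignment column")
    return edited, sorted(removed)


def drop_partial_rows(msa: Msa, meta_labels: Mapping[str, str]) -> Msa:
    """Remove rows whose transcript is meta-annotated Partial.

    Rows without a meta label (reference genes) are always kept.
    """
    rows = [(rid, seq) for rid, seq in msa.rows
            if meta_labels.get(rid) != "Partial"]
    return Msa(rows)


def drop_species_rows(msa: Msa, species_excluded: Iterable[str],
                      species_of: Mapping[str, str]) -> Msa:
    """Remove rows of excluded species; rows of unknown species are kept."""
    excluded = set(species_excluded)
    rows = [(rid, seq) for rid, seq in msa.rows
            if species_of.get(rid) not in excluded]
    if not rows:
        logger.warning("species filtering removed every alignment row")
    return Msa(rows)
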