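"""Completeness meta-annotation and homology-based functional transfer.

Meta-annotation compares a transcript's ORF length (in nucleotides) to
the coding-sequence lengths of its assigned gene family: the family
lengths are sorted, the longest and shortest 10% removed, and the mean
and standard deviation of the remainder computed.  ORFs shorter than
mean minus two standard deviations are Partial; otherwise Quasi Full
Length, upgraded to Full Length when the ORF has both a start and a
stop codon.  Families smaller than five members give No Information.

Functional transfer takes the GO terms and protein domains carried by
at least half of the family members (consensus), the best hit's own
terms, or the union of both.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "MetaAnnotation",
    "TransferredAnnotation",
    "META_LABELS",
    "meta_annotate",
    "transfer_annotation",
]

META_LABELS = ("No Information", "Partial", "Quasi Full Length", "Full Length")


@dataclass
class MetaAnnotation:
    """Completeness label for one transcript with the statistics behind it."""

    transcript_id: str
    label: str
    trimmed_mean: float | None = None
    trimmed_sd: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.label not in META_LABELS:
            raise ValueError(f"invalid meta-annotation label {self.label!r}")


@dataclass
class TransferredAnnotation:
    """Functional terms transferred to one transcript."""

    transcript_id: str
    terms: set[tuple[str, str]] = field(default_factory=set)
    source: str = "family_consensus"

    def __post_init__(self) -> None:
        if self.source not in ("family_consensus", "best_hit", "both"):
            raise ValueError(f"invalid transfer source {self.source!r}")


def trimmed_length_stats(family_cds_lengths: Sequence[int],
                         trim_fraction: float) -> tuple[float, float]:
    """Mean and sample SD of family CDS lengths after two-sided trimming.

    ``floor(trim_fraction * n)`` values are removed from each end of the
    sorted lengths.  If fewer than two values would remain, the
    untrimmed lengths are used instead (with a warning).
    """
    lengths = sorted(int(x) for x in family_cds_lengths)
    n = len(lengths)
    cut = int(trim_fraction * n)
    kept = lengths[cut:n - cut] if cut else lengths
    if len(kept) < 2:
        logger.warning(
            "trimming left %d of %d lengths; falling back to untrimmed stats",
            len(kept), n,
        )
        kept = lengths
    if len(kept) < 2:
        return float(kept[0]), 0.0
    return statistics.mean(kept), statistics.stdev(kept)


def meta_annotate(orf_len_nt: int, family_cds_lengths: Sequence[int] | None,
                  has_start: bool, has_stop: bool,
                  config: PipelineConfig | None = None,
                  transcript_id: str = "") -> MetaAnnotation:
    """Completeness label from trimmed family CDS-length statistics."""
    config = config or PipelineConfig()
    if orf_len_nt < 0:
        raise ValueError("orf_len_nt must be >= 0")
    if (family_cds_lengths is None
            or len(family_cds_lengths) < config.min_family_size_meta):
        return MetaAnnotation(transcript_id, "No Information")
    mean, sd = trimmed_length_stats(family_cds_lengths, config.trim_fraction)
    threshold = mean - config.sd_multiplier * sd
    if orf_len_nt < threshold:
        label = "Partial"
    elif has_start and has_stop:
        label = "Full Length"
    else:
        label = "Quasi Full Length"
    return MetaAnnotation(transcript_id, label, mean, sd, threshold)


def transfer_annotation(
    family_terms: Iterable[set[tuple[str, str]]] | None,
    best_hit_terms: set[tuple[str, str]] | None,
    source: str = "family_consensus",
    config: PipelineConfig | None = None,
    transcript_id: str = "",
) -> TransferredAnnotation:
    """Transfer functional terms by family consensus and/or best hit.

    ``family_terms`` is one term set per family member (members without
    annotation contribute an empty set — the consensus denominator is
    the family size, not the number of annotated members).  A term
    qualifies for consensus transfer when carried by at least
    ``consensus_fraction`` of the members.
    """
    config = config or PipelineConfig()
    if source not in ("family_consensus", "best_hit", "both"):
        raise ValueError(f"invalid transfer source {source!r}")
    terms: set[tuple[str, str]] = set()
    if source in ("family_consensus", "both") and family_terms is not None:
        member_terms = list(family_terms)
        size = len(member_terms)
        counts: dict[tuple[str, str], int] = {}
        for member in member_terms:
            for term in member:
                counts[term] = counts.get(term, 0) + 1
        if size:
            terms |= {t for t, c in counts.items()
                      if c / size >= config.consensus_fraction}
    if source in ("best_hit", "both") and best_hit_terms:
        terms |= set(best_hit_terms)
    return TransferredAnnotation(transcript_id, terms, source)
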