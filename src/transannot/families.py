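"""Gene-family assignment from ranked similarity hits.

Two assignment rules are provided, matching how reference databases are
typically used: best-hit (take the family of the single top hit; suited
to species/clade proteomes) and top-k majority voting (suited to reduced
family-representative databases).  A per-species family representative
selector picks the most central member of a similarity graph, for
building such reduced databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Hsp, ReferenceGene

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyAssignment",
    "SimilarityGraph",
    "rank_hits",
    "assign_best_hit",
    "assign_majority",
    "select_representatives",
]


@dataclass
class FamilyAssignment:
    """Outcome of assigning one transcript to a gene family."""

    transcript_id: str
    family_id: str | None
    method: str  # "best_hit" | "majority_topk"
    votes: dict[str, int] = field(default_factory=dict)
    best_hit_id: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("best_hit", "majority_topk"):
            raise ValueError(f"invalid method {self.method!r}")
        if self.family_id is not None and self.votes.get(self.family_id, 0) < 1:
            raise ValueError("assigned family must carry at least one vote")


@dataclass
class SimilarityGraph:
    """Undirected similarity graph: genes as nodes, bit scores as edge weights."""

    species_of: dict[str, str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on {a!r}-{b!r}")


def rank_hits(hsps: Iterable[Hsp]) -> list[Hsp]:
    """Canonical best-first hit order: bitscore desc, evalue asc, subject id."""
    return sorted(hsps, key=lambda h: (-h.bitscore, h.evalue, h.sid, h.qstart))


def _family_of(sid: str, family_map: dict[str, ReferenceGene]) -> str | None:
    gene = family_map.get(sid)
    if gene is None:
        logger.warning("hit subject %r absent from family map; skipped", sid)
        return None
    return gene.family_id


def assign_best_hit(hits: Sequence[Hsp], family_map: dict[str, ReferenceGene],
                    transcript_id: str | None = None) -> FamilyAssignment:
    """Assign the family of the top-ranked hit whose subject is mapped.

    Hits whose subject is absent from the family map are skipped with a
    warning; with no usable hits the transcript gets no family (and,
    downstream, no functional annotation).
    """
    hits = rank_hits(hits)
    tid = hits[0].qid if hits else (transcript_id or "")
    for h in hits:
        fam = _family_of(h.sid, family_map)
        if fam is not None:
            return FamilyAssignment(h.qid, fam, "best_hit",
                                    votes={fam: 1}, best_hit_id=h.sid)
    return FamilyAssignment(tid, None, "best_hit")


def assign_majority(hits: Sequence[Hsp], family_map: dict[str, ReferenceGene],
                    k: int = 5, transcript_id: str | None = None) -> FamilyAssignment:
    """Majority vote over the families of the top ``k`` mappable hits.

    Ties are broken in favour of the tied family containing the single
    best-scoring hit (i.e. the one appearing earliest in the ranked
    list).  ``k=1`` reduces exactly to :func:`assign_best_hit`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = rank_hits(hits)
    tid = hits[0].qid if hits else (transcript_id or "")
    considered: list[tuple[str, str]] = []  # (family, sid) in rank order
    for h in hits:
        if len(considered) >= k:
            break
        fam = _family_of(h.sid, family_map)
        if fam is not None:
            considered.append((fam, h.sid))
    if not considered:
        return FamilyAssignment(tid, None, "majority_topk")
    votes: dict[str, int] = {}
    for fam, _ in considered:
        votes[fam] = votes.get(fam, 0) + 1
    top = max(votes.values())
    tied = {fam for fam, c in votes.items() if c == top}
    winner = next(fam for fam, _ in considered if fam in tied)
    return FamilyAssignment(tid, winner, "majority_topk",
                            votes=votes, best_hit_id=considered[0][1])


def select_representatives(graph: SimilarityGraph,
                           members: Iterable[str]) -> dict[str, str]:
    """Per species, the family member with maximal weighted degree.

    Centrality of a member is the sum of bit scores on its edges to
    other family members; ties go to the lexicographically smallest gene
    id and isolated members have centrality 0.  Species with no members
    are absent from the output.
    """
    members = set(members)
    degree: dict[str, float] = {m: 0.0 for m in members}
    for a, b, w in graph.edges:
        if a in members and b in members:
            degree[a] += w
            degree[b] += w
    best: dict[str, tuple[float, str]] = {}
    for gene in sorted(members):
        sp = graph.species_of.get(gene)
        if sp is None:
            raise KeyError(f"no species recorded for gene {gene!r}")
        cur = best.get(sp)
        if cur is None or degree[gene] > cur[0]:
            best[sp] = (degree[gene], gene)
    return {sp: gene for sp, (_, gene) in sorted(best.items())}
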