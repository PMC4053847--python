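"""Functional-term enrichment in labelled transcript subsets.

Each labelled subset is tested against the whole experiment (the
background is every uploaded transcript, not a genome): for each term
observed in the subset, the upper-tail hypergeometric probability
P(X >= k) of drawing k or more term-carrying transcripts in a subset of
size n from a background of N transcripts of which K carry the term.
Raw p-values are Bonferroni-corrected by the number of terms tested for
that label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_upper", "enrich_subsets", "query_terms"]

_EXACT_N_LIMIT = 1000


@dataclass
class EnrichmentResult:
    """One (subset label, term) enrichment test."""

    label: str
    term_id: str
    term_type: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term-carrying transcripts among ``n`` drawn without
    replacement from ``N`` of which ``K`` carry the term.  Exact integer
    combinatorics are used for N <= 1000; the scipy survival function
    (log-space stable) otherwise.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    if N <= _EXACT_N_LIMIT:
        total = comb(N, n)
        num = sum(comb(K, i) * comb(N - K, n - i)
                  for i in range(k, min(n, K) + 1))
        return num / total
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_subsets(
    transcript_labels: Mapping[str, set[str]],
    transcript_terms: Mapping[str, set[tuple[str, str]]],
    background_ids: Iterable[str],
    config: PipelineConfig | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every subset-observed term, per label.

    Counting is transcript-level: a transcript counts once per term.
    The Bonferroni factor for a label is the number of distinct terms
    observed in that subset; results are sorted by adjusted p-value,
    then term id.
    """
    config = config or PipelineConfig()
    background = sorted(set(background_ids))
    N = len(background)
    term_carriers: dict[tuple[str, str], set[str]] = {}
    for tid in background:
        for term in transcript_terms.get(tid, ()):  # noqa: B020
            term_carriers.setdefault(term, set()).add(tid)
    labels: dict[str, set[str]] = {}
    for tid, lbls in transcript_labels.items():
        for lbl in lbls:
            labels.setdefault(lbl, set()).add(tid)
    results: list[EnrichmentResult] = []
    for label in sorted(labels):
        subset = labels[label] & set(background)
        n = len(subset)
        if n == 0:
            continue
        observed = sorted(
            {t for tid in subset for t in transcript_terms.get(tid, ())}
        )
        m = len(observed)
        label_results = []
        for term_id, term_type in observed:
            carriers = term_carriers[(term_id, term_type)]
            k = len(carriers & subset)
            K = len(carriers)
            p_raw = hypergeom_upper(k, n, K, N)
            p_adj = min(1.0, m * p_raw)
            label_results.append(EnrichmentResult(
                label, term_id, term_type, k, n, K, N,
                p_raw, p_adj, p_adj < config.alpha,
            ))
        label_results.sort(key=lambda r: (r.p_adj, r.term_id))
        results.extend(label_results)
    return results


def query_terms(
    subset_ids: Iterable[str],
    transcript_terms: Mapping[str, set[tuple[str, str]]],
    term_query: str,
    term_names: Mapping[str, str] | None = None,
) -> list[str]:
    """Transcripts of a subset carrying a term, by id or (optionally) name.

    With a ``term_names`` table, the query also matches any term whose
    name contains the query string (case-insensitive).
    """
    matching_ids = {term_query}
    if term_names:
        q = term_query.lower()
        matching_ids |= {tid for tid, name in term_names.items()
                         if q in name.lower()}
    hits = [tid for tid in sorted(set(subset_ids))
            if any(term in matching_ids
                   for term, _ in transcript_terms.get(tid, ()))]
    if not hits and not any(
        term_query == term for terms in transcript_terms.values()
        for term, _ in terms
    ):
        logger.warning("term %r not found in any transcript annotation", term_query)
    return hits
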