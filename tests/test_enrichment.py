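"""Hypergeometric enrichment of labelled subsets."""

import numpy as np
import pytest

from _oracles import exact_hypergeom_upper
from transannot.enrichment import enrich_subsets, hypergeom_upper, query_terms


class TestHypergeomUpper:
    def test_all_in_subset_worked_example(self):
        # drawing all 5 carriers in a subset of 5 from 20: 1/C(20,5)
        assert hypergeom_upper(5, 5, 5, 20) == pytest.approx(1 / 15504)

    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 7, 3, 20) == 1.0

    def test_degenerate_certainty(self):
        assert hypergeom_upper(4, 4, 4, 4) == 1.0

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            hypergeom_upper(6, 5, 5, 20)
        with pytest.raises(ValueError):
            hypergeom_upper(2, 5, 25, 20)

    def test_matches_exhaustive_enumeration_small_n(self):
        for N in (5, 8, 11):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(0, min(n, K) + 1):
                        expect = float(exact_hypergeom_upper(k, n, K, N))
                        assert hypergeom_upper(k, n, K, N) == \
                            pytest.approx(expect, abs=1e-12)

    def test_exact_and_logspace_paths_agree(self):
        # straddle the exact/scipy switch at N=1000
        for k, n, K in ((10, 100, 80), (3, 50, 200), (25, 120, 300)):
            lo = hypergeom_upper(k, n, K, 1000)
            hi = hypergeom_upper(k, n, K, 1001)
            assert lo == pytest.approx(hi, rel=0.05)


class TestEnrichSubsets:
    def _setup(self):
        background = [f"t{i}" for i in range(20)]
        term = ("GO:0003700", "GO")
        terms = {f"t{i}": {term} for i in range(5)}
        labels = {f"t{i}": {"sub"} for i in range(5)}
        return background, terms, labels

    def test_single_term_worked_example(self):
        background, terms, labels = self._setup()
        (r,) = enrich_subsets(labels, terms, background)
        assert (r.k, r.n, r.K, r.N) == (5, 5, 5, 20)
        assert r.p_raw == pytest.approx(6.4499e-5, rel=1e-3)
        assert r.p_adj == r.p_raw  # m = 1
        assert r.significant

    def test_bonferroni_scales_with_terms_tested(self):
        background, terms, labels = self._setup()
        # add 9 more terms present in the subset -> m = 10
        for i in range(5):
            for j in range(9):
                terms[f"t{i}"] = terms[f"t{i}"] | {(f"GO:x{j}", "GO")}
        results = enrich_subsets(labels, terms, background)
        main = [r for r in results if r.term_id == "GO:0003700"][0]
        assert main.p_adj == pytest.approx(10 * main.p_raw)

    def test_terms_absent_from_subset_not_tested(self):
        background, terms, labels = self._setup()
        terms["t19"] = {("GO:outside", "GO")}  # background-only term
        results = enrich_subsets(labels, terms, background)
        assert {r.term_id for r in results} == {"GO:0003700"}

    def test_empty_subset_gives_no_results(self):
        background, terms, _ = self._setup()
        assert enrich_subsets({"tX": {"sub"}}, terms, background) == []

    def test_adjusted_p_monotone_in_m(self):
        background, terms, labels = self._setup()
        results_m1 = enrich_subsets(labels, terms, background)
        terms2 = {tid: ts | {("GO:extra", "GO")} for tid, ts in terms.items()}
        results_m2 = enrich_subsets(labels, terms2, background)
        p1 = [r for r in results_m1 if r.term_id == "GO:0003700"][0].p_adj
        p2 = [r for r in results_m2 if r.term_id == "GO:0003700"][0].p_adj
        assert p2 >= p1

    def test_type_i_error_calibration_under_permutation(self):
        """Shuffling term carriers against transcripts gives ~5% of raw
        p-values below 0.05 (small permutation count; the full
        calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(99)
        N, n, n_terms = 400, 120, 20
        background = [f"t{i}" for i in range(N)]
        labels = {f"t{i}": {"sub"} for i in range(n)}
        hits = total = 0
        for _ in range(100):
            terms: dict[str, set] = {}
            for j in range(n_terms):
                K = int(rng.integers(40, 161))
                for idx in rng.choice(N, size=K, replace=False):
                    terms.setdefault(f"t{idx}", set()).add((f"GO:{j}", "GO"))
            for r in enrich_subsets(labels, terms, background):
                total += 1
                hits += r.p_raw < 0.05
        assert total == 100 * n_terms
        assert 0.02 <= hits / total <= 0.08


class TestQueryTerms:
    def test_exact_term_id_query(self):
        terms = {"t1": {("GO:0003700", "GO")}, "t2": {("GO:0003700", "GO")},
                 "t3": {("GO:0008150", "GO")}}
        assert query_terms(["t1", "t2", "t3"], terms, "GO:0003700") == \
            ["t1", "t2"]

    def test_name_table_matching(self):
        terms = {"t1": {("GO:0003700", "GO")}}
        names = {"GO:0003700": "transcription factor activity"}
        assert query_terms(["t1"], terms, "transcription factor",
                           term_names=names) == ["t1"]

    def test_unknown_term_empty(self):
        assert query_terms(["t1"], {"t1": {("GO:1", "GO")}}, "GO:none") == []

    def test_empty_subset_empty(self):
        assert query_terms([], {"t1": {("GO:1", "GO")}}, "GO:1") == []
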