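"""Family assignment rules and representative selection."""

import numpy as np
import pytest

from _oracles import weighted_degree_representatives
from transannot.families import (
    SimilarityGraph,
    assign_best_hit,
    assign_majority,
    rank_hits,
    select_representatives,
)
from transannot.io_formats import Hsp, ReferenceGene


def _hit(qid, sid, bitscore, evalue=1e-20, frame=1):
    return Hsp(qid, sid, 90.0, 30, 3, 0, 1, 90, 1, 30, evalue, bitscore, frame)


def _fam_map(mapping):
    return {gid: ReferenceGene(id=gid, species="sp", family_id=fam,
                               cds_length_nt=300)
            for gid, fam in mapping.items()}


class TestBestHit:
    def test_top_hit_family_assigned(self):
        hits = [_hit("t", "g1", 100), _hit("t", "g2", 90)]
        a = assign_best_hit(hits, _fam_map({"g1": "F1", "g2": "F2"}))
        assert a.family_id == "F1" and a.best_hit_id == "g1"
        assert a.votes == {"F1": 1}

    def test_no_hits_gives_no_family(self):
        a = assign_best_hit([], _fam_map({}), transcript_id="t")
        assert a.family_id is None and a.transcript_id == "t"

    def test_unmapped_top_hit_skipped(self):
        hits = [_hit("t", "gX", 100), _hit("t", "g2", 90)]
        a = assign_best_hit(hits, _fam_map({"g2": "F2"}))
        assert a.family_id == "F2"


class TestMajority:
    def test_strict_majority_wins(self):
        fams = {"g1": "F1", "g2": "F1", "g3": "F2", "g4": "F1", "g5": "F3"}
        hits = [_hit("t", g, 100 - i) for i, g in enumerate(fams)]
        a = assign_majority(hits, _fam_map(fams), k=5)
        assert a.family_id == "F1" and a.votes["F1"] == 3

    def test_tie_broken_by_best_hit_family(self):
        fams = {"g1": "F1", "g2": "F2", "g3": "F1", "g4": "F2", "g5": "F3"}
        hits = [_hit("t", g, 100 - i) for i, g in enumerate(fams)]
        a = assign_majority(hits, _fam_map(fams), k=5)
        assert a.family_id == "F1"

    def test_k1_reduces_to_best_hit(self, small_sim_hits, small_sim):
        _, reference, _, _ = small_sim
        for hits in small_sim_hits.values():
            best = assign_best_hit(hits, reference.genes, transcript_id="t")
            major = assign_majority(hits, reference.genes, k=1,
                                    transcript_id="t")
            assert major.family_id == best.family_id
            assert major.best_hit_id == best.best_hit_id

    def test_fewer_hits_than_k(self):
        hits = [_hit("t", "g1", 100)]
        a = assign_majority(hits, _fam_map({"g1": "F1"}), k=5)
        assert a.family_id == "F1"


def test_assignment_invariant_to_row_order():
    rng = np.random.default_rng(3)
    fams = {f"g{i}": f"F{i % 3}" for i in range(8)}
    hits = [_hit("t", g, 100 - i, evalue=10.0 ** -(20 - i))
            for i, g in enumerate(fams)]
    fam_map = _fam_map(fams)
    ref_best = assign_best_hit(hits, fam_map)
    ref_major = assign_majority(hits, fam_map, k=5)
    for _ in range(10):
        shuffled = [hits[i] for i in rng.permutation(len(hits))]
        assert assign_best_hit(shuffled, fam_map) == ref_best
        assert assign_majority(shuffled, fam_map, k=5) == ref_major


class TestRepresentatives:
    def test_weighted_degree_example(self):
        graph = SimilarityGraph(
            {"a": "X", "b": "X", "c": "X"},
            [("a", "b", 100.0), ("a", "c", 90.0), ("b", "c", 10.0)],
        )
        assert select_representatives(graph, {"a", "b", "c"}) == {"X": "a"}

    def test_single_member_species(self):
        graph = SimilarityGraph({"a": "X", "b": "Y"}, [("a", "b", 50.0)])
        assert select_representatives(graph, {"a", "b"}) == {"X": "a", "Y": "b"}

    def test_no_edges_ties_to_smallest_id(self):
        graph = SimilarityGraph({"a": "X", "b": "X"}, [])
        assert select_representatives(graph, {"a", "b"}) == {"X": "a"}

    def test_invariant_to_edge_order(self, rng):
        species = {f"g{i}": f"sp{i % 2}" for i in range(6)}
        edges = [(f"g{i}", f"g{j}", float(rng.integers(1, 200)))
                 for i in range(6) for j in range(i + 1, 6)]
        graph1 = SimilarityGraph(species, edges)
        graph2 = SimilarityGraph(species, edges[::-1])
        members = set(species)
        assert select_representatives(graph1, members) == \
            select_representatives(graph2, members)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            species = {f"g{i:02d}": f"sp{int(rng.integers(3))}"
                       for i in range(n)}
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges.append((f"g{i:02d}", f"g{j:02d}",
                                      float(rng.integers(1, 500))))
            members = set(species)
            got = select_representatives(SimilarityGraph(species, edges),
                                         members)
            assert got == weighted_degree_representatives(species, edges,
                                                          members)

    def test_graph_invariants(self):
        with pytest.raises(ValueError):
            SimilarityGraph({"a": "X"}, [("a", "a", 10.0)])
        with pytest.raises(ValueError):
            SimilarityGraph({"a": "X", "b": "X"}, [("a", "b", 0.0)])


def test_rank_hits_canonical_order():
    hits = [_hit("t", "gB", 50), _hit("t", "gA", 50), _hit("t", "gC", 80)]
    assert [h.sid for h in rank_hits(hits)] == ["gC", "gA", "gB"]
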