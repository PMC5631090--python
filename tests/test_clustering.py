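"""Reference clustering, closed/open assignment, de novo clustering, QC scans."""

import numpy as np
import pytest

from otubench._align import pairwise_identity
from otubench.clustering import (ReferenceDB, RefEntry, closed_reference_assign,
                                 cluster_reference_97, decompose_fail_causes,
                                 denovo_cluster, dereplicate,
                                 find_exact_duplicates, open_reference)


def _rand_seq(rng, n=100):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _db(seqs, clustered=True):
    return ReferenceDB([RefEntry(f"ref{i:03d}", s) for i, s in enumerate(seqs)],
                       clustered_97=clustered)


class TestClusterReference:
    def test_identical_sequences_one_centroid(self):
        seq = "ACGT" * 25
        out = cluster_reference_97(_db([seq, seq], clustered=False))
        assert len(out) == 1

    def test_96pct_pair_stays_two_centroids(self):
        rng = np.random.default_rng(0)
        a = _rand_seq(rng)
        b = _mutate_at(a, [3, 17, 42, 77])  # 96/100
        out = cluster_reference_97(_db([a, b], clustered=False))
        assert len(out) == 2

    def test_97pct_pair_collapses(self):
        rng = np.random.default_rng(1)
        a = _rand_seq(rng)
        b = _mutate_at(a, [3, 17, 42])  # 97/100, inclusive threshold
        out = cluster_reference_97(_db([a, b], clustered=False))
        assert len(out) == 1

    def test_centroids_mutually_below_threshold_all_vs_all(self):
        rng = np.random.default_rng(2)
        bases = [_rand_seq(rng) for _ in range(8)]
        seqs = []
        for b in bases:
            seqs.append(b)
            for k in (1, 2, 5):
                seqs.append(_mutate_at(b, list(rng.choice(100, size=k,
                                                          replace=False))))
        out = cluster_reference_97(_db(seqs, clustered=False))
        cents = [e.sequence for e in out.entries]
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                assert pairwise_identity(cents[i], cents[j]) < 0.97

    def test_matches_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(3)
        bases = [_rand_seq(rng) for _ in range(5)]
        seqs = [
            _mutate_at(b, list(rng.choice(100, size=int(k), replace=False)))
            for b in bases for k in rng.integers(0, 8, size=10)
        ]
        got = cluster_reference_97(_db(seqs, clustered=False))
        # independent greedy loop
        oracle = []
        for s in seqs:
            if all(pairwise_identity(s, c) < 0.97 for c in oracle):
                oracle.append(s)
        assert [e.sequence for e in got.entries] == oracle


class TestClosedReference:
    def test_exact_match_assigns_identity_one(self):
        rng = np.random.default_rng(4)
        seqs = [_rand_seq(rng) for _ in range(5)]
        refs = _db(seqs)
        (res,) = closed_reference_assign([("q", seqs[2], 1)], refs)
        assert res.otu_id == "ref002"
        assert res.identity == 1.0

    def test_four_substitutions_in_100nt_fails(self):
        rng = np.random.default_rng(5)
        seq = _rand_seq(rng)
        query = _mutate_at(seq, [1, 2, 3, 4])
        (res,) = closed_reference_assign([("q", query, 1)], _db([seq]))
        assert res.otu_id is None
        assert res.identity == pytest.approx(0.96)

    def test_threshold_is_inclusive_at_exactly_97pct(self):
        rng = np.random.default_rng(6)
        seq = _rand_seq(rng)
        query = _mutate_at(seq, [10, 50, 90])  # exactly 97/100
        (res,) = closed_reference_assign([("q", query, 1)], _db([seq]))
        assert res.otu_id is not None
        assert res.identity == pytest.approx(0.97)

    def test_invariant_to_query_and_reference_order(self):
        rng = np.random.default_rng(7)
        refs_seqs = [_rand_seq(rng) for _ in range(6)]
        queries = [(f"q{i}", _mutate_at(refs_seqs[i % 6],
                                        list(rng.choice(100, size=2,
                                                        replace=False))), 1)
                   for i in range(12)]
        fwd = closed_reference_assign(queries, _db(refs_seqs))
        entries = [RefEntry(f"ref{i:03d}", s) for i, s in enumerate(refs_seqs)]
        rev_db = ReferenceDB(entries[::-1], clustered_97=True)
        rev = closed_reference_assign(queries[::-1], rev_db)
        fwd_map = {a.query_id: a.otu_id for a in fwd}
        rev_map = {a.query_id: a.otu_id for a in rev}
        assert fwd_map == rev_map

    def test_tie_broken_by_lowest_ref_id(self):
        seq = "ACGT" * 25
        refs = ReferenceDB([RefEntry("b", seq), RefEntry("a", seq)],
                           clustered_97=True)
        (res,) = closed_reference_assign([("q", seq, 1)], refs)
        assert res.otu_id == "a"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            closed_reference_assign([("q", "ACGT", 1)],
                                    ReferenceDB([], clustered_97=True))

    def test_heuristic_hits_are_never_false_accepts(self):
        rng = np.random.default_rng(8)
        refs_seqs = [_rand_seq(rng) for _ in range(10)]
        queries = []
        for i in range(30):
            base = refs_seqs[i % 10]
            k = int(rng.integers(0, 10))
            queries.append((f"q{i}", _mutate_at(base, list(
                rng.choice(100, size=k, replace=False))), 1))
        res = closed_reference_assign(queries, _db(refs_seqs), mode="heuristic")
        for a in res:
            if a.otu_id is not None:
                assert a.identity >= 0.97
        # heuristic assignments agree with exact-mode threshold decisions
        exact = {a.query_id: a.otu_id for a in
                 closed_reference_assign(queries, _db(refs_seqs))}
        for a in res:
            if a.otu_id is not None:
                assert exact[a.query_id] is not None


class TestDenovo:
    def test_identical_sequences_one_otu(self):
        seqs = [(f"q{i}", "ACGT" * 25, 1) for i in range(5)]
        out = denovo_cluster(seqs)
        assert len(out.otus) == 1
        assert out.richness() == 1

    def test_one_sub_variants_join_their_source_otu(self):
        rng = np.random.default_rng(9)
        seq = _rand_seq(rng, 250)
        variants = [_mutate_at(seq, [p]) for p in (3, 50, 99, 160, 249)]
        queries = [("src", seq, 10)] + [(f"v{i}", v, 1)
                                        for i, v in enumerate(variants)]
        out = denovo_cluster(queries)
        assert len(out.otus) == 1

    def test_divergent_pair_two_otus(self):
        rng = np.random.default_rng(10)
        a = _rand_seq(rng)
        b = _mutate_at(a, list(range(10)))  # 90%
        out = denovo_cluster([("a", a, 1), ("b", b, 1)])
        assert len(out.otus) == 2

    def test_centroids_mutually_below_threshold(self):
        rng = np.random.default_rng(11)
        seqs = []
        for i in range(60):
            base = _rand_seq(rng)
            seqs.append((f"q{i}", base, int(rng.integers(1, 20))))
        out = denovo_cluster(seqs)
        cents = [o.representative for o in out.otus]
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                assert pairwise_identity(cents[i], cents[j]) < 0.97

    def test_processing_order_by_abundance(self):
        # the abundant sequence founds the centroid, the rare variant joins it
        rng = np.random.default_rng(12)
        seq = _rand_seq(rng)
        variant = _mutate_at(seq, [5])
        out = denovo_cluster([("rare", variant, 1), ("abundant", seq, 50)])
        assert out.otus[0].representative == seq


class TestOpenReference:
    def _setup(self):
        rng = np.random.default_rng(13)
        refs_seqs = [_rand_seq(rng) for _ in range(4)]
        novel = _rand_seq(rng)
        return refs_seqs, novel

    def test_all_matching_queries_no_denovo(self):
        refs_seqs, _ = self._setup()
        queries = [(f"q{i}", s, 3) for i, s in enumerate(refs_seqs)]
        out = open_reference(queries, _db(refs_seqs))
        assert all(o.origin == "reference" for o in out.otus)

    def test_two_copies_of_novel_tag_survive(self):
        refs_seqs, novel = self._setup()
        queries = [("known", refs_seqs[0], 5), ("novel", novel, 2)]
        out = open_reference(queries, _db(refs_seqs), min_otu_size=2)
        denovo_otus = [o for o in out.otus if o.origin == "denovo"]
        assert len(denovo_otus) == 1

    def test_singleton_novel_tag_discarded(self):
        refs_seqs, novel = self._setup()
        queries = [("known", refs_seqs[0], 5), ("novel", novel, 1)]
        out = open_reference(queries, _db(refs_seqs), min_otu_size=2)
        assert all(o.origin == "reference" for o in out.otus)
        (novel_res,) = [a for a in out.assignments if a.query_id == "novel"]
        assert novel_res.discarded

    def test_conservation_assigned_plus_failed_plus_discarded(self):
        rng = np.random.default_rng(14)
        refs_seqs = [_rand_seq(rng) for _ in range(5)]
        queries = []
        for i in range(40):
            base = refs_seqs[i % 5]
            k = int(rng.integers(0, 12))
            queries.append((f"q{i}", _mutate_at(base, list(
                rng.choice(100, size=k, replace=False))), int(rng.integers(1, 4))))
        total = sum(q[2] for q in queries)
        out = open_reference(queries, _db(refs_seqs), min_otu_size=2)
        n_assigned = sum(out.query_abundance[a.query_id]
                         for a in out.assignments if a.otu_id is not None)
        n_disc = sum(out.query_abundance[a.query_id]
                     for a in out.assignments if a.discarded)
        n_fail = sum(out.query_abundance[a.query_id]
                     for a in out.assignments if a.is_fail)
        assert n_assigned + n_disc + n_fail == total

    def test_min_size_one_loses_nothing(self):
        refs_seqs, novel = self._setup()
        queries = [("a", refs_seqs[0], 1), ("b", novel, 1)]
        out = open_reference(queries, _db(refs_seqs), min_otu_size=1)
        assert all(a.otu_id is not None for a in out.assignments)


class TestDereplicationAndDuplicates:
    def test_dereplicate_collapses_and_counts(self):
        queries, members = dereplicate([("r1", "AAAA"), ("r2", "CCCC"),
                                        ("r3", "AAAA"), ("r4", "AAAA")])
        assert queries == [("r1", "AAAA", 3), ("r2", "CCCC", 1)]
        assert members["r1"] == ["r1", "r3", "r4"]

    def test_no_duplicates_empty(self):
        rng = np.random.default_rng(15)
        refs = _db([_rand_seq(rng) for _ in range(20)])
        assert find_exact_duplicates(refs) == []

    def test_three_identical_gives_three_pairs(self):
        seq = "ACGT" * 25
        refs = ReferenceDB([RefEntry(i, seq) for i in "abc"])
        assert find_exact_duplicates(refs) == [("a", "b"), ("a", "c"),
                                               ("b", "c")]

    def test_planted_pair_among_many(self):
        rng = np.random.default_rng(16)
        entries = [RefEntry(f"r{i:04d}", _rand_seq(rng)) for i in range(1000)]
        entries[500] = RefEntry("r0500", entries[3].sequence)
        refs = ReferenceDB(entries)
        assert find_exact_duplicates(refs) == [("r0003", "r0500")]


class TestFailCauses:
    def test_three_causes_distinguished(self):
        rng = np.random.default_rng(17)
        full_seqs = [_rand_seq(rng, 150) for _ in range(6)]
        # ref97 keeps the first four; seq 4 is in full refs but its "tag"
        # will be queried at sub-threshold identity; seq 5 is truly novel
        full_refs = ReferenceDB([RefEntry(f"full{i}", s)
                                 for i, s in enumerate(full_seqs)])
        ref97 = ReferenceDB([RefEntry(f"full{i}", full_seqs[i])
                             for i in range(4)], clustered_97=True)
        q_hit = ("hit", full_seqs[0], 1)
        q_below = ("below", _mutate_at(full_seqs[4], list(range(30))), 1)
        q_novel = ("novel", _rand_seq(rng, 150), 1)
        causes = decompose_fail_causes(
            [q_hit, q_below, q_novel], full_refs, ref97,
            source_ids={"below": "full4"}, max_rejects=32)
        assert "hit" not in causes  # assigned, no cause needed
        assert causes["below"] == "below_threshold_vs_ref97"
        assert causes["novel"] == "true_novel"

    def test_heuristic_miss_detected_with_tiny_reject_budget(self):
        rng = np.random.default_rng(18)
        target = _rand_seq(rng, 150)
        # the decoy contains every 8-mer of the target (two overlapping
        # segments joined by junk) so it ties the k-mer ranking and wins the
        # tie on ref id, yet its gapped identity is far below threshold
        decoy = target[:80] + _rand_seq(rng, 20) + target[72:]
        ref97 = ReferenceDB([RefEntry("a_decoy", decoy),
                             RefEntry("target", target)], clustered_97=True)
        query = [("q", target, 1)]
        (heur,) = closed_reference_assign(query, ref97, mode="heuristic",
                                          max_rejects=1)
        assert heur.otu_id is None
        assert heur.fail_cause == "heuristic_miss"
        (exact,) = closed_reference_assign(query, ref97, mode="exact")
        assert exact.otu_id == "target"
        causes = decompose_fail_causes(query, ReferenceDB([]), ref97,
                                       max_rejects=1)
        assert causes["q"] == "heuristic_miss"
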