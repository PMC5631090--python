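"""OTU tables, subsampling, weighted Jaccard/UniFrac, reports."""

import numpy as np
import pandas as pd
import pytest

from otubench.clustering import (OTU, AssignmentResult, OTUSet,
                                 denovo_cluster)
from otubench.metrics import (OTUTable, build_otu_table, coassignment_matrix,
                              distance_histogram, rarefaction_curve, richness,
                              splitting_report, subsample_counts,
                              tree_from_newick, upgma_tree_from_sequences,
                              weighted_jaccard, weighted_unifrac)


def _otu_set(assign_pairs, abundance=None):
    """assign_pairs: list of (query_id, otu_id or None)."""
    otus = sorted({o for _q, o in assign_pairs if o is not None})
    return OTUSet(
        otus=[OTU(o, "A" * 10, "denovo") for o in otus],
        assignments=[AssignmentResult(q, o, 1.0 if o else None, "denovo")
                     for q, o in assign_pairs],
        query_abundance=abundance or {q: 1 for q, _o in assign_pairs},
    )


class TestOTUTable:
    def test_single_sample_single_otu(self):
        table = build_otu_table(
            {"s1": _otu_set([(f"r{i}", "otu1") for i in range(10)])})
        assert table.counts.shape == (1, 1)
        assert table.total("s1") == 10

    def test_disjoint_samples_block_diagonal(self):
        table = build_otu_table({
            "s1": _otu_set([("r1", "a"), ("r2", "a")]),
            "s2": _otu_set([("r3", "b"), ("r4", "b")]),
        })
        assert table.counts.loc["s1", "b"] == 0
        assert table.counts.loc["s2", "a"] == 0

    def test_fails_excluded_and_reads_conserved(self):
        rng = np.random.default_rng(0)
        pairs = [(f"r{i}", rng.choice(["a", "b", None]))
                 for i in range(50)]
        pairs = [(q, None if o is None else str(o)) for q, o in pairs]
        table = build_otu_table({"s": _otu_set(pairs)})
        n_assigned = sum(o is not None for _q, o in pairs)
        assert table.total("s") == n_assigned

    def test_abundance_weighting(self):
        table = build_otu_table(
            {"s": _otu_set([("q1", "a")], abundance={"q1": 7})})
        assert table.counts.loc["s", "a"] == 7

    def test_richness(self):
        table = build_otu_table(
            {"s": _otu_set([("r1", "a"), ("r2", "b"), ("r3", "b")])})
        assert richness(table, "s") == 2
        with pytest.raises(KeyError):
            richness(table, "unknown")

    def test_tsv_roundtrip(self, tmp_path):
        table = build_otu_table({
            "s1": _otu_set([("r1", "a"), ("r2", "b")]),
            "s2": _otu_set([("r3", "b")]),
        })
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = OTUTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.counts, table.counts)


class TestSubsampling:
    def test_full_depth_unchanged(self):
        counts = pd.Series({"a": 5, "b": 3})
        assert subsample_counts(counts, 8, seed=1).sum() == 8
        pd.testing.assert_series_equal(subsample_counts(counts, 8, seed=1),
                                       counts)

    def test_depth_one(self):
        counts = pd.Series({"a": 5, "b": 3})
        sub = subsample_counts(counts, 1, seed=2)
        assert sub.sum() == 1

    def test_depth_above_n_rejected(self):
        with pytest.raises(ValueError):
            subsample_counts(pd.Series({"a": 3}), 4, seed=1)

    def test_expected_frequency_preserved(self):
        counts = pd.Series({"a": 700, "b": 200, "c": 100})
        sub_fracs = []
        for seed in range(200):
            sub = subsample_counts(counts, 100, seed=seed)
            sub_fracs.append(sub["a"] / 100)
        # hypergeometric mean 0.7; SE of the mean over 200 draws
        se = np.sqrt(0.7 * 0.3 / 100 / 200 * (1000 - 100) / (1000 - 1))
        assert abs(np.mean(sub_fracs) - 0.7) < 3 * se


class TestWeightedJaccard:
    def test_identical_vectors_zero(self):
        x = pd.Series({"a": 0.5, "b": 0.5})
        assert weighted_jaccard(x, x) == 0.0

    def test_disjoint_supports_one(self):
        x = pd.Series({"a": 1.0, "b": 0.0})
        y = pd.Series({"a": 0.0, "b": 1.0})
        assert weighted_jaccard(x, y) == 1.0

    def test_hand_worked_example(self):
        x = np.array([0.5, 0.5, 0.0])
        y = np.array([0.25, 0.25, 0.5])
        assert weighted_jaccard(x, y) == pytest.approx(2 / 3)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.dirichlet(np.ones(6))
            y = rng.dirichlet(np.ones(6))
            assert weighted_jaccard(x, y) == pytest.approx(
                weighted_jaccard(y, x))
            assert 0.0 <= weighted_jaccard(x, y) <= 1.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            weighted_jaccard(np.zeros(3), np.zeros(3))


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        tree = tree_from_newick("((a:1,b:1):1,c:2);")
        x = pd.Series({"a": 0.3, "b": 0.3, "c": 0.4})
        assert weighted_unifrac(x, x, tree) == 0.0

    def test_two_leaf_tree_fully_distinct_samples(self):
        tree = tree_from_newick("(a:1,b:1);")
        x = pd.Series({"a": 1.0, "b": 0.0})
        y = pd.Series({"a": 0.0, "b": 1.0})
        assert weighted_unifrac(x, y, tree) == pytest.approx(1.0)

    def test_unmapped_otu_rejected(self):
        tree = tree_from_newick("(a:1,b:1);")
        x = pd.Series({"a": 0.5, "zzz": 0.5})
        with pytest.raises(ValueError):
            weighted_unifrac(x, x, tree)

    def test_agrees_with_skbio_on_random_trees(self):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        rng = np.random.default_rng(4)
        for rep in range(10):
            # random 8-leaf tree via random pairwise distances
            labels = [f"t{i}" for i in range(8)]
            seqs = [(l, "".join(rng.choice(list("ACGT"), size=60)))
                    for l in labels]
            tree = upgma_tree_from_sequences(seqs)
            counts_x = rng.integers(0, 50, size=8)
            counts_y = rng.integers(0, 50, size=8)
            if counts_x.sum() == 0 or counts_y.sum() == 0:
                continue
            x = pd.Series(counts_x / counts_x.sum(), index=labels)
            y = pd.Series(counts_y / counts_y.sum(), index=labels)
            expected = skbio_wu(counts_x, counts_y, taxa=labels, tree=tree,
                                normalized=True)
            assert weighted_unifrac(x, y, tree) == pytest.approx(expected)

    def test_unnormalized_variant_exposed(self):
        tree = tree_from_newick("(a:2,b:2);")
        x = pd.Series({"a": 1.0, "b": 0.0})
        y = pd.Series({"a": 0.0, "b": 1.0})
        assert weighted_unifrac(x, y, tree, normalized=False) == pytest.approx(4.0)


class TestDistanceHistogram:
    def test_all_zero_distances(self):
        hist = distance_histogram([0.0] * 5)
        assert hist.iloc[0] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_uniform_grid_one_per_bin(self):
        values = [round(i * 0.05 + 0.001, 5) for i in range(20)]
        hist = distance_histogram(values)
        assert list(hist.values) == pytest.approx([1 / 20] * 20)

    def test_twenty_bins_and_last_bin_closed(self):
        hist = distance_histogram([1.0])
        assert len(hist) == 20
        assert hist.iloc[-1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([1.2])


class TestRarefaction:
    def test_full_depth_equals_exact_richness(self):
        counts = pd.Series({"a": 40, "b": 30, "c": 30})
        curve = rarefaction_curve(counts, [100], iterations=5, seed=1)
        assert curve[100] == 3.0

    def test_single_otu_flat_curve(self):
        counts = pd.Series({"a": 100})
        curve = rarefaction_curve(counts, [10, 50, 100], iterations=5, seed=2)
        assert (curve == 1.0).all()

    def test_monotone_in_expectation(self):
        rng = np.random.default_rng(5)
        counts = pd.Series(rng.integers(1, 30, size=40),
                           index=[f"o{i}" for i in range(40)])
        curve = rarefaction_curve(counts, [10, 50, 100, int(counts.sum())],
                                  iterations=20, seed=3)
        assert (curve.diff().dropna() >= 0).all()


class TestSplittingReport:
    def _assign(self, otu):
        return AssignmentResult("q", otu, 1.0 if otu else None, "closed")

    def test_clean_community_no_splits_no_lumps(self):
        assignments = {(f"s{i}", "p1", "V4"): self._assign(f"otu{i}")
                       for i in range(5)}
        rep = splitting_report(assignments)
        assert rep.split_strains == []
        assert rep.lumped_groups == {}
        assert rep.failed_strains == []

    def test_strain_split_over_three_otus_counted_with_multiplicity(self):
        assignments = {("s1", f"p{i}", "V4"): self._assign(f"otu{i}")
                       for i in range(3)}
        rep = splitting_report(assignments)
        assert rep.split_strains == ["s1"]
        assert rep.n_split_otus == 3

    def test_two_strains_sharing_one_otu_lumped(self):
        assignments = {("s1", "p1", "V4"): self._assign("shared"),
                       ("s2", "p1", "V4"): self._assign("shared")}
        rep = splitting_report(assignments)
        assert rep.lumped_groups == {"shared": {"s1", "s2"}}

    def test_failed_strain_recorded(self):
        assignments = {("s1", "p1", "V4"): self._assign("otu1"),
                       ("s2", "p1", "V4"): self._assign(None)}
        rep = splitting_report(assignments)
        assert rep.failed_strains == ["s2"]


class TestCoassignment:
    def _assign(self, otu):
        return AssignmentResult("q", otu, 1.0 if otu else None, "closed")

    def test_always_same_otu(self):
        assignments = {}
        for src in ("x", "y", "z"):
            for t in ("V13", "V4"):
                assignments[(src, t)] = self._assign(f"otu_{src}")
        mat, all_same = coassignment_matrix(assignments, ["V13", "V4"])
        assert (mat.values == 1.0).all()
        assert all_same == 1.0

    def test_independent_assignment_approaches_half(self):
        rng = np.random.default_rng(6)
        assignments = {}
        for i in range(2000):
            for t in ("a", "b"):
                assignments[(f"s{i}", t)] = self._assign(
                    str(rng.choice(["otu1", "otu2"])))
        mat, _ = coassignment_matrix(assignments, ["a", "b"])
        assert mat.loc["a", "b"] == pytest.approx(0.5, abs=0.05)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(7)
        assignments = {}
        for i in range(50):
            for t in ("a", "b", "c"):
                otu = str(rng.choice(["o1", "o2", None]))
                assignments[(f"s{i}", t)] = self._assign(
                    None if otu == "None" else otu)
        mat, _ = coassignment_matrix(assignments, ["a", "b", "c"])
        for t in "abc":
            if not np.isnan(mat.loc[t, t]):
                assert mat.loc[t, t] == 1.0
        for u in "abc":
            for v in "abc":
                if not np.isnan(mat.loc[u, v]):
                    assert mat.loc[u, v] == mat.loc[v, u]

    def test_all_same_fraction_denominator_is_all_sources(self):
        assignments = {("s1", "a"): self._assign("o1"),
                       ("s1", "b"): self._assign("o1"),
                       ("s2", "a"): self._assign("o1"),
                       ("s2", "b"): self._assign(None)}
        _mat, all_same = coassignment_matrix(assignments, ["a", "b"])
        assert all_same == 0.5
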