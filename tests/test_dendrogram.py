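"""Correlation distances, minimax linkage, cuts, pruning, review sheets."""

import numpy as np
import pytest

from litnet.dendrogram import (
    ClusterSet,
    counts_to_distance,
    cut_tree,
    minimax_linkage,
    prune_small,
    sample_review_sheet,
    subcut,
    to_newick,
)
from litnet.ebc import EnsembleCocluster


def make_ensemble(freq_rows, n_runs=100):
    """EnsembleCocluster whose frequency matrix equals the given rows."""
    f = np.asarray(freq_rows, dtype=float)
    counts = np.round(f * n_runs).astype(int)
    counts = np.maximum(counts, counts.T)
    np.fill_diagonal(counts, n_runs)
    return EnsembleCocluster(counts, n_runs)


def brute_minimax(d):
    """Independent naive minimax linkage: python loops and dicts only."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                union = active[a] + active[b]
                radius = min(max(d[c][x] for x in union) for c in union)
                key = (radius, a, b)
                if best is None or key < best:
                    best = key
        radius, a, b = best
        union = active[a] + active[b]
        merges.append((a, b, radius, len(union)))
        del active[a], active[b]
        active[next_id] = union
        next_id += 1
    return merges


class TestCountsToDistance:
    def test_identical_rows_are_distance_zero(self):
        f = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.2], [0.2, 0.2, 1.0]])
        # make rows 0 and 1 identical frequency profiles
        f[1] = f[0]
        dist = counts_to_distance(make_ensemble(f), ["a", "b", "c"])
        assert dist.distances[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_are_distance_two(self):
        x = np.array([0.9, 0.1, 0.8, 0.2])
        rows = np.vstack([x, 1 - x, x, 1 - x])
        dist = counts_to_distance(make_ensemble(rows), list("abcd"))
        assert dist.distances[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_matches_pearson_formula_oracle(self, rng):
        counts = rng.integers(0, 101, size=(10, 10))
        counts = np.maximum(counts, counts.T)
        np.fill_diagonal(counts, 100)
        ens = EnsembleCocluster(counts, 100)
        dist = counts_to_distance(ens, [f"p{i}" for i in range(10)])
        f = counts / 100
        for i in range(10):
            for j in range(10):
                if i == j:
                    continue
                xi, xj = f[i] - f[i].mean(), f[j] - f[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert dist.distances[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_depends_only_on_counts_not_cluster_ids(self):
        # two ensembles producing the same counts are indistinguishable
        counts = np.array([[5, 3, 1], [3, 5, 2], [1, 2, 5]])
        a = counts_to_distance(EnsembleCocluster(counts, 5), list("xyz"))
        b = counts_to_distance(EnsembleCocluster(counts.copy(), 5), list("xyz"))
        assert np.array_equal(a.distances, b.distances)

    def test_constant_row_gets_unit_distance(self):
        counts = np.array([[4, 4, 4], [4, 4, 1], [4, 1, 4]])
        dist = counts_to_distance(EnsembleCocluster(counts, 4), list("abc"))
        assert dist.distances[0, 1] == pytest.approx(1.0)

    def test_single_path_rejected(self):
        with pytest.raises(ValueError):
            counts_to_distance(EnsembleCocluster(np.array([[3]]), 3), ["a"])


class TestMinimaxLinkage:
    def test_two_points_merge_at_their_distance(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = minimax_linkage(d)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(0.3)

    def test_three_collinear_points(self):
        """d(1,2)=d(2,3)=1, d(1,3)=2: first merge {1,2} at 1 (tie-break),
        then the middle point covers everything within radius 1."""
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        tree = minimax_linkage(d)
        assert tree.merges[0].tolist() == [0.0, 1.0, 1.0, 2.0]
        assert tree.merges[1, 2] == pytest.approx(1.0)
        assert tree.prototypes[1] == 1  # the middle point is the prototype

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 8))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = minimax_linkage(d)
            oracle = brute_minimax(d)
            for got, exp in zip(tree.merges, oracle):
                assert got[0] == exp[0] and got[1] == exp[1]
                assert got[2] == pytest.approx(exp[2], abs=1e-12)
                assert got[3] == exp[3]

    def test_prototype_property(self, rng):
        """Every merge height is realized by a prototype's covering radius."""
        n = 9
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = minimax_linkage(d)
        sets = tree.leaf_sets()
        for step, (a, b, h, _) in enumerate(tree.merges):
            members = sorted(sets[n + step])
            radii = [max(d[c][x] for x in members) for c in members]
            assert min(radii) == pytest.approx(h, abs=1e-12)
            assert max(d[tree.prototypes[step]][x] for x in members) == pytest.approx(h)


class TestCutPrune:
    @pytest.fixture()
    def tree(self, rng):
        d = rng.random((12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return minimax_linkage(d)

    def test_single_cluster_holds_all_leaves(self, tree):
        cs = cut_tree(tree, 1)
        assert len(cs.clusters) == 1
        assert sorted(sum(cs.clusters.values(), [])) == sorted(tree.labels)

    def test_full_cut_gives_singletons(self, tree):
        cs = cut_tree(tree, 12)
        assert len(cs.clusters) == 12
        assert all(len(v) == 1 for v in cs.clusters.values())

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_cut_partitions_leaves(self, tree, k):
        cs = cut_tree(tree, k)
        assert len(cs.clusters) == k
        members = sum(cs.clusters.values(), [])
        assert sorted(members) == sorted(tree.labels)

    def test_cut_refinement(self, tree):
        """cut(k) refines cut(k-1): every finer cluster sits in a coarser one."""
        for k in range(2, 12):
            coarse = cut_tree(tree, k - 1)
            fine = cut_tree(tree, k)
            coarse_sets = [set(v) for v in coarse.clusters.values()]
            for paths in fine.clusters.values():
                assert any(set(paths) <= c for c in coarse_sets)

    def test_out_of_range_cut_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 13)

    def test_prune_default_removes_ten_or_fewer(self):
        cs = ClusterSet(
            {
                "1": [f"p{i}" for i in range(12)],
                "2": [f"q{i}" for i in range(10)],
                "3": ["r0", "r1", "r2"],
            }
        )
        kept = prune_small(cs)
        assert list(kept.clusters) == ["1"]

    def test_prune_empty_and_identity(self):
        assert prune_small(ClusterSet({})).clusters == {}
        cs = ClusterSet({"1": ["a"], "2": ["b", "c"]})
        assert prune_small(cs, min_size=0).clusters == cs.clusters


class TestSubcut:
    def test_subcut_into_one_is_identity(self, rng):
        d = rng.random((8, 8)); d = (d + d.T) / 2; np.fill_diagonal(d, 0.0)
        tree = minimax_linkage(d)
        cs = cut_tree(tree, 2)
        cid = next(iter(cs.clusters))
        assert subcut(cs, cid, 1, tree).clusters == cs.clusters

    def test_subcut_partitions_the_cluster(self, rng):
        d = rng.random((20, 20)); d = (d + d.T) / 2; np.fill_diagonal(d, 0.0)
        tree = minimax_linkage(d)
        cs = cut_tree(tree, 1)
        out = subcut(cs, "1", 2, tree)
        assert set(out.clusters) == {"1.1", "1.2"}
        assert sorted(out.clusters["1.1"] + out.clusters["1.2"]) == sorted(tree.labels)
        assert out.provenance["1.1"]["parent"] == "1"

    def test_subcut_separates_planted_subthemes(self):
        """Two well-separated sub-blocks inside one cluster split cleanly."""
        d = np.full((10, 10), 0.9)
        d[:5, :5] = 0.1
        d[5:, 5:] = 0.1
        np.fill_diagonal(d, 0.0)
        tree = minimax_linkage(d)
        cs = cut_tree(tree, 1)
        out = subcut(cs, "1", 2, tree)
        groups = [set(map(int, v)) for v in out.clusters.values()]
        assert sorted(groups, key=min) == [set(range(5)), set(range(5, 10))]

    def test_unknown_cluster_rejected(self, rng):
        d = rng.random((4, 4)); d = (d + d.T) / 2; np.fill_diagonal(d, 0.0)
        tree = minimax_linkage(d)
        with pytest.raises(KeyError):
            subcut(cut_tree(tree, 2), "nope", 2, tree)


class TestReviewSheet:
    def test_small_cluster_lists_all_paths(self, clean_records):
        paths = sorted({r.path for r in clean_records})[:4]
        cs = ClusterSet({"1": paths})
        sheet = sample_review_sheet(cs, clean_records, n_paths=10, seed=0)
        assert set(sheet["path"]) == set(paths)

    def test_same_seed_same_sheet(self, clean_records):
        paths = sorted({r.path for r in clean_records})
        cs = ClusterSet({"1": paths[:8], "2": paths[8:14]})
        a = sample_review_sheet(cs, clean_records, seed=3)
        b = sample_review_sheet(cs, clean_records, seed=3)
        assert a.equals(b)

    def test_listed_sentences_contain_the_path(self, clean_records):
        by_path = {}
        for r in clean_records:
            by_path.setdefault(r.path, set()).add(r.sentence)
        cs = ClusterSet({"1": sorted(by_path)[:6]})
        sheet = sample_review_sheet(cs, clean_records, n_sentences=2, seed=1)
        for _, row in sheet.iterrows():
            if row["sentence"]:
                assert row["sentence"] in by_path[row["path"]]


def test_newick_export_parses_and_preserves_leaves(rng):
    import dendropy

    d = rng.random((7, 7)); d = (d + d.T) / 2; np.fill_diagonal(d, 0.0)
    tree = minimax_linkage(d)
    tree.labels = [f"w|{i} x" for i in range(7)]  # awkward path-like labels
    newick = to_newick(tree)
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    assert {t.label for t in parsed.taxon_namespace} == set(tree.labels)
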