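import inspect

import numpy as np
import pytest

from helpers import naive_cut, naive_linkage
from layervis.cluster import (
    DEFAULT_METHOD,
    METHODS,
    cluster_overlay,
    cut,
    linkage,
    save_cluster_ids,
)
from layervis.core import ExpressionMatrix, GeneList
from layervis.errors import ValidationError


def _points(n=8, d=3, seed=0):
    return np.random.default_rng(seed).normal(size=(n, d))


class TestLinkage:
    def test_two_profiles_merge_at_their_distance(self):
        data = np.array([[0.0, 0.0], [3.0, 4.0]])
        for method in METHODS:
            tree = linkage(data, method)
            assert len(tree.merges) == 1
            assert tree.heights[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("method", ["single", "complete", "average"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, method, seed):
        data = _points(8, seed=seed)
        tree = linkage(data, method)
        oracle_merges, oracle_heights = naive_linkage(data, method)
        assert [m[:2] for m in tree.merges] == oracle_merges
        np.testing.assert_allclose(tree.heights, oracle_heights, rtol=1e-9)

    def test_heights_nondecreasing_for_monotone_linkages(self):
        for method in ("single", "complete", "average", "ward.D", "ward.D2", "mcquitty"):
            tree = linkage(_points(12, seed=4), method)
            assert np.all(np.diff(tree.heights) >= -1e-12), method

    def test_permutation_invariance_up_to_relabeling(self):
        data = _points(10, seed=6)
        rng = np.random.default_rng(7)
        perm = rng.permutation(10)
        for method in ("single", "complete", "average"):
            p1 = _partition(cut(linkage(data, method), 3), range(10))
            tree2 = linkage(data[perm], method)
            assignment2 = cut(tree2, 3)
            # map permuted leaves back to original indices
            groups = {}
            for leaf_label, c in assignment2.assignment.items():
                groups.setdefault(c, set()).add(int(perm[int(leaf_label)]))
            assert {frozenset(g) for g in groups.values()} == p1

    def test_ward_d_and_ward_d2_differ_in_general(self):
        data = _points(10, seed=9)
        h1 = linkage(data, "ward.D").heights
        h2 = linkage(data, "ward.D2").heights
        assert not np.allclose(h1, h2)

    def test_unknown_method_lists_menu(self):
        with pytest.raises(ValidationError, match="ward.D"):
            linkage(_points(), "upgma")

    def test_default_method_is_ward_d(self):
        assert DEFAULT_METHOD == "ward.D"
        assert inspect.signature(linkage).parameters["method"].default == "ward.D"


def _partition(assignment, leaves):
    groups = {}
    for leaf in leaves:
        groups.setdefault(assignment.assignment[str(leaf)], set()).add(leaf)
    return {frozenset(g) for g in groups.values()}


class TestCut:
    def test_trivial_cuts(self):
        tree = linkage(_points(8, seed=1), "average")
        all_one = cut(tree, 1)
        assert set(all_one.assignment.values()) == {1}
        singletons = cut(tree, 8)
        assert sorted(singletons.assignment.values()) == list(range(1, 9))

    def test_k3_matches_component_oracle(self):
        for seed in range(5):
            data = _points(8, seed=seed)
            tree = linkage(data, "single")
            got = _partition(cut(tree, 3), range(8))
            merges, _ = naive_linkage(data, "single")
            assert got == set(naive_cut(merges, 8, 3))

    def test_every_k_is_a_partition(self):
        tree = linkage(_points(9, seed=3), "complete")
        for k in range(1, 10):
            assignment = cut(tree, k)
            assert len(assignment.assignment) == 9
            sizes = [len(v) for v in assignment.clusters().values()]
            assert sum(sizes) == 9 and all(s > 0 for s in sizes)
            assert len(assignment.clusters()) == k

    def test_cluster_indices_by_first_appearance(self):
        tree = linkage(_points(6, seed=5), "average")
        assignment = cut(tree, 3)
        first_seen = []
        for leaf in tree.leaf_ids:
            c = assignment.assignment[leaf]
            if c not in first_seen:
                first_seen.append(c)
        assert first_seen == [1, 2, 3]

    def test_k_out_of_range_rejected(self):
        tree = linkage(_points(5, seed=2), "average")
        with pytest.raises(ValidationError):
            cut(tree, 0)
        with pytest.raises(ValidationError):
            cut(tree, 6)

    def test_palette_injective_and_stable(self):
        tree = linkage(_points(8, seed=8), "ward.D")
        a1, a2 = cut(tree, 4), cut(tree, 4)
        assert a1.palette == a2.palette
        assert len(set(a1.palette.values())) == 4


def _two_group_matrix():
    """Two planted profile shapes: rising vs falling across samples."""
    rng = np.random.default_rng(12)
    rising = np.array([10, 20, 40, 80.0]) * rng.uniform(0.8, 1.2, size=(10, 1))
    falling = np.array([80, 40, 20, 10.0]) * rng.uniform(0.8, 1.2, size=(10, 1))
    counts = np.vstack([rising, falling])
    return ExpressionMatrix.from_arrays(
        [f"up{i}" for i in range(10)] + [f"dn{i}" for i in range(10)],
        counts,
        ["A.1", "A.2", "B.1", "B.2"],
    )


class TestClusterOverlay:
    def test_approach3_overlays_everything(self):
        matrix = _two_group_matrix()
        assignment, figures = cluster_overlay(matrix, None, k=2, approach=3)
        total = sum(len(f.foreground.elements) for f in figures.values())
        assert total == matrix.n_genes
        # planted structure recovered: rising and falling separate
        clusters = assignment.clusters()
        shapes = [{g[:2] for g in members} for members in clusters.values()]
        assert {frozenset(s) for s in shapes} == {frozenset({"up"}), frozenset({"dn"})}

    def test_approach2_overlays_subset_with_full_data_labels(self):
        matrix = _two_group_matrix()
        subset = GeneList.of(["up0", "up1", "dn0"])
        assignment, figures = cluster_overlay(matrix, subset, k=2, approach=2)
        assert len(assignment.assignment) == matrix.n_genes  # clustered all
        overlaid = {
            e["id"] for f in figures.values() for e in f.foreground.elements
        }
        assert overlaid == set(subset.ids)

    def test_approach1_clusters_only_subset(self):
        matrix = _two_group_matrix()
        subset = GeneList.of(["up0", "up1", "up2", "dn0", "dn1", "dn2"])
        assignment, figures = cluster_overlay(matrix, subset, k=2, approach=1)
        assert set(assignment.assignment) == set(subset.ids)

    def test_approaches_1_and_2_generally_differ(self):
        matrix = _two_group_matrix()
        # a subset drawn from one planted group only: approach 1 must split it,
        # approach 2 keeps its full-data labels (all one cluster)
        subset = GeneList.of([f"up{i}" for i in range(10)])
        a1, _ = cluster_overlay(matrix, subset, k=2, approach=1)
        a2, _ = cluster_overlay(matrix, subset, k=2, approach=2)
        labels1 = {a1.assignment[g] for g in subset.ids}
        labels2 = {a2.assignment[g] for g in subset.ids}
        assert len(labels1) == 2 and len(labels2) == 1

    def test_summary_underlay_comes_from_full_dataset(self):
        matrix = _two_group_matrix()
        _, figures = cluster_overlay(matrix, None, k=2, approach=3)
        docs = {f.background.digest for f in figures.values()}
        assert len(docs) == 1  # every cluster figure shares the full-data summary

    def test_missing_subset_rejected_for_approaches_1_and_2(self):
        matrix = _two_group_matrix()
        for approach in (1, 2):
            with pytest.raises(ValidationError):
                cluster_overlay(matrix, None, k=2, approach=approach)


class TestSaveClusterIds:
    def test_files_partition_the_genes(self, tmp_path):
        matrix = _two_group_matrix()
        assignment, _ = cluster_overlay(matrix, None, k=3, approach=3)
        paths = save_cluster_ids(assignment, tmp_path)
        assert len(paths) == 3
        assert [p.name for p in paths] == [
            f"cluster_{c}_of_3_ward.D.txt" for c in (1, 2, 3)
        ]
        seen: list[str] = []
        for path in paths:
            ids = path.read_text().split()
            assert ids  # non-empty cluster
            seen.extend(ids)
        assert sorted(seen) == sorted(matrix.gene_ids)

    def test_reload_reproduces_partition(self, tmp_path):
        matrix = _two_group_matrix()
        assignment, _ = cluster_overlay(matrix, None, k=2, approach=3)
        paths = save_cluster_ids(assignment, tmp_path)
        reloaded = {
            c + 1: set(path.read_text().split()) for c, path in enumerate(paths)
        }
        assert reloaded == {c: set(m) for c, m in assignment.clusters().items()}
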