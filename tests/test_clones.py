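import numpy as np
import pytest

from scnavar.clones import (Alteration, Clone, build_clone_tree,
                            characterize_clones, cluster_subclones,
                            match_alterations, merge_adjacent_alterations)
from scnavar.cnv_call import SegmentCall
from scnavar.config import CloneConfig

MB = 1_000_000


def call(chrom, start, end, state, n_cells=4):
    return SegmentCall(chrom, start, end, 10,
                       np.full(n_cells, state), state, float(state - 2))


class TestClusterSubclones:
    def test_two_planted_populations_split_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(80, 500))
        x[40:] += 10.0
        labels = cluster_subclones(x, k_neighbors=10, seed=1)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1

    def test_identical_rows_single_community(self):
        x = np.ones((30, 50))
        labels = cluster_subclones(x, seed=1)
        assert len(np.unique(labels)) == 1

    def test_partition_invariant_under_row_permutation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(60, 200))
        x[30:] += 8.0
        perm = rng.permutation(60)
        a = cluster_subclones(x, seed=2)
        b = cluster_subclones(x[perm], seed=2)
        # same partition up to label renaming
        for lab in np.unique(a):
            members = np.where(a == lab)[0]
            image = b[np.argsort(perm)][members]
            assert len(np.unique(image)) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 100))
        np.testing.assert_array_equal(cluster_subclones(x, seed=9),
                                      cluster_subclones(x, seed=9))


class TestMergeAdjacent:
    def test_same_state_below_10mb_gap_merged(self):
        calls = [call("1", 10 * MB, 30 * MB, 3), call("1", 35 * MB, 50 * MB, 3)]
        merged = merge_adjacent_alterations(calls)
        assert len(merged) == 1
        assert (merged[0].start_bp, merged[0].end_bp) == (10 * MB, 50 * MB)

    def test_different_states_not_merged(self):
        calls = [call("1", 10 * MB, 30 * MB, 3), call("1", 31 * MB, 50 * MB, 1)]
        assert len(merge_adjacent_alterations(calls)) == 2

    def test_gap_of_exactly_10mb_not_merged(self):
        calls = [call("1", 10 * MB, 30 * MB, 3), call("1", 40 * MB, 50 * MB, 3)]
        assert len(merge_adjacent_alterations(calls)) == 2

    def test_neutral_segments_never_become_alterations(self):
        calls = [call("1", 10 * MB, 30 * MB, 2), call("1", 31 * MB, 50 * MB, 3)]
        merged = merge_adjacent_alterations(calls)
        assert len(merged) == 1
        assert merged[0].state == 3


class TestMatchAlterations:
    def test_close_boundaries_and_similar_size_match(self):
        a = Alteration("1", 20 * MB, 60 * MB, 3)
        b = Alteration("1", 25 * MB, 62 * MB, 3)
        assert match_alterations(a, b)

    def test_size_difference_of_half_rejected(self):
        a = Alteration("1", 20 * MB, 60 * MB, 3)
        b = Alteration("1", 20 * MB, 40 * MB, 3)
        assert not match_alterations(a, b)

    def test_identical_alterations_match(self):
        a = Alteration("2", 5 * MB, 15 * MB, 1)
        assert match_alterations(a, Alteration("2", 5 * MB, 15 * MB, 1))

    def test_different_chromosome_or_state_never_match(self):
        a = Alteration("1", 5 * MB, 15 * MB, 3)
        assert not match_alterations(a, Alteration("2", 5 * MB, 15 * MB, 3))
        assert not match_alterations(a, Alteration("1", 5 * MB, 15 * MB, 4))

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s1, s2 = rng.integers(0, 100 * MB, 2)
            a = Alteration("1", s1, s1 + int(rng.integers(MB, 50 * MB)), 3)
            b = Alteration("1", s2, s2 + int(rng.integers(MB, 50 * MB)), 3)
            assert match_alterations(a, b) == match_alterations(b, a)


class TestCharacterize:
    def _clone(self, cid, cells, calls):
        clone = Clone(cid, cells)
        clone.calls = calls
        return clone

    def test_single_clone_alterations_all_clonal(self):
        clone = self._clone(0, ["a", "b"], [call("1", 10 * MB, 30 * MB, 3)])
        cna = np.zeros((2, 10))
        groups, kept = characterize_clones([clone], cna, {"a": 0, "b": 1})
        assert len(kept) == 1
        assert [g.category for g in groups] == ["clonal"]

    def test_alteration_in_all_clones_is_clonal(self):
        truncal = lambda: call("1", 10 * MB, 30 * MB, 3)
        clones = [
            self._clone(0, ["a"], [truncal(),
                                   call("2", 5 * MB, 20 * MB, 1)]),
            self._clone(1, ["b"], [truncal(),
                                   call("3", 5 * MB, 20 * MB, 3)]),
            self._clone(2, ["c"], [truncal(),
                                   call("4", 5 * MB, 20 * MB, 1)]),
        ]
        cna = np.random.default_rng(0).normal(size=(3, 10))
        groups, kept = characterize_clones(clones, cna,
                                           {"a": 0, "b": 1, "c": 2})
        cats = {(g.chrom, g.category) for g in groups}
        assert ("1", "clonal") in cats
        assert sum(g.category == "specific" for g in groups) == 3

    def test_planted_truncal_plus_private_events(self):
        truncal = lambda: call("1", 10 * MB, 40 * MB, 3)
        clones = [
            self._clone(0, ["a", "b"], [truncal(),
                                        call("2", 50 * MB, 80 * MB, 1)]),
            self._clone(1, ["c", "d"], [truncal(),
                                        call("3", 10 * MB, 30 * MB, 4)]),
        ]
        cna = np.random.default_rng(1).normal(size=(4, 20))
        groups, kept = characterize_clones(
            clones, cna, {c: i for i, c in enumerate("abcd")})
        cats = sorted(g.category for g in groups)
        assert cats == ["clonal", "specific", "specific"]
        assert len(kept) == 2

    def test_categories_partition_matched_groups(self):
        truncal = lambda: call("1", 10 * MB, 40 * MB, 3)
        clones = [
            self._clone(0, ["a"], [truncal(), call("2", 1 * MB, 9 * MB, 1)]),
            self._clone(1, ["b"], [truncal(), call("2", 40 * MB, 60 * MB, 4),
                                   call("4", 1 * MB, 20 * MB, 3)]),
            self._clone(2, ["c"], [truncal(), call("4", 2 * MB, 21 * MB, 3),
                                   call("5", 1 * MB, 9 * MB, 0)]),
        ]
        cna = np.random.default_rng(2).normal(size=(3, 10))
        groups, _ = characterize_clones(clones, cna,
                                        {"a": 0, "b": 1, "c": 2})
        counts = {c: sum(g.category == c for g in groups)
                  for c in ("clonal", "shared", "specific")}
        assert sum(counts.values()) == len(groups)
        assert counts["clonal"] == 1
        assert counts["shared"] == 1  # chr4 gain in clones 1 and 2

    def test_clone_without_specific_alterations_dissolved(self):
        truncal = lambda: call("1", 10 * MB, 40 * MB, 3)
        rng = np.random.default_rng(3)
        cna = rng.normal(0, 0.01, size=(6, 30))
        cna[:4, :10] += 1.0  # clones 0 and 1 share profile structure
        clones = [
            self._clone(0, ["a", "b"], [truncal()]),
            self._clone(1, ["c", "d"], [truncal()]),
            self._clone(2, ["e", "f"], [truncal(),
                                        call("2", 1 * MB, 20 * MB, 4)]),
        ]
        groups, kept = characterize_clones(
            clones, cna, {c: i for i, c in enumerate("abcdef")})
        assert len(kept) < 3
        all_cells = sorted(c for k in kept for c in k.cells)
        assert all_cells == list("abcdef")  # no cell lost


class TestCloneTree:
    def _clone_with_states(self, cid, states):
        from scnavar.config import SegConfig
        from scnavar.segment import joint_segment

        n = len(states)
        clone = Clone(cid, [f"x{cid}"])
        sig = np.asarray(states, dtype=float)[None, :]
        clone.segmentation = joint_segment(sig, cfg=SegConfig(beta=1e-6))
        clone.calls = []
        for region in clone.segmentation.regions:
            state = int(states[region.start])
            clone.calls.append(SegmentCall(
                "1", region.start, region.end, region.size,
                np.array([state]), state, 0.0))
        return clone

    def test_identical_clones_share_a_cherry_against_distant_third(self):
        a = self._clone_with_states(0, [3] * 10 + [2] * 30)
        b = self._clone_with_states(1, [3] * 10 + [2] * 30)
        c = self._clone_with_states(2, [2] * 20 + [0] * 20)
        nwk = build_clone_tree([a, b, c])
        import io

        from skbio import TreeNode
        tree = TreeNode.read(io.StringIO(nwk))
        tips_a = tree.find("clone_0")
        assert {t.name for t in tips_a.parent.tips()} >= {"clone_0", "clone_1"}

    def test_single_clone_gives_one_leaf_tree(self):
        a = self._clone_with_states(0, [3] * 5 + [2] * 5)
        assert "clone_0" in build_clone_tree([a])

    def test_distance_matrix_symmetry_zero_diagonal(self):
        from scnavar.clones import clone_state_vectors
        a = self._clone_with_states(0, [3] * 10 + [2] * 10)
        b = self._clone_with_states(1, [2] * 10 + [1] * 10)
        vecs = clone_state_vectors([a, b])
        d_ab = np.abs(vecs[0] - vecs[1]).sum()
        d_ba = np.abs(vecs[1] - vecs[0]).sum()
        assert d_ab == d_ba
        assert np.abs(vecs[0] - vecs[0]).sum() == 0
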