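from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from scnavar.config import SegConfig
from scnavar.evaluate import score_breakpoints
from scnavar.segment import (JointSegmenter, Region, build_cna_matrix,
                             joint_segment, merge_cost, segment_means,
                             total_variability, write_seg)


def data_energy(matrix, regions):
    """Brute-force data term of the piecewise-constant energy."""
    total = 0.0
    for start, size in regions:
        block = matrix[:, start:start + size]
        total += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum()
    return total


def replay_merges(matrix, seg):
    """Re-apply the merge log from singletons, recomputing E from scratch."""
    regions = {i: 1 for i in range(matrix.shape[1])}
    e_prev = 0.0
    for removed, lam in seg.merge_log:
        starts = sorted(regions)
        left = starts[starts.index(removed) - 1]
        regions[left] += regions.pop(removed)
        e_now = data_energy(matrix, regions.items())
        yield e_now - e_prev, lam
        e_prev = e_now


class TestTotalVariability:
    def test_constant_matrix_is_zero(self):
        assert total_variability(np.full((5, 20), 7.0)) == 0.0

    def test_direct_formula(self):
        mat = np.array([[0.0, 2.0], [1.0, 1.0]])
        assert total_variability(mat) == pytest.approx(1.0)

    def test_matches_independent_two_pass_summation(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(10, 50))
        two_pass = sum(
            np.sqrt(np.mean((row - np.mean(row)) ** 2)) for row in mat)
        assert total_variability(mat) == pytest.approx(two_pass, abs=1e-12)

    def test_single_gene_is_zero(self):
        assert total_variability(np.array([[3.0], [9.0]])) == 0.0


class TestMergeCost:
    def test_equal_means_cost_zero(self):
        left = Region(0, 2, np.array([1.0, 2.0]))
        right = Region(2, 4, np.array([1.0, 2.0]))
        assert merge_cost(left, right) == 0.0

    def test_direct_arithmetic(self):
        left = Region(0, 2, np.array([1.0]))
        right = Region(2, 4, np.array([3.0]))
        assert merge_cost(left, right) == pytest.approx(4.0)

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError):
            merge_cost(Region(0, 2, np.zeros(1)), Region(3, 4, np.zeros(1)))

    def test_cost_equals_brute_force_energy_increase(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(4, 10))
        left = Region(2, 5, mat[:, 2:5].mean(axis=1))
        right = Region(5, 9, mat[:, 5:9].mean(axis=1))
        merged = data_energy(mat, [(2, 7)])
        split = data_energy(mat, [(2, 3), (5, 4)])
        assert merge_cost(left, right) == pytest.approx(merged - split,
                                                        abs=1e-9)


class TestJointSegment:
    def test_constant_matrix_one_region_per_chromosome(self):
        mat = np.full((3, 40), 1.5)
        seg = joint_segment(mat, [(0, 25), (25, 40)])
        assert seg.breakpoints == [0, 25, 40]
        assert len(seg.regions) == 2

    def test_noiseless_three_block_signal_recovers_exact_breakpoints(self):
        mat = np.concatenate([np.zeros(50), np.full(50, 4.0),
                              np.zeros(50)])[None, :]
        seg = joint_segment(mat, cfg=SegConfig(beta=0.5))
        assert seg.interior_breakpoints == [50, 100]
        # cross-check against the exhaustive 2-breakpoint minimizer of the
        # piecewise-constant energy
        best = min(
            ((data_energy(mat, [(0, b1), (b1, b2 - b1), (b2, 150 - b2)]),
              b1, b2)
             for b1, b2 in combinations(range(10, 140, 10), 2)),
        )
        assert (best[1], best[2]) == (50, 100)

    def test_energy_bookkeeping_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            mat = rng.normal(size=(5, 60))
            seg = joint_segment(mat, [(0, 30), (30, 60)], SegConfig(beta=3.0))
            for delta_e, lam in replay_merges(mat, seg):
                assert delta_e == pytest.approx(lam, abs=1e-9)

    def test_lambda_history_non_decreasing(self):
        rng = np.random.default_rng(3)
        seg = joint_segment(rng.normal(size=(8, 100)), cfg=SegConfig(beta=1.0))
        lh = seg.lambda_history
        assert all(a <= b + 1e-12 for a, b in zip(lh, lh[1:]))

    def test_breakpoints_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(12, 80))
        mat[:, 30:50] += 2.0
        seg1 = joint_segment(mat, cfg=SegConfig(beta=0.5))
        seg2 = joint_segment(mat[rng.permutation(12)], cfg=SegConfig(beta=0.5))
        assert seg1.breakpoints == seg2.breakpoints

    @pytest.mark.parametrize("betas", [(0.1, 0.5, 1.0, 2.0, 3.0, 4.0)])
    def test_larger_beta_gives_coarser_segmentation(self, betas):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(6, 200))
        mat[:, 60:120] += 1.0
        counts = [len(joint_segment(mat, [(0, 100), (100, 200)],
                                    SegConfig(beta=b)).interior_breakpoints)
                  for b in betas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_steps_five_sigma_recovered_at_tight_tolerance(self):
        f1s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m, n, sd = 20, 200, 0.2
            cuts = sorted(rng.choice(np.arange(20, 180), 3, replace=False))
            mat = np.zeros((m, n))
            level = np.zeros(m)
            bounds = [0, *cuts, n]
            for i in range(len(bounds) - 1):
                if i:
                    level = level + rng.choice([-1, 1], m) * (5 * sd
                                                              + rng.random(m))
                mat[:, bounds[i]:bounds[i + 1]] = level[:, None]
            mat += rng.normal(0, sd, size=(m, n))
            seg = joint_segment(mat, cfg=SegConfig(beta=0.5))
            f1s.append(score_breakpoints(seg.interior_breakpoints, cuts, 2).f1)
        assert np.mean(f1s) >= 0.95

    def test_min_region_size_floor(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(4, 60))
        seg = joint_segment(mat, cfg=SegConfig(beta=0.05, min_region_size=5))
        assert all(r.size >= 5 for r in seg.regions)


class TestCnaMatrix:
    def test_single_region_rows_constant_at_row_mean(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(3, 20))
        seg = joint_segment(np.zeros_like(mat))
        cna = build_cna_matrix(mat, seg)
        np.testing.assert_allclose(cna, mat.mean(axis=1, keepdims=True)
                                   * np.ones_like(mat))

    def test_singleton_regions_identity(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(2, 12))
        est = JointSegmenter(beta=1e-12, epsilon=1e-300)
        # a beta*nu threshold of ~0 stops before any merge
        est.fit(mat)
        if all(r.size == 1 for r in est.segmentation_.regions):
            np.testing.assert_allclose(est.transform(mat), mat)

    def test_hand_computed_region_means(self):
        mat = np.array([[1.0, 2, 3, 10, 10, 10],
                        [4.0, 4, 4, 0, 0, 6]])
        seg = joint_segment(np.array([[0.0, 0, 0, 9, 9, 9]]),
                            cfg=SegConfig(beta=0.5))
        assert seg.interior_breakpoints == [3]
        cna = build_cna_matrix(mat, seg)
        np.testing.assert_allclose(cna[0], [2, 2, 2, 10, 10, 10])
        np.testing.assert_allclose(cna[1], [4, 4, 4, 2, 2, 2])

    def test_segment_means_shape(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(size=(5, 30))
        seg = joint_segment(mat, cfg=SegConfig(beta=2.0))
        means = segment_means(mat, seg)
        assert means.shape == (5, len(seg.regions))


def test_seg_writer_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    mat = rng.normal(size=(2, 10))
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(10)],
        "chrom": ["1"] * 10,
        "start": np.arange(10) * 100 + 1,
        "end": np.arange(10) * 100 + 50,
    })
    seg = joint_segment(mat, cfg=SegConfig(beta=3.0))
    path = tmp_path / "out.seg"
    write_seg(seg, mat, ["a", "b"], genes, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["sample", "chrom", "loc.start", "loc.end",
                                "num.mark", "seg.mean"]
    assert df["num.mark"].sum() == 10 * 2  # every gene once per cell
    assert set(df["sample"]) == {"a", "b"}
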