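"""Seeded region growing: preprocessing, growth rules, invariants, QC."""

import numpy as np
import pytest

from blastovol import segmentation as seg, synthetic as syn
from blastovol.segmentation import SeedSet, _grow, iteration_budget
from blastovol.stacks import ImageStack


def flat_stack(values, spacing=(1.0, 0.5, 0.5)):
    return ImageStack(np.asarray(values, dtype=np.float32), spacing=spacing)


class TestPreprocess:
    def test_constant_image_unchanged_below_threshold(self):
        stack = flat_stack(np.full((4, 12, 12), 7.0))
        out = seg.preprocess(stack, background_threshold=5.0)
        assert np.allclose(out.voxels, 7.0)

    def test_isolated_bright_voxel_mean_filter_arithmetic(self):
        img = np.zeros((3, 11, 11), dtype=np.float32)
        img[1, 5, 5] = 25.0
        out = seg.preprocess(flat_stack(img), background_threshold=0.5)
        # 5 x 5 x 1 box mean: 25 / 25 = 1 at the centre, kept at threshold 0.5
        assert out.voxels[1, 5, 5] == pytest.approx(1.0)
        # a threshold above the filtered value removes it entirely
        out2 = seg.preprocess(flat_stack(img), background_threshold=1.5)
        assert out2.voxels[1, 5, 5] == 0.0

    def test_background_outside_embryo_is_exactly_zero(self):
        truth = syn.single_germline_cell(3.0)
        mem, _ = syn.render_embryo_stack(
            truth, noise=syn.NoiseSettings(additive_sigma=0.0), seed=0)
        out = seg.preprocess(mem, background_threshold=20.0)
        cell = truth.cells[0]
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in out.voxels.shape],
                                 indexing="ij")
        coords = np.stack([zz, yy, xx], axis=-1) * np.array(out.spacing)
        # allow for the 2-voxel in-plane smear of the box filter
        far = np.linalg.norm(coords - cell.center, axis=-1) > cell.radius + 0.4
        assert np.all(out.voxels[far] == 0.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            seg.preprocess(flat_stack(np.ones((2, 5, 5))), background_threshold=0)


class TestIterationBudget:
    @pytest.mark.parametrize("n, expected", [(9, 300), (99, 150), (1, 997)])
    def test_budget_formula(self, n, expected):
        assert iteration_budget(n) == expected

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            iteration_budget(0)


class TestSeedSet:
    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SeedSet(names=["a", "b"], coords=np.array([[1, 2, 3], [1, 2, 3]]))

    def test_csv_round_trip(self, tmp_path):
        seeds = SeedSet(names=["AB", "P1"],
                        coords=np.array([[1, 2, 3], [4, 5, 6]]))
        path = tmp_path / "seeds.csv"
        seg.write_seeds_csv(path, seeds)
        back = seg.read_seeds_csv(path)
        assert back.names == seeds.names
        assert np.array_equal(back.coords, seeds.coords)


class TestGrowSeeds:
    def test_uniform_interior_floods_and_stops_at_background(self):
        img = np.zeros((5, 24, 24), dtype=np.float32)
        img[1:4, 6:18, 6:18] = 100.0
        stack = flat_stack(img)
        lm = seg.grow_seeds(stack, SeedSet(["c"], np.array([[2, 12, 12]])),
                            q=0.98, rng_seed=0, n_coarse=80, n_fine=40,
                            downscale=1, cleanup_kernel=None)
        assert np.array_equal(lm.labels == 1, img > 0)

    def test_identical_rng_seed_gives_identical_labels(self):
        truth = syn.two_cell_embryo(mother_radius=4.0)
        mem, _ = syn.render_embryo_stack(truth, seed=5)
        names, coords = syn.seeds_from_truth(truth)
        pre = seg.preprocess(mem)
        a = seg.grow_seeds(pre, SeedSet(names, coords), rng_seed=7,
                           n_coarse=120)
        b = seg.grow_seeds(pre, SeedSet(names, coords), rng_seed=7,
                           n_coarse=120)
        assert np.array_equal(a.labels, b.labels)

    def test_seed_on_zero_voxel_rejected(self):
        img = np.zeros((3, 8, 8), dtype=np.float32)
        img[1, 4, 4] = 10.0
        with pytest.raises(ValueError, match="zero-intensity"):
            seg.grow_seeds(flat_stack(img), SeedSet(["c"], np.array([[0, 0, 0]])))

    def test_invalid_q_rejected(self):
        img = np.ones((3, 8, 8), dtype=np.float32)
        seeds = SeedSet(["c"], np.array([[1, 4, 4]]))
        with pytest.raises(ValueError):
            seg.grow_seeds(flat_stack(img), seeds, q=0.0)

    def test_growth_is_monotone_disjoint_and_avoids_background(self):
        rng_img = np.random.default_rng(11)
        img = np.zeros((5, 30, 30), dtype=np.float32)
        img[1:4, 2:28, 2:28] = 100.0 + rng_img.normal(0, 3, (3, 26, 26))
        labels = np.zeros_like(img, dtype=np.int32)
        labels[2, 8, 8] = 1
        labels[2, 8, 21] = 2
        rng = np.random.default_rng(13)
        prev_counts = np.array([1, 1])
        for _ in range(40):
            _grow(labels, img, 0.98, rng, 1)
            counts = np.array([(labels == 1).sum(), (labels == 2).sum()])
            assert np.all(counts >= prev_counts)  # regions never lose voxels
            prev_counts = counts
            assert np.all(labels[img == 0] == 0)  # background never claimed
        assert prev_counts.sum() > 200  # growth actually happened

    def test_two_cell_volumes_within_three_percent_of_truth(
            self, segmented_division_noiseless):
        data = segmented_division_noiseless["after"]
        for name, v_true in data["truth"].items():
            v_seg = data["segmented"][name]
            assert v_seg == pytest.approx(v_true, rel=0.03)

    def test_boundary_traces_membrane_within_voxels(
            self, segmented_division_noiseless):
        # along in-plane rays from the seed, the segmented boundary must sit
        # within a couple of in-plane voxels of the true cell radius
        data = segmented_division_noiseless["before"]
        lm = data["labelmap"]
        truth_cell = 9.0  # mother radius, µm
        center_vox = np.round(
            np.array([11.0, 11.0, 11.0]) / np.array(lm.spacing)).astype(int)
        z0, y0, x0 = center_vox
        lx = lm.spacing[2]
        row = lm.labels[z0, y0, :]
        xs = np.nonzero(row == 1)[0]
        for edge in (x0 - xs.min(), xs.max() - x0):
            assert edge * lx == pytest.approx(truth_cell, abs=3 * lx + 0.4)


class TestTimeseries:
    def test_single_stack_series_equals_grow_seeds(self):
        truth = syn.two_cell_embryo(mother_radius=4.0)
        mem, _ = syn.render_embryo_stack(truth, seed=3)
        names, coords = syn.seeds_from_truth(truth)
        seeds = SeedSet(names, coords)
        maps, _ = seg.segment_timeseries([mem], [seeds], rng_seed=5,
                                         n_coarse=120)
        direct = seg.grow_seeds(seg.preprocess(mem), seeds, rng_seed=5,
                                n_coarse=120)
        assert np.array_equal(maps[0].labels, direct.labels)

    def test_division_qc_below_three_percent(self, segmented_division_noiseless):
        before = segmented_division_noiseless["before"]
        after = segmented_division_noiseless["after"]
        v_mother = before["segmented"]["P1"]
        v_sum = after["segmented"]["EMS"] + after["segmented"]["P2"]
        assert abs(v_mother - v_sum) / v_mother < 0.03

    def test_empty_series_is_empty_result(self):
        maps, qc = seg.segment_timeseries([], [])
        assert maps == []
        assert qc.volumes.empty and qc.divisions.empty

    def test_mismatched_lengths_rejected(self):
        stack = flat_stack(np.ones((2, 4, 4)))
        with pytest.raises(ValueError, match="one SeedSet per stack"):
            seg.segment_timeseries([stack], [])

    def test_qc_flags_inconsistent_division(self):
        # QC flags a fabricated division whose daughters lose 10% of volume
        import pandas as pd
        from blastovol.segmentation import QCReport
        vols = pd.DataFrame({
            "name": ["M", "D1", "D2"], "timepoint": [0, 1, 1],
            "volume": [1000.0, 500.0, 400.0]})
        qc = QCReport(volumes=vols, divisions=pd.DataFrame([
            dict(mother="M", daughter1="D1", daughter2="D2",
                 deviation=0.1, flagged=True)]))
        assert len(qc.flagged) == 1
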