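"""Metrics against brute-force oracles; hole filling; region growing; folds."""

import math

import numpy as np
import pytest

from boxsup3d import (
    dice,
    directed_hausdorff,
    evaluate_cohort,
    fill_holes,
    hausdorff,
    hausdorff95,
    region_grow_baseline,
)
from boxsup3d.evaluate import SegmentationResult, evaluate_volumes


def _brute_directed(a_pts, b_pts, spacing=(1, 1, 1)):
    """Exhaustive double loop over voxel coordinate pairs."""
    sp = np.asarray(spacing, float)
    dists = []
    for a in a_pts:
        dists.append(min(np.linalg.norm((np.asarray(a) - b) * sp) for b in b_pts))
    return np.array(dists)


def _random_mask(rng, side=12, p=0.1):
    m = rng.random((side, side, side)) < p
    if not m.any():
        m[tuple(rng.integers(0, side, 3))] = True
    return m


class TestDice:
    def test_identical_nonempty(self, rng):
        m = _random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_counting_example(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.ravel()[:4] = True
        b.ravel()[1:7] = True  # |A|=4, |B|=6, |A∩B|=3
        assert dice(a, b) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_symmetry_and_shape_check(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError):
            dice(a, np.zeros((5, 5, 5), bool))


class TestHausdorff:
    def test_identical_sets_zero(self, rng):
        m = _random_mask(rng)
        assert hausdorff(m, m) == 0.0
        assert hausdorff95(m, m) == 0.0

    def test_single_pair(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 0, 0] = True
        assert directed_hausdorff(a, b) == pytest.approx(3.0)

    def test_subset_with_outlier(self):
        a = np.zeros((10, 10, 10), bool)
        a[0, 0, 0] = True
        b = a.copy()
        b[5, 0, 0] = True  # extra point at distance 5
        assert directed_hausdorff(a, b) == 0.0
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[0, 0, 1] = True
        assert hausdorff(a, b, spacing=(1, 1, 2.5)) == pytest.approx(2.5)

    def test_empty_set_gives_nan_sentinel(self):
        a = np.zeros((4, 4, 4), bool)
        b = a.copy()
        b[0, 0, 0] = True
        assert math.isnan(directed_hausdorff(a, b))
        assert math.isnan(hausdorff95(a, b))

    def test_collinear_shift_hd95(self):
        """100 collinear points (spaced 3 voxels) vs the same set shifted by
        one voxel: every nearest distance equals 1, so hd95 is exactly 1.0."""
        a = np.zeros((302, 3, 3), bool)
        b = np.zeros((302, 3, 3), bool)
        a[0:300:3, 1, 1] = True
        b[1:301:3, 1, 1] = True
        assert a.sum() == b.sum() == 100
        assert hausdorff95(a, b) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            a, b = _random_mask(rng), _random_mask(rng)
            spacing = tuple(rng.uniform(0.5, 2.0, 3))
            a_pts, b_pts = np.argwhere(a), np.argwhere(b)
            d_ab = _brute_directed(a_pts, b_pts, spacing)
            d_ba = _brute_directed(b_pts, a_pts, spacing)
            assert directed_hausdorff(a, b, spacing) == pytest.approx(d_ab.max(), abs=1e-9)
            assert hausdorff(a, b, spacing) == pytest.approx(
                max(d_ab.max(), d_ba.max()), abs=1e-9
            )
            hd95 = max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
            assert hausdorff95(a, b, spacing) == pytest.approx(hd95, abs=1e-9)
            assert hausdorff95(a, b, spacing) <= hausdorff(a, b, spacing) + 1e-12


class TestFillHoles:
    def test_single_voxel_cavity_filled(self):
        m = np.zeros((7, 7, 7), bool)
        m[2:5, 2:5, 2:5] = True
        m[3, 3, 3] = False
        assert fill_holes(m)[3, 3, 3]

    def test_no_cavity_unchanged(self, rng):
        m = _random_mask(rng, p=0.05)
        filled = fill_holes(m)
        # sparse random voxels rarely enclose cavities; monotone either way
        assert (filled & m).sum() == m.sum()

    def test_hollow_shell_filled_to_cube(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        m[3:6, 3:6, 3:6] = False  # hollow 5^3 shell
        assert fill_holes(m).sum() == 5**3

    def test_idempotent_and_monotone(self, rng):
        m = _random_mask(rng, p=0.3)
        once = fill_holes(m)
        assert np.array_equal(fill_holes(once), once)
        assert (once | m).sum() == once.sum()


class TestRegionGrow:
    def _step_phantom(self):
        """Noise-free piecewise-constant phantom: tumor step of 2 units."""
        ch = np.zeros((24, 24, 24), dtype=np.float32)
        ch[2:22, 2:22, 2:22] = 1.0
        tumor = np.zeros_like(ch, dtype=bool)
        tumor[8:14, 8:14, 8:14] = True
        ch[tumor] = 3.0
        return ch, tumor

    def test_recovers_component_exactly(self):
        ch, tumor = self._step_phantom()
        grown = region_grow_baseline(ch, (10, 10, 10), threshold=0.5)
        assert np.array_equal(grown, tumor)

    def test_zero_threshold_keeps_seed_only(self):
        ch, _ = self._step_phantom()
        grown = region_grow_baseline(ch, (10, 10, 10), threshold=0.0)
        assert grown.sum() == 1

    def test_seed_on_background_errors(self):
        ch, _ = self._step_phantom()
        with pytest.raises(ValueError, match="background"):
            region_grow_baseline(ch, (0, 0, 0))

    def test_grown_region_is_connected_and_contains_seed(self, normalized_phantom):
        from scipy import ndimage

        vol, _, box = normalized_phantom
        seed = tuple((l + h) // 2 for l, h in zip(box.low, box.high))
        grown = region_grow_baseline(vol.intensities, seed, threshold=0.5)
        assert grown[seed]
        _, n = ndimage.label(grown, ndimage.generate_binary_structure(3, 1))
        assert n == 1


class TestEvaluateCohort:
    def _perfect(self, rng, n=10):
        gts = [_random_mask(rng, p=0.2) for _ in range(n)]
        results = [
            SegmentationResult(g.astype(np.float32), patient_id=f"p{i}")
            for i, g in enumerate(gts)
        ]
        return results, gts

    def test_perfect_predictions(self, rng):
        results, gts = self._perfect(rng)
        report = evaluate_cohort(results, gts, seed=0)
        assert report.summary["dice"]["mean"] == pytest.approx(1.0)
        assert report.summary["dice"]["std"] == pytest.approx(0.0)

    def test_five_folds_reported(self, rng):
        results, gts = self._perfect(rng, n=30)
        report = evaluate_cohort(results, gts, seed=1)
        assert len(report.folds) == 5

    def test_fold_aggregate_arithmetic(self, rng):
        """Cohort mean/std equal hand-computed aggregates of fold means."""
        results, gts = self._perfect(rng, n=10)
        # corrupt some predictions so folds differ
        for i in (1, 4, 7):
            prob = gts[i].astype(np.float32) * 0.0
            prob[0, 0, 0] = 1.0
            results[i] = SegmentationResult(prob, patient_id=f"p{i}")
        report = evaluate_cohort(results, gts, seed=3)
        vals = report.folds["dice_mean"].to_numpy()
        assert report.summary["dice"]["mean"] == pytest.approx(vals.mean())
        assert report.summary["dice"]["std"] == pytest.approx(vals.std())

    def test_too_small_cohort_rejected(self, rng):
        results, gts = self._perfect(rng, n=3)
        with pytest.raises(ValueError, match="at least 5"):
            evaluate_cohort(results, gts)

    def test_empty_prediction_scores_dice_zero_hausdorff_missing(self, rng):
        gts = [_random_mask(rng, p=0.2) for _ in range(5)]
        results = [
            SegmentationResult(np.zeros_like(g, dtype=np.float32), patient_id=f"p{i}")
            for i, g in enumerate(gts)
        ]
        df = evaluate_volumes(results, gts)
        assert (df["dice"] == 0.0).all()
        assert df["hausdorff"].isna().all()
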