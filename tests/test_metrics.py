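"""DSC / HD95 / correction-region behaviour against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autosegeval import BinaryMask, dice, hd95, restrict_to_region, superellipsoid
from autosegeval.metrics import metrics_for_cohort

from ._oracles import brute_dice, brute_hd95
from .conftest import random_blob


def block(shape, lo, size, spacing=(1.0, 1.0, 1.0)):
    v = np.zeros(shape, dtype=bool)
    v[lo[0]:lo[0] + size[0], lo[1]:lo[1] + size[1], lo[2]:lo[2] + size[2]] = True
    return BinaryMask(v, spacing)


class TestDice:
    def test_identical_masks_give_one(self):
        m = block((8, 8, 8), (2, 2, 2), (3, 3, 3))
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = block((10, 10, 10), (0, 0, 0), (2, 2, 2))
        b = block((10, 10, 10), (6, 6, 6), (2, 2, 2))
        assert dice(a, b) == 0.0

    def test_shifted_block_half_overlap(self):
        # 2x2x2 blocks shifted one voxel: |A|=|B|=8, |A∩B|=4 -> 0.5
        a = block((8, 8, 8), (2, 2, 2), (2, 2, 2))
        b = block((8, 8, 8), (3, 2, 2), (2, 2, 2))
        assert dice(a, b) == pytest.approx(0.5, abs=0)
        assert dice(a, b) == brute_dice(a, b)

    def test_spacing_invariance(self, rng):
        a = random_blob((14, 14, 14), (1, 1, 1), rng)
        b = random_blob((14, 14, 14), (1, 1, 1), rng)
        a2 = BinaryMask(a.voxels, (2.5, 1.0, 3.0))
        b2 = BinaryMask(b.voxels, (2.5, 1.0, 3.0))
        assert dice(a, b) == dice(a2, b2)

    def test_errors(self):
        a = block((8, 8, 8), (2, 2, 2), (2, 2, 2))
        with pytest.raises(ValueError):
            dice(a, block((9, 8, 8), (2, 2, 2), (2, 2, 2)))
        with pytest.raises(ValueError):
            dice(a, BinaryMask(a.voxels, (2, 2, 2)))
        empty = BinaryMask(np.zeros((8, 8, 8), bool))
        with pytest.raises(ValueError):
            dice(empty, empty)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        a = random_blob((10, 10, 10), (1, 1, 1), r, frac=70)
        b = random_blob((10, 10, 10), (1, 1, 1), r, frac=70)
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


class TestHD95:
    def test_identical_masks_give_zero(self):
        m = block((8, 8, 8), (2, 2, 2), (3, 3, 3))
        assert hd95(m, m) == 0.0

    def test_single_voxel_pair_distance(self):
        v1 = np.zeros((12, 12, 12), bool); v1[2, 2, 2] = True
        v2 = np.zeros((12, 12, 12), bool); v2[2, 2, 9] = True
        a, b = BinaryMask(v1, (1, 1, 1)), BinaryMask(v2, (1, 1, 1))
        assert hd95(a, b) == pytest.approx(7.0, abs=1e-12)

    def test_oracle_equivalence_small_sample(self, rng):
        for _ in range(10):
            sh = tuple(rng.integers(10, 25, 3))
            sp = tuple(rng.choice([1.0, 1.5, 2.0], 3))
            a, b = random_blob(sh, sp, rng), random_blob(sh, sp, rng)
            assert hd95(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)
            assert hd95(a, b) == hd95(b, a)

    def test_linear_scaling_with_spacing(self, rng):
        a = random_blob((14, 14, 14), (1, 1, 1), rng)
        b = random_blob((14, 14, 14), (1, 1, 1), rng)
        a2 = BinaryMask(a.voxels, (3, 3, 3))
        b2 = BinaryMask(b.voxels, (3, 3, 3))
        assert hd95(a2, b2) == pytest.approx(3 * hd95(a, b), rel=1e-12)

    def test_bounded_by_exact_hausdorff(self, rng):
        from scipy.spatial.distance import cdist

        from autosegeval.metrics import boundary_voxels
        for _ in range(5):
            a = random_blob((12, 12, 12), (1, 1, 1), rng)
            b = random_blob((12, 12, 12), (1, 1, 1), rng)
            pa = np.argwhere(boundary_voxels(a)).astype(float)
            pb = np.argwhere(boundary_voxels(b)).astype(float)
            D = cdist(pa, pb)
            hd100 = max(D.min(axis=1).max(), D.min(axis=0).max())
            assert hd95(a, b) <= hd100 + 1e-12

    def test_empty_mask_rejected(self):
        a = block((8, 8, 8), (2, 2, 2), (2, 2, 2))
        with pytest.raises(ValueError):
            hd95(a, BinaryMask(np.zeros((8, 8, 8), bool)))


class TestRestrictToRegion:
    def test_huge_margin_is_identity(self):
        m = block((10, 10, 10), (1, 1, 1), (4, 4, 4), (2, 2, 2))
        t = block((10, 10, 10), (7, 7, 7), (1, 1, 1), (2, 2, 2))
        out = restrict_to_region(m, t, 1e4)
        assert np.array_equal(out.voxels, m.voxels)

    def test_zero_margin_is_intersection(self):
        m = block((10, 10, 10), (1, 1, 1), (5, 5, 5), (2, 2, 2))
        t = block((10, 10, 10), (4, 4, 4), (4, 4, 4), (2, 2, 2))
        out = restrict_to_region(m, t, 0.0)
        assert np.array_equal(out.voxels, m.voxels & t.voxels)

    def test_single_voxel_target_matches_exhaustive_ball(self):
        # every voxel centre within 4 mm of the target centre, 2 mm spacing
        sp = (2.0, 2.0, 2.0)
        t = np.zeros((9, 9, 9), bool); t[4, 4, 4] = True
        m = BinaryMask(np.ones((9, 9, 9), bool), sp)
        out = restrict_to_region(m, BinaryMask(t, sp), 4.0)
        centers = np.indices((9, 9, 9)).reshape(3, -1).T * 2.0
        d = np.sqrt(((centers - np.array([8.0, 8.0, 8.0])) ** 2).sum(axis=1))
        expected = (d <= 4.0).reshape(9, 9, 9)
        assert np.array_equal(out.voxels, expected)

    def test_empty_target_rejected(self):
        m = block((8, 8, 8), (1, 1, 1), (2, 2, 2))
        with pytest.raises(ValueError):
            restrict_to_region(m, BinaryMask(np.zeros((8, 8, 8), bool)), 5.0)


def test_metrics_table_emits_missing_rows():
    from autosegeval import CohortConfig, generate_cohort

    cfg = CohortConfig(n_patients=2, organs=("prostate", "bowel"),
                       exclude_bowel_patient=1, seed=3)
    mt = metrics_for_cohort(generate_cohort(cfg))
    assert len(mt) == 2 * 2 * 2 * 3
    miss = mt[mt["missing"]]
    assert set(miss["organ"]) == {"bowel"}
    assert set(miss["patient_id"]) == {"P01"}
    assert miss["dsc"].isna().all()
    assert len(miss) == 2 * 3
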