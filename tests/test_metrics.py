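import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import random_blob_pair
from provseg.metrics import (
    contour_dice,
    dice,
    rtog_pass_rate,
    slice_contour,
    surface_distances,
    surface_voxels,
    true_positive_filter,
    uncertainty_density,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths)
# ---------------------------------------------------------------------------


def brute_surface_distances(a, b, spacing):
    pa = np.argwhere(surface_voxels(a)) * np.array(spacing)
    pb = np.argwhere(surface_voxels(b)) * np.array(spacing)
    d = cdist(pa, pb)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return (d_ab.mean() + d_ba.mean()) / 2.0, max(d_ab.max(), d_ba.max())


def brute_contour_dice(a, b, tol, spacing):
    _, sy, sx = spacing
    matched = total = 0
    for z in range(a.shape[0]):
        ca = np.argwhere(slice_contour(a[z])) * np.array([sy, sx])
        cb = np.argwhere(slice_contour(b[z])) * np.array([sy, sx])
        total += len(ca) + len(cb)
        if len(ca) and len(cb):
            d = cdist(ca, cb)
            matched += int((d.min(axis=1) <= tol).sum())
            matched += int((d.min(axis=0) <= tol).sum())
    return 1.0 if total == 0 else matched / total


def brute_wilcoxon_two_sided(x, y):
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    m = n * (n + 1) / 2
    w_low = min(w_plus, m - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, m - w) <= w_low:
            count += 1
    return count / 2**n


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------


class TestDice:
    def test_identity_disjoint_and_empty(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        b = np.zeros_like(a)
        b[3, 3, 3] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0
        assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0
        assert dice(a, np.zeros_like(a)) == 0.0

    def test_hand_counted_toy(self):
        a = np.zeros((1, 2, 4), bool)
        b = np.zeros_like(a)
        a[0, 0, :4] = True          # |A| = 4
        b[0, 0, 2:4] = True         # |B| = 2, overlap 2
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_symmetry_and_mirror_invariance(self):
        a, b, _ = random_blob_pair(3)
        assert dice(a, b) == dice(b, a)
        assert dice(a[:, :, ::-1], b[:, :, ::-1]) == dice(a, b)


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:4, 1:4, 1:4] = True
        assert surface_distances(a, a, (1.0, 1.0, 1.0)) == (0.0, 0.0)

    def test_single_voxels_four_apart(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros_like(a)
        a[5, 5, 2] = True
        b[5, 5, 6] = True
        msd, hd = surface_distances(a, b, (1.5, 1.5, 1.5))
        assert msd == pytest.approx(6.0)
        assert hd == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        a = np.zeros((4, 4, 4), bool)
        b = a.copy()
        b[1, 1, 1] = True
        with pytest.raises(ValueError, match="empty"):
            surface_distances(a, b, (1, 1, 1))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_masks(self, seed):
        a, b, spacing = random_blob_pair(seed)
        msd, hd = surface_distances(a, b, spacing)
        msd_ref, hd_ref = brute_surface_distances(a, b, spacing)
        assert msd == pytest.approx(msd_ref, abs=1e-6)
        assert hd == pytest.approx(hd_ref, abs=1e-6)

    def test_hausdorff_dominates_msd(self):
        for seed in range(5):
            a, b, spacing = random_blob_pair(seed + 50)
            msd, hd = surface_distances(a, b, spacing)
            assert hd >= msd


# ---------------------------------------------------------------------------
# contour dice
# ---------------------------------------------------------------------------


class TestContourDice:
    def test_identical_masks_score_one(self):
        a, _, spacing = random_blob_pair(1)
        for tol in (1.0, 3.0):
            assert contour_dice(a, a, tol, spacing) == 1.0

    def test_saturates_for_huge_tolerance(self):
        a, b, spacing = random_blob_pair(2)
        assert contour_dice(a, b, 1000.0, spacing) == 1.0

    def test_shifted_rectangle_matches_exhaustive_computation(self):
        a = np.zeros((3, 16, 16), bool)
        b = np.zeros_like(a)
        a[1, 4:10, 4:12] = True
        b[1, 6:12, 4:12] = True  # shifted 2 voxels on a 1-mm grid
        spacing = (1.0, 1.0, 1.0)
        for tol in (1.0, 3.0):
            assert contour_dice(a, b, tol, spacing) == pytest.approx(
                brute_contour_dice(a, b, tol, spacing), abs=1e-9
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_masks(self, seed):
        a, b, spacing = random_blob_pair(seed + 10)
        for tol in (1.0, 3.0, 5.0):
            assert contour_dice(a, b, tol, spacing) == pytest.approx(
                brute_contour_dice(a, b, tol, spacing), abs=1e-9
            )

    def test_non_decreasing_in_tolerance(self):
        a, b, spacing = random_blob_pair(20)
        vals = [contour_dice(a, b, t, spacing) for t in (1, 3, 5, 7, 10)]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))

    def test_both_empty_everywhere_scores_one(self):
        z = np.zeros((2, 4, 4), bool)
        assert contour_dice(z, z, 1.0, (1, 1, 1)) == 1.0


# ---------------------------------------------------------------------------
# RTOG passing rate
# ---------------------------------------------------------------------------


class TestRtogPassRate:
    def test_hand_counted(self):
        assert rtog_pass_rate([5, 6, 8]) == pytest.approx(100 * 2 / 3)

    def test_saturation(self):
        assert rtog_pass_rate([1.0, 6.9, 7.0]) == 100.0

    def test_matches_direct_recount(self, rng):
        hds = rng.uniform(0, 15, size=45)
        expected = 100.0 * sum(1 for h in hds if h <= 7.0) / 45
        assert rtog_pass_rate(hds) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rtog_pass_rate([])


# ---------------------------------------------------------------------------
# uncertainty density
# ---------------------------------------------------------------------------


class TestUncertaintyDensity:
    def test_constant_field_returns_constant(self):
        pred = np.zeros((8, 8, 8), bool)
        pred[3:5, 3:5, 3:5] = True
        u = np.full((8, 8, 8), 0.42)
        for tol in (1.5, 4.5):
            assert uncertainty_density(u, pred, pred, tol, (1.5, 1.5, 1.5)) == pytest.approx(0.42)

    def test_zero_entropy_returns_zero(self):
        pred = np.zeros((6, 6, 6), bool)
        pred[2:4, 2:4, 2:4] = True
        assert uncertainty_density(np.zeros((6, 6, 6)), pred, pred, 3.0, (1, 1, 1)) == 0.0

    def test_matches_hand_enumeration_on_toy_grid(self):
        # 8^3 grid, 2^3 predicted cube, tau = 1.5 mm on a 1-mm grid
        shape = (8, 8, 8)
        pred = np.zeros(shape, bool)
        pred[3:5, 3:5, 3:5] = True
        rng = np.random.default_rng(0)
        u = rng.random(shape)
        spacing = (1.0, 1.0, 1.0)
        tol = 1.5
        surf = np.argwhere(surface_voxels(pred)) * np.array(spacing)
        coords = np.indices(shape).reshape(3, -1).T * np.array(spacing)
        band = cdist(coords, surf).min(axis=1) <= tol
        expected = u.reshape(-1)[band].mean()
        assert uncertainty_density(u, pred, pred, tol, spacing) == pytest.approx(expected, abs=1e-12)

    def test_false_positive_components_excluded(self):
        shape = (8, 10, 10)
        pred = np.zeros(shape, bool)
        ref = np.zeros(shape, bool)
        pred[2:4, 2:4, 2:4] = True   # overlaps reference
        pred[6:8, 7:10, 7:10] = True  # disconnected false positive
        ref[2:4, 2:4, 2:4] = True
        filtered = true_positive_filter(pred, ref)
        assert filtered[2:4, 2:4, 2:4].all()
        assert not filtered[6:8, 7:10, 7:10].any()
        u = np.zeros(shape)
        u[6:8, 7:10, 7:10] = 1.0  # entropy only near the false positive
        val = uncertainty_density(u, pred, ref, 1.0, (1, 1, 1))
        assert val == pytest.approx(0.0)

    def test_no_true_positive_returns_none(self):
        pred = np.zeros((6, 6, 6), bool)
        ref = np.zeros_like(pred)
        pred[0:2, 0:2, 0:2] = True
        ref[4:6, 4:6, 4:6] = True
        assert uncertainty_density(np.ones((6, 6, 6)), pred, ref, 1.5, (1, 1, 1)) is None

    def test_invalid_tolerance_rejected(self):
        pred = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="tolerance"):
            uncertainty_density(np.zeros((2, 2, 2)), pred, pred, 0.0, (1, 1, 1))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_exact_matches_enumeration_for_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = x + 0.8 + rng.normal(scale=0.3, size=10)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(brute_wilcoxon_two_sided(x, y), abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        x = np.arange(8.0)
        assert wilcoxon_signed_rank(x, x.copy()) == 1.0

    def test_larger_shift_gives_smaller_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        noise = rng.normal(scale=0.2, size=12)
        p_small = wilcoxon_signed_rank(x, x + 0.2 + noise)
        p_large = wilcoxon_signed_rank(x, x + 2.0 + noise)
        assert p_large < p_small

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = x + 0.5
        p = wilcoxon_signed_rank(x, y)
        assert 0.0 < p < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])
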