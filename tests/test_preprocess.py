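"""Balancing, thinning, scaling, and tiling geometry."""

import numpy as np
import pytest

import panelhic as ph


def sinkhorn_ipf(m: np.ndarray, iters=2000) -> np.ndarray:
    """Independent symmetric iterative-proportional-fitting oracle.

    Alternately rescales rows/columns by 1/sqrt(row sum) until the matrix is
    balanced to unit row sums.
    """
    b = m.astype(float).copy()
    for _ in range(iters):
        r = b.sum(axis=1)
        d = 1.0 / np.sqrt(r)
        b = b * d[:, None] * d[None, :]
    return b


class TestIceBalance:
    def test_doubly_stochastic_band_yields_unit_weights(self):
        # circulant symmetric matrix with constant row sums
        n = 8
        m = np.zeros((n, n))
        for i in range(n):
            m[i, i] = 2.0
            m[i, (i + 1) % n] = 1.0
            m[(i + 1) % n, i] = 1.0
        m = np.triu(m)
        cm = ph.ContactMap("c", 5000, m, max_distance_bins=n - 1)
        bal = ph.ice_balance(cm, mask_quantile=0.0)
        w = bal.weights
        assert np.allclose(w, w[0])
        rs = bal.dense(balanced=True).sum(axis=1)
        assert np.allclose(rs, 1.0, atol=1e-4)

    def test_4x4_dense_matches_ipf_oracle(self):
        rng = np.random.default_rng(0)
        full = rng.integers(1, 40, (4, 4)).astype(float)
        full = full + full.T
        cm = ph.ContactMap("c", 5000, np.triu(full), max_distance_bins=3)
        bal = ph.ice_balance(cm, tol=1e-12, max_iter=5000, mask_quantile=0.0)
        ours = bal.dense(balanced=True)
        oracle = sinkhorn_ipf(full)
        assert np.allclose(ours, oracle, atol=1e-6)

    def test_zero_coverage_bin_is_masked_and_rest_balanced(self):
        rng = np.random.default_rng(1)
        full = rng.integers(1, 20, (6, 6)).astype(float)
        full = np.triu(full + full.T)
        full[2, :] = 0
        full[:, 2] = 0
        cm = ph.ContactMap("c", 5000, full, max_distance_bins=5)
        bal = ph.ice_balance(cm, mask_quantile=0.0)
        assert np.isnan(bal.weights[2])
        rs = bal.dense(balanced=True).sum(axis=1)
        keep = np.arange(6) != 2
        assert np.allclose(rs[keep], 1.0, atol=1e-3)

    def test_fully_empty_matrix_is_an_error(self):
        cm = ph.ContactMap("c", 5000, np.zeros((4, 4)), max_distance_bins=3)
        with pytest.raises(ValueError, match="unmasked"):
            ph.ice_balance(cm)


class TestDownsample:
    def test_ratio_one_is_identity(self, rng):
        from conftest import random_banded_map
        cm = random_banded_map(rng)
        out = ph.downsample(cm, 1.0, seed=0)
        assert np.array_equal(out.counts, cm.counts)

    @pytest.mark.parametrize("ratio", [0.0, -0.1, 1.5])
    def test_out_of_range_ratio_is_rejected(self, ratio, small_counts):
        with pytest.raises(ValueError, match="ratio"):
            ph.downsample(small_counts, ratio, seed=0)

    def test_total_within_4_sd_of_binomial_expectation(self, small_counts):
        total = small_counts.counts.sum()
        for ratio in (0.5, 1 / 16):
            out = ph.downsample(small_counts, ratio, seed=3)
            sd = np.sqrt(total * ratio * (1 - ratio))
            assert abs(out.counts.sum() - ratio * total) < 4 * sd

    def test_sixteenth_of_4000_is_250(self):
        """Coverage semantics: 1/16 of 4000 M valid pairs is 250 M."""
        assert 4000 * (1 / 16) == 250

    def test_thinning_composition_matches_single_step_in_mean_and_variance(self):
        spec = ph.GenomeSpec(n_bins=40, noise_dispersion=0.0)
        ct = ph.CellTypeSpec(base=spec, seed=0)
        cm = ph.sample_counts(ph.expected_map(ct), 50_000, seed=0)
        r1, r2 = 0.5, 0.5
        tot_two, tot_one = [], []
        for s in range(200):
            step = ph.downsample(ph.downsample(cm, r1, seed=2 * s), r2,
                                 seed=2 * s + 1)
            tot_two.append(step.counts.sum())
            tot_one.append(ph.downsample(cm, r1 * r2, seed=10_000 + s).counts.sum())
        tot_two, tot_one = np.array(tot_two), np.array(tot_one)
        se = np.sqrt(tot_one.var() / 200 + tot_two.var() / 200)
        assert abs(tot_two.mean() - tot_one.mean()) < 4 * se
        assert 0.6 < tot_two.var() / tot_one.var() < 1.6

    def test_float_counts_are_rejected(self, rng):
        from conftest import random_banded_map
        cm = random_banded_map(rng, float_values=True)
        with pytest.raises(ValueError, match="integer"):
            ph.downsample(cm, 0.5, seed=0)


class TestScalePatch:
    def test_all_zero_patch_scales_to_zero_with_floor_scale(self):
        p = ph.scale_patch(np.zeros((8, 8)), np.ones((8, 8), bool))
        assert np.all(p.values == 0)
        assert p.scale == pytest.approx(1e-6)

    def test_inverse_restores_values(self, rng):
        v = rng.random((16, 16)) * 10
        mask = rng.random((16, 16)) > 0.1
        p = ph.scale_patch(v, mask)
        back = ph.unscale_values(p.values, p.scale)
        assert np.allclose(back[mask], v[mask], atol=1e-6)
        assert p.values[mask].min() >= 0 and p.values[mask].max() <= 1

    def test_scaling_preserves_value_ranking(self, rng):
        v = rng.random((12, 12)) * 100
        mask = np.ones((12, 12), bool)
        p = ph.scale_patch(v, mask)
        assert np.array_equal(np.argsort(v.ravel()), np.argsort(p.values.ravel()))

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="mask"):
            ph.scale_patch(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestTilePlan:
    def test_chromosome_equal_to_window_gives_single_tile(self):
        plan = ph.make_tile_plan(n_bins=40, w=40, trim=10, max_distance_bins=39)
        assert plan.tiles == [(0, 0)]
        assert plan.cores == [(0, 40)]

    def test_band_coverage_is_exact_partition(self):
        """Brute-force audit: every band pixel is covered by exactly one core."""
        n, w, trim, band = 1000, 200, 10, 600
        plan = ph.make_tile_plan(n, w, trim, band)
        assert plan.step == 180
        cover = np.zeros((n, n), dtype=int)
        for corner in plan.tiles:
            r0, r1, c0, c1 = plan.core_bounds(corner)
            rows = np.arange(r0, r1)
            cols = np.arange(c0, c1)
            d = cols[None, :] - rows[:, None]
            keep = (d >= 0) & (d <= band)
            cover[r0:r1, c0:c1] += keep
        i, j = np.indices((n, n), sparse=True)
        in_band = (j - i >= 0) & (j - i <= band)
        assert np.all(cover[in_band] == 1)
        assert np.all(cover[~in_band] == 0)
        # and every tile contributes at least one band pixel
        for corner in plan.tiles:
            r0, r1, c0, c1 = plan.core_bounds(corner)
            assert c0 - (r1 - 1) <= band

    def test_interior_cores_are_180x180(self):
        plan = ph.make_tile_plan(1000, 200, 10, 600)
        interior = plan.cores[1:-1]
        for a, b in interior[:-1]:
            assert b - a == 180

    def test_window_larger_than_chromosome_tells_user_to_pad(self):
        with pytest.raises(ValueError, match="pad"):
            ph.make_tile_plan(100, 200, 10, 50)

    def test_window_must_be_divisible_by_8(self):
        with pytest.raises(ValueError, match="divisible"):
            ph.make_tile_plan(500, 100, 10, 50)


class TestExtractPatch:
    def test_diagonal_corner_patch_is_symmetric(self, small_balanced):
        v, m = ph.extract_patch(small_balanced, (20, 20), 40)
        assert np.allclose(v, v.T)
        assert np.array_equal(m, m.T)

    def test_band_edge_mask_matches_brute_force(self, small_balanced):
        band = small_balanced.max_distance_bins
        corner = (0, 140)
        v, m = ph.extract_patch(small_balanced, corner, 40)
        for a in range(40):
            for b in range(40):
                expected = abs((corner[1] + b) - (corner[0] + a)) <= band
                expected &= np.isfinite(small_balanced.weights[corner[0] + a])
                expected &= np.isfinite(small_balanced.weights[corner[1] + b])
                assert m[a, b] == expected

    def test_masked_bins_propagate_into_patch_mask(self, small_balanced):
        cm = small_balanced.copy_with()
        cm.weights = cm.weights.copy()
        cm.weights[25] = np.nan
        v, m = ph.extract_patch(cm, (20, 20), 40)
        assert not m[5, :].any() and not m[:, 5].any()
        assert np.all(v[5, :] == 0)

    def test_out_of_range_corner_is_rejected(self, small_balanced):
        with pytest.raises(ValueError, match="corner"):
            ph.extract_patch(small_balanced, (190, 190), 40)
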