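"""Patch metrics, diagonal correlations, and stratum-adjusted correlation."""

import numpy as np
import pytest
from scipy.stats import pearsonr, rankdata, spearmanr

import panelhic as ph


def ssim_sliding_window_oracle(x, y, data_range, win=11, sigma=1.5,
                               k1=0.01, k2=0.03):
    """Independent SSIM: explicit Gaussian-weighted local stats per window,
    averaged over all fully interior window positions."""
    r = win // 2
    ax = np.arange(-r, r + 1)
    g1 = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    n = x.shape[0]
    vals = []
    for i in range(r, n - r):
        for j in range(r, n - r):
            xw = x[i - r:i + r + 1, j - r:j + r + 1]
            yw = y[i - r:i + r + 1, j - r:j + r + 1]
            ux = (kernel * xw).sum()
            uy = (kernel * yw).sum()
            vx = (kernel * xw * xw).sum() - ux ** 2
            vy = (kernel * yw * yw).sum() - uy ** 2
            cxy = (kernel * xw * yw).sum() - ux * uy
            vals.append(((2 * ux * uy + c1) * (2 * cxy + c2))
                        / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


class TestPatchMetrics:
    def test_perfect_prediction_hits_metric_extremes(self, rng):
        t = rng.random((32, 32))
        m = ph.patch_metrics(t.copy(), t)
        assert m["mse"] == 0 and m["mae"] == 0
        assert m["ssim"] == pytest.approx(1.0)
        assert np.isinf(m["psnr"])

    def test_constant_offset_gives_analytic_mse_and_psnr(self):
        t = np.zeros((32, 32))
        t[0, 0] = 1.0  # dynamic range R = 1
        p = t + 0.1
        m = ph.patch_metrics(p, t)
        assert m["mse"] == pytest.approx(0.01, abs=1e-12)
        assert m["mae"] == pytest.approx(0.1, abs=1e-12)
        assert m["psnr"] == pytest.approx(20.0, abs=1e-9)

    def test_ssim_matches_sliding_window_oracle(self, rng):
        t = rng.random((32, 32))
        p = np.clip(t + rng.normal(0, 0.1, (32, 32)), 0, None)
        r = float(t.max())
        ours = ph.patch_metrics(p, t)["ssim"]
        oracle = ssim_sliding_window_oracle(p, t, r)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_masked_pixels_are_excluded_from_errors(self, rng):
        t = rng.random((16, 16))
        p = t.copy()
        p[0, 0] = 100.0
        mask = np.ones((16, 16), bool)
        mask[0, 0] = False
        m = ph.patch_metrics(p, t, mask)
        assert m["mse"] == 0

    def test_fully_masked_patch_is_an_error(self):
        with pytest.raises(ValueError, match="masked"):
            ph.patch_metrics(np.ones((8, 8)), np.ones((8, 8)),
                             np.zeros((8, 8), bool))


class TestDiagonalCorrelation:
    def test_identical_maps_correlate_perfectly_at_every_distance(self, rng):
        m = rng.random((30, 30))
        m = m + m.T
        out = ph.diagonal_correlation(m, m, 10, "pcc")
        assert np.allclose(out["pcc"].dropna(), 1.0)

    def test_negated_map_gives_minus_one_pcc(self, rng):
        m = rng.random((30, 30))
        m = m + m.T
        out = ph.diagonal_correlation(-m + 5.0, m, 10, "pcc")
        assert np.allclose(out["pcc"].dropna(), -1.0)

    @pytest.mark.parametrize("kind", ["pcc", "srcc"])
    def test_matches_independent_per_diagonal_loop(self, rng, kind):
        a = rng.random((25, 25))
        a = a + a.T
        b = rng.random((25, 25))
        b = b + b.T
        out = ph.diagonal_correlation(a, b, 8, kind)
        for k in range(9):
            x, y = np.diagonal(a, k), np.diagonal(b, k)
            expect = (pearsonr(x, y).statistic if kind == "pcc"
                      else spearmanr(x, y).statistic)
            assert out[kind][k] == pytest.approx(expect, abs=1e-12)

    def test_degenerate_distances_report_missing(self):
        m = np.ones((5, 5))
        out = ph.diagonal_correlation(m, m, 4, "pcc")
        assert out["pcc"].isna().all()  # zero variance everywhere


class TestHicrepScc:
    def test_identical_maps_score_one_regardless_of_smoothing(self, small_balanced):
        for h in (0, 1, 3):
            assert ph.hicrep_scc(small_balanced, small_balanced,
                                 smooth_h=h) == pytest.approx(1.0)

    def test_independent_noise_maps_score_near_zero(self):
        """Null simulation: maps with no shared structure give |SCC| < 0.1."""
        sccs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            i, j = np.indices((500, 500), sparse=True)
            band = (j - i >= 0) & (j - i <= 100)
            a = np.where(band, rng.poisson(5, (500, 500)), 0).astype(float)
            b = np.where(band, rng.poisson(5, (500, 500)), 0).astype(float)
            ca = ph.ContactMap("c", 5000, a, max_distance_bins=100)
            cb = ph.ContactMap("c", 5000, b, max_distance_bins=100)
            sccs.append(ph.hicrep_scc(ca, cb, smooth_h=0, max_distance_bins=100))
        assert np.all(np.abs(sccs) < 0.1)

    @pytest.mark.parametrize("kind", ["pcc", "srcc"])
    def test_three_stratum_toy_matches_direct_formula(self, rng, kind):
        """Oracle: hand-evaluated sum(w_k rho_k) / sum(w_k) on 3 strata."""
        n = 12
        a = rng.random((n, n)) * 4
        a = a + a.T
        b = a + rng.normal(0, 0.5, (n, n))
        b = (b + b.T) / 2
        num = den = 0.0
        for k in range(3):
            x, y = np.diagonal(a, k).copy(), np.diagonal(b, k).copy()
            if kind == "srcc":
                x, y = rankdata(x), rankdata(y)
            rho = pearsonr(x, y).statistic
            wk = len(x) * np.std(x) * np.std(y)
            num += wk * rho
            den += wk
        oracle = num / den
        ours = ph.hicrep_scc(a, b, smooth_h=0, max_distance_bins=2, kind=kind)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_scc_is_symmetric_in_its_arguments(self, rng):
        a = rng.random((40, 40))
        a = a + a.T
        b = rng.random((40, 40))
        b = b + b.T
        assert ph.hicrep_scc(a, b, max_distance_bins=15) == pytest.approx(
            ph.hicrep_scc(b, a, max_distance_bins=15), abs=1e-12)

    def test_pcc_variant_is_invariant_to_positive_affine_transform(self, rng):
        a = rng.random((40, 40))
        a = a + a.T
        b = rng.random((40, 40))
        b = b + b.T
        base = ph.hicrep_scc(a, b, smooth_h=0, max_distance_bins=15)
        scaled = ph.hicrep_scc(3.0 * a + 2.0, b, smooth_h=0, max_distance_bins=15)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_no_computable_stratum_is_an_error(self):
        m = np.ones((4, 4))
        with pytest.raises(ValueError, match="stratum"):
            ph.hicrep_scc(m, m, smooth_h=0, max_distance_bins=2)


class TestEvaluateMaps:
    def test_report_tables_have_expected_shape(self, small_balanced):
        pred = small_balanced.copy_with(
            counts=np.round(small_balanced.counts * 2), weights=None)
        report = ph.evaluate_maps(pred, small_balanced, w=40)
        assert {"mse", "mae", "psnr", "ssim"} <= set(report.per_patch.columns)
        assert {"pcc", "srcc"} <= set(report.per_distance.columns)
        assert set(report.hicrep) == {"pcc", "srcc"}
        s = report.summary()
        assert -1 <= s["hicrep_pcc"] <= 1
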