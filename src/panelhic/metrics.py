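"""Evaluation battery for contact-map enhancement.

Per-patch image metrics (MSE, MAE, PSNR, SSIM), diagonal-wise correlations
(Pearson/Spearman per genomic distance), and the HiCRep-style
stratum-adjusted correlation coefficient (SCC) — a 2D-smoothed,
distance-stratified correlation weighted by stratum size and within-stratum
variability, in both its Pearson and rank (Spearman) variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.stats import rankdata
from skimage.metrics import structural_similarity

from .hic_io import ContactMap

__all__ = [
    "MetricReport",
    "patch_metrics",
    "diagonal_correlation",
    "hicrep_scc",
    "evaluate_maps",
]


def _dense(m, balanced="auto") -> tuple[np.ndarray, np.ndarray]:
    """Normalize input to (dense symmetric array, per-bin validity mask)."""
    if isinstance(m, ContactMap):
        use_bal = (m.weights is not None) if balanced == "auto" else balanced
        return m.dense(balanced=use_bal), m.bin_mask()
    m = np.asarray(m, dtype=float)
    return m, np.ones(m.shape[0], dtype=bool)


# ---------------------------------------------------------------------------
# Per-patch metrics
# ---------------------------------------------------------------------------

def patch_metrics(pred: np.ndarray, target: np.ndarray,
                  mask: np.ndarray | None = None) -> dict[str, float]:
    """MSE/MAE over unmasked pixels; PSNR and SSIM with the target's max as
    dynamic range.

    PSNR = 10 log10(R^2 / MSE); a perfect prediction reports ``inf`` as a
    sentinel (callers exclude it from averages). SSIM uses an 11x11 Gaussian
    window (sigma 1.5, K1=0.01, K2=0.03); masked pixels are zero-filled in
    both images before the SSIM pass.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    if mask is None:
        mask = np.ones_like(pred, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("patch_metrics: all pixels are masked")
    diff = pred[mask] - target[mask]
    mse = float(np.mean(diff ** 2))
    mae = float(np.mean(np.abs(diff)))
    r = float(target[mask].max())
    psnr = np.inf if mse == 0 else 10.0 * np.log10(max(r, np.finfo(float).tiny) ** 2 / mse)
    p = np.where(mask, pred, 0.0)
    t = np.where(mask, target, 0.0)
    ssim = float(structural_similarity(
        t, p, win_size=min(11, (min(pred.shape) // 2) * 2 - 1),
        gaussian_weights=True, sigma=1.5, K1=0.01, K2=0.03,
        use_sample_covariance=False, data_range=r if r > 0 else 1.0))
    return {"mse": mse, "mae": mae, "psnr": float(psnr), "ssim": ssim}


# ---------------------------------------------------------------------------
# Diagonal-wise correlation
# ---------------------------------------------------------------------------

def _corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if len(x) < 3:
        return np.nan
    if kind == "srcc":
        x, y = rankdata(x), rankdata(y)
    elif kind != "pcc":
        raise ValueError(f"unknown correlation kind {kind!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def diagonal_correlation(pred_map, target_map, max_distance_bins: int,
                         kind: str = "pcc") -> pd.DataFrame:
    """Per-distance correlation of the two maps across unmasked (i, i+k).

    Distances with fewer than 3 valid points or zero variance report NaN.
    """
    a, ma = _dense(pred_map)
    b, mb = _dense(target_map)
    if a.shape != b.shape:
        raise ValueError("maps must share binning to correlate")
    valid = ma & mb
    rows = []
    n = a.shape[0]
    for k in range(0, min(max_distance_bins, n - 1) + 1):
        ok = valid[:n - k] & valid[k:]
        x = np.diagonal(a, k)[ok]
        y = np.diagonal(b, k)[ok]
        rows.append({"distance_bins": k, kind: _corr(x, y, kind)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HiCRep-style stratum-adjusted correlation
# ---------------------------------------------------------------------------

def hicrep_scc(map_a, map_b, smooth_h: int = 1,
               max_distance_bins: int | None = None,
               kind: str = "pcc") -> float:
    """Stratum-adjusted correlation coefficient between two contact maps.

    Both maps are smoothed with a (2h+1)^2 mean filter, stratified by
    genomic distance, and each stratum's correlation rho_k (Pearson, or
    Pearson-on-ranks for the SRCC variant) is combined with weights
    w_k = N_k * sigma_{a,k} * sigma_{b,k} (rank-transformed values in the
    SRCC variant). Strata with < 3 pixels or zero variance are skipped; the
    result is clipped to [-1, 1].
    """
    a, ma = _dense(map_a)
    b, mb = _dense(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must share binning for SCC")
    if max_distance_bins is None:
        for m in (map_a, map_b):
            if isinstance(m, ContactMap):
                max_distance_bins = m.max_distance_bins
                break
        else:
            max_distance_bins = a.shape[0] - 1
    if smooth_h > 0:
        size = 2 * smooth_h + 1
        a = uniform_filter(a, size=size, mode="constant")
        b = uniform_filter(b, size=size, mode="constant")
    valid = ma & mb
    n = a.shape[0]
    num, den = 0.0, 0.0
    computable = 0
    for k in range(0, min(max_distance_bins, n - 1) + 1):
        ok = valid[:n - k] & valid[k:]
        x = np.diagonal(a, k)[ok]
        y = np.diagonal(b, k)[ok]
        if len(x) < 3:
            continue
        if kind == "srcc":
            x, y = rankdata(x), rankdata(y)
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            continue
        rho = float(np.corrcoef(x, y)[0, 1])
        wk = len(x) * sx * sy
        num += wk * rho
        den += wk
        computable += 1
    if computable == 0:
        raise ValueError("no computable stratum for SCC")
    return float(np.clip(num / den, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Whole-map report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    per_patch: pd.DataFrame      # corner_i, corner_j, mse, mae, psnr, ssim
    per_distance: pd.DataFrame   # distance_bins, pcc, srcc
    hicrep: dict[str, float]     # {"pcc": ..., "srcc": ...}

    def summary(self) -> dict[str, float]:
        finite_psnr = self.per_patch["psnr"][np.isfinite(self.per_patch["psnr"])]
        return {
            "mse": float(self.per_patch["mse"].mean()),
            "mae": float(self.per_patch["mae"].mean()),
            "psnr": float(finite_psnr.mean()) if len(finite_psnr) else np.nan,
            "ssim": float(self.per_patch["ssim"].mean()),
            "pcc": float(self.per_distance["pcc"].mean(skipna=True)),
            "srcc": float(self.per_distance["srcc"].mean(skipna=True)),
            "hicrep_pcc": self.hicrep["pcc"],
            "hicrep_srcc": self.hicrep["srcc"],
        }


def evaluate_maps(pred_map: ContactMap, target_map: ContactMap,
                  tiles: list[tuple[int, int]] | None = None,
                  w: int = 200, smooth_h: int = 1) -> MetricReport:
    """The seven-metric battery on a predicted/target chromosome pair."""
    from .preprocess import extract_patch, make_tile_plan

    if pred_map.n_bins != target_map.n_bins:
        raise ValueError("prediction and target chromosomes differ in size")
    if tiles is None:
        plan = make_tile_plan(pred_map.n_bins, w, max(1, w // 20),
                              pred_map.max_distance_bins)
        tiles = plan.tiles
    rows = []
    for corner in tiles:
        pv, pm = extract_patch(pred_map, corner, w,
                               balanced=pred_map.weights is not None)
        tv, tm = extract_patch(target_map, corner, w,
                               balanced=target_map.weights is not None)
        mask = pm & tm
        if not mask.any():
            continue
        m = patch_metrics(pv, tv, mask)
        rows.append({"corner_i": corner[0], "corner_j": corner[1], **m})
    per_patch = pd.DataFrame(rows)
    band = min(pred_map.max_distance_bins, target_map.max_distance_bins)
    pcc = diagonal_correlation(pred_map, target_map, band, "pcc")
    srcc = diagonal_correlation(pred_map, target_map, band, "srcc")
    per_distance = pcc.merge(srcc, on="distance_bins")
    hicrep = {kind: hicrep_scc(pred_map, target_map, smooth_h=smooth_h,
                               max_distance_bins=band, kind=kind)
              for kind in ("pcc", "srcc")}
    return MetricReport(per_patch=per_patch, per_distance=per_distance,
                        hicrep=hicrep)
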