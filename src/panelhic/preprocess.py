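"""ICE balancing, coverage downsampling, patch scaling, and tiling geometry.

Shared by training and inference. The tiling convention: a chromosome's
band is split into partially overlapping ``w x w`` squares whose top-left
corners (i, j), j >= i, lie on a grid of step ``w - 2*trim``; after
prediction each square is trimmed by ``trim`` bins per interior side so the
retained cores partition the band exactly (trim is suppressed on sides
flush with the chromosome start/end, and the terminal grid position is
re-anchored at ``n_bins - w`` with its core clipped to start where the
previous core ends, so no pixel is lost and none is fabricated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMap

__all__ = [
    "PipelineConfig",
    "Patch",
    "TilePlan",
    "ice_balance",
    "downsample",
    "map_scale",
    "scale_patch",
    "unscale_values",
    "make_tile_plan",
    "extract_patch",
]

SCALE_EPS = 1e-6


@dataclass
class PipelineConfig:
    """Knobs shared across preprocessing and inference."""

    window: int = 200            # w, bins
    trim: int = 10               # bins trimmed per interior side
    max_distance: int = 3_000_000  # bp band half-width
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    ice_mask_quantile: float = 0.02


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_balance(cm: ContactMap, tol: float = 1e-5, max_iter: int = 200,
                mask_quantile: float = 0.02) -> ContactMap:
    """Iterative-correction balancing of a banded contact map.

    Repeats ``b_i <- b_i / s_i`` where ``s`` is the row sum of the current
    balanced (symmetric, band-restricted) matrix normalized to unit mean over
    unmasked bins, until the maximum relative row-sum deviation drops below
    ``tol``. Bins with zero coverage, and bins whose raw coverage falls in
    the bottom ``mask_quantile`` of nonzero-coverage bins, are masked (NaN
    weight) before iterating. Returned weights are scaled so balanced row
    sums have unit mean.
    """
    full = cm.dense(balanced=False)
    coverage = full.sum(axis=1)
    mask = coverage > 0
    if mask.any() and mask_quantile > 0:
        cutoff = np.quantile(coverage[mask], mask_quantile)
        mask &= coverage >= cutoff
    if not mask.any():
        raise ValueError("no unmasked bins; cannot balance an empty matrix")

    s_mat = full.copy()
    s_mat[~mask, :] = 0.0
    s_mat[:, ~mask] = 0.0
    b = np.ones(cm.n_bins)
    for _ in range(max_iter):
        s = (s_mat * b[:, None] * b[None, :]).sum(axis=1)
        sm = s[mask].mean()
        if sm <= 0:
            raise ValueError("balancing degenerated: zero total coverage")
        s = s / sm
        dev = np.abs(s[mask] - 1.0).max()
        b[mask] /= s[mask]
        if dev < tol:
            break
    # scale so balanced row sums have unit mean
    s = (s_mat * b[:, None] * b[None, :]).sum(axis=1)
    b /= np.sqrt(s[mask].mean())
    weights = np.where(mask, b, np.nan)
    return cm.copy_with(weights=weights)


# ---------------------------------------------------------------------------
# Coverage downsampling (binomial thinning)
# ---------------------------------------------------------------------------

def downsample(cm: ContactMap, ratio: float, seed: int) -> ContactMap:
    """Binomially thin raw counts: each count c becomes Binomial(c, ratio).

    Acts on raw integer counts (downsampling precedes balancing); ratio 1 is
    the identity.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"downsampling ratio must be in (0, 1], got {ratio}")
    if not np.allclose(cm.counts, np.round(cm.counts)):
        raise ValueError("downsample requires integer raw counts")
    if ratio == 1.0:
        return cm.copy_with(counts=cm.counts.copy(), weights=None)
    rng = np.random.default_rng(seed)
    i, j = np.nonzero(cm.counts)
    thinned = rng.binomial(cm.counts[i, j].astype(np.int64), ratio)
    counts = np.zeros_like(cm.counts)
    counts[i, j] = thinned
    return cm.copy_with(counts=counts, weights=None)


# ---------------------------------------------------------------------------
# Patch scaling
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """A scaled w x w submatrix anchored at bin corner (i, j)."""

    corner: tuple[int, int]
    values: np.ndarray        # scaled to [0, 1] on the mask
    mask: np.ndarray          # True where the pixel is usable
    scale: float              # log1p(pair max), recorded for inversion

    @property
    def w(self) -> int:
        return self.values.shape[0]


def map_scale(cm: ContactMap) -> float:
    """Per-map value scale: log1p of the largest balanced band value.

    One scale per contact map (rather than per patch) keeps all tiles of a
    chromosome in a common unit system: at low coverage a per-patch maximum
    is a shot-noise statistic, and inverting with it modulates stitched
    values tile-by-tile.
    """
    vals = cm.balanced() if cm.weights is not None else cm.counts
    top = float(np.nanmax(vals)) if vals.size else 0.0
    return max(float(np.log1p(max(top, 0.0))), SCALE_EPS)


def scale_patch(values: np.ndarray, mask: np.ndarray,
                corner: tuple[int, int] = (0, 0),
                scale: float | None = None) -> Patch:
    """Map balanced values into [0, 1] via v -> log1p(v) / scale.

    ``scale`` is normally the map-level scale of the source map (or the
    shared study/target pair scale during training; see :func:`map_scale`);
    it defaults to log1p of the patch maximum, clamped to at least
    ``SCALE_EPS`` so all-zero patches stay well defined.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot scale a fully masked patch")
    if scale is None:
        scale = float(np.log1p(values[mask].max()))
    scale = max(scale, SCALE_EPS)
    scaled = np.where(mask, np.log1p(np.maximum(values, 0.0)) / scale, 0.0)
    return Patch(corner=tuple(corner), values=scaled, mask=mask, scale=scale)


def unscale_values(scaled: np.ndarray, scale: float) -> np.ndarray:
    """Invert :func:`scale_patch`: v -> expm1(v * scale)."""
    return np.expm1(np.asarray(scaled, dtype=float) * scale)


# ---------------------------------------------------------------------------
# Tiling geometry
# ---------------------------------------------------------------------------

@dataclass
class TilePlan:
    """Tile corners plus the per-axis retained-core partition."""

    w: int
    trim: int
    step: int
    n_bins: int
    max_distance_bins: int
    positions: list[int]              # per-axis corner positions
    cores: list[tuple[int, int]]      # per-axis retained half-open intervals
    tiles: list[tuple[int, int]]      # (i, j) corners, j >= i

    def core_bounds(self, corner: tuple[int, int]) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) retained half-open core of the tile at ``corner``."""
        a = self.positions.index(corner[0])
        b = self.positions.index(corner[1])
        r0, r1 = self.cores[a]
        c0, c1 = self.cores[b]
        return r0, r1, c0, c1


def make_tile_plan(n_bins: int, w: int, trim: int,
                   max_distance_bins: int) -> TilePlan:
    """Plan the tile corners and retained cores covering a chromosome's band.

    Corners lie on the grid {0, step, 2*step, ...} with ``step = w - 2*trim``;
    if the final grid position does not reach ``n_bins - w`` a terminal tile
    re-anchored there is appended. A tile (i, j) is included iff j >= i and
    its retained core contains at least one band pixel. Cores partition
    [0, n_bins) along each axis.
    """
    if w % 8 != 0:
        raise ValueError(f"window w={w} must be divisible by 8 (encoder downsamples 3x)")
    if n_bins < w:
        raise ValueError(
            f"chromosome has {n_bins} bins but the window is {w}; pad the "
            f"matrix or reduce the window size")
    step = w - 2 * trim
    if step <= 0:
        raise ValueError("trim too large: step = w - 2*trim must be positive")
    positions = list(range(0, n_bins - w + 1, step))
    if positions[-1] != n_bins - w:
        positions.append(n_bins - w)

    cores: list[tuple[int, int]] = []
    prev_end = 0
    for k, p in enumerate(positions):
        start = 0 if k == 0 else max(p + trim, prev_end)
        end = n_bins if p + w == n_bins else p + w - trim
        cores.append((start, end))
        prev_end = end

    tiles = []
    for a, (r0, r1) in enumerate(cores):
        for b in range(a, len(positions)):
            c0, c1 = cores[b]
            # smallest j - i over the core is c0 - (r1 - 1)
            if c0 - (r1 - 1) <= max_distance_bins:
                tiles.append((positions[a], positions[b]))
    return TilePlan(w=w, trim=trim, step=step, n_bins=n_bins,
                    max_distance_bins=max_distance_bins,
                    positions=positions, cores=cores, tiles=tiles)


def extract_patch(cm: ContactMap, corner: tuple[int, int], w: int,
                  balanced: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Dense w x w block of (balanced) values at ``corner``, with usability mask.

    The block is read from the symmetrized matrix (diagonal tiles are
    symmetric); pixels outside the distance band or touching masked bins are
    False in the mask and zero-filled in the values.
    """
    i0, j0 = corner
    n = cm.n_bins
    if not (0 <= i0 <= n - w and 0 <= j0 <= n - w):
        raise ValueError(f"corner {corner} out of range for {n} bins, w={w}")
    full = cm.dense(balanced=balanced)
    block = full[i0:i0 + w, j0:j0 + w].copy()
    rows = np.arange(i0, i0 + w)
    cols = np.arange(j0, j0 + w)
    dist = np.abs(cols[None, :] - rows[:, None])
    mask = dist <= cm.max_distance_bins
    bin_ok = cm.bin_mask()
    mask &= bin_ok[rows][:, None] & bin_ok[cols][None, :]
    block[~mask] = 0.0
    return block, mask
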