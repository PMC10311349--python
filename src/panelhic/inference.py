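"""Whole-chromosome enhancement: tile, predict, trim, stitch, symmetrize, write.

Each tile's study patch and the panel's patches at the same coordinates are
scaled, passed through the model, inverse-scaled, trimmed to the tile's
retained core, and written into the output band; where terminal-tile
re-anchoring makes cores overlap, overlapping predictions are averaged.
The stitched result is symmetric by construction (only the upper band is
stored; consumers mirror it) and exact for an identity model — the
geometry loses nothing.
"""

from __future__ import annotations

import logging
import time
from typing import Callable, Sequence

import numpy as np

from .hic_io import ContactMap, ReferencePanel, read_cooler, write_cooler
from .model import RefPanelUNet
from .preprocess import (PipelineConfig, TilePlan, extract_patch, ice_balance,
                         make_tile_plan, map_scale, scale_patch, unscale_values)

__all__ = ["enhance_chromosome", "enhance_genome"]

logger = logging.getLogger(__name__)

EnhanceFn = Callable[[np.ndarray, np.ndarray | None], np.ndarray]


def _as_enhance_fn(model) -> EnhanceFn:
    """Normalize a RefPanelUNet or a plain callable to (study, refs) -> (w, w)."""
    if isinstance(model, RefPanelUNet):
        model.eval()

        def fn(study, refs):
            return model.forward(study, refs).data[0, 0]

        return fn
    return model


def enhance_chromosome(study_map: ContactMap,
                       panel_maps: Sequence[ContactMap],
                       model,
                       plan: TilePlan) -> ContactMap:
    """Enhance one chromosome's banded contact map.

    ``study_map`` and the panel maps must carry balancing weights (the model
    consumes balanced values). ``model`` is a trained :class:`RefPanelUNet`,
    or any callable ``(study_scaled, ref_stack_or_None) -> (w, w) array``
    operating in scaled space. Returns a float-valued ContactMap in balanced
    space (no weights), band mask preserved.
    """
    if study_map.n_bins != plan.n_bins:
        raise ValueError("tile plan does not match the study chromosome size")
    fn = _as_enhance_fn(model)
    use_panel = not (isinstance(model, RefPanelUNet) and not model.use_panel)
    if use_panel and isinstance(model, RefPanelUNet) and len(panel_maps) == 0:
        raise ValueError("reference panel is empty")
    w = plan.w
    n = plan.n_bins
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=np.int32)

    study_scale = map_scale(study_map)
    ref_scales = [map_scale(cm) for cm in panel_maps]
    ref_scaled: dict[tuple, np.ndarray] = {}
    for corner in plan.tiles:
        sv, sm = extract_patch(study_map, corner, w)
        if not sm.any():
            continue  # fully masked region contributes nothing
        study = scale_patch(sv, sm, corner, scale=study_scale)
        refs = None
        if use_panel and panel_maps:
            stack = []
            for r, cm in enumerate(panel_maps):
                key = (r, corner)
                if key not in ref_scaled:
                    rv, rm = extract_patch(cm, corner, w)
                    ref_scaled[key] = (scale_patch(rv, rm, corner,
                                                   scale=ref_scales[r]).values
                                       if rm.any() else np.zeros((w, w)))
                stack.append(ref_scaled[key])
            refs = np.asarray(stack)
        pred = unscale_values(np.asarray(fn(study.values, refs)), study.scale)
        if corner[0] == corner[1]:
            # a diagonal tile predicts each pair twice; average the mirror
            pred = 0.5 * (pred + pred.T)
        pred[~sm] = 0.0

        r0, r1, c0, c1 = plan.core_bounds(corner)
        i0, j0 = corner
        core = pred[r0 - i0:r1 - i0, c0 - j0:c1 - j0]
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        dist = cols[None, :] - rows[:, None]
        keep = (dist >= 0) & (dist <= plan.max_distance_bins)
        sub_acc = acc[r0:r1, c0:c1]
        sub_cnt = cnt[r0:r1, c0:c1]
        sub_acc[keep] += core[keep]
        sub_cnt[keep] += 1

    out = np.zeros((n, n))
    np.divide(acc, cnt, out=out, where=cnt > 0)
    out = np.maximum(out, 0.0)
    return ContactMap(chrom=study_map.chrom, bin_size=study_map.bin_size,
                      counts=out, max_distance_bins=study_map.max_distance_bins)


def enhance_genome(cooler_in, panel: ReferencePanel, model, chroms: list[str],
                   out_cooler, cfg: PipelineConfig | None = None,
                   bin_size: int | None = None) -> ContactMap | None:
    """Enhance several chromosomes of a cooler file and write one output cooler.

    Maps lacking balancing weights are ICE-balanced on the fly. A failure on
    any chromosome aborts with that chromosome's name.
    """
    cfg = cfg or PipelineConfig()
    if bin_size is None:
        bin_size = 5000
    band = cfg.max_distance // bin_size
    enhanced = []
    for chrom in chroms:
        t0 = time.time()
        try:
            study = read_cooler(cooler_in, chrom, bin_size, band)
            if study.weights is None:
                study = ice_balance(study, tol=cfg.ice_tol,
                                    max_iter=cfg.ice_max_iter,
                                    mask_quantile=cfg.ice_mask_quantile)
            panel_maps = []
            for entry in panel:
                cm = read_cooler(entry.source, chrom, bin_size, band)
                if cm.weights is None:
                    cm = ice_balance(cm, tol=cfg.ice_tol,
                                     max_iter=cfg.ice_max_iter,
                                     mask_quantile=cfg.ice_mask_quantile)
                panel_maps.append(cm)
            plan = make_tile_plan(study.n_bins, cfg.window, cfg.trim, band)
            out = enhance_chromosome(study, panel_maps, model, plan)
        except Exception as e:
            raise RuntimeError(f"enhancement failed on chromosome {chrom}: {e}") from e
        enhanced.append(out)
        logger.info("enhanced %s: %d tiles in %.1f s", chrom, len(plan.tiles),
                    time.time() - t0)
    write_cooler(enhanced, out_cooler)
    return enhanced[0] if len(enhanced) == 1 else None
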