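"""Synthetic multi-cell-type Hi-C generator.

Emulates the features of real cis contact maps that the enhancement model
exploits: a power-law distance decay, TAD blocks of enriched contact
frequency along the diagonal, focal loop "dots", and — across cell types —
a conserved structural backbone with per-type variation (dropped/added
loops, jittered TAD boundaries). Counts are drawn multinomially so that a
map with "N valid read pairs" has exactly N counts in its band.

The generator is first-class, deterministic under seeds, and is what every
downstream stage (preprocessing, training, inference, metrics) is exercised
on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hic_io import ContactMap, PanelEntry, write_cooler, write_manifest

__all__ = [
    "Loop",
    "GenomeSpec",
    "CellTypeSpec",
    "base_tads",
    "cell_type_structures",
    "expected_map",
    "sample_counts",
    "make_panel",
]


@dataclass(frozen=True)
class Loop:
    """A focal contact enrichment at anchors (i, j), i < j."""
    i: int
    j: int
    strength: float = 3.0
    radius: int = 1


@dataclass
class GenomeSpec:
    """Backbone structure of a synthetic chromosome shared by all cell types."""

    n_bins: int
    bin_size: int = 5000
    decay_exponent: float = 1.0          # gamma: decay(s) ~ (1+s)^-gamma
    tad_length_range: tuple[int, int] = (30, 80)   # bins
    tad_enrichment: float = 1.8          # fold over decay inside a TAD
    loop_set: list[Loop] = field(default_factory=list)
    noise_dispersion: float = 0.1        # sd of multiplicative log-normal jitter
    max_distance_bins: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.max_distance_bins is None:
            self.max_distance_bins = min(self.n_bins - 1, 3_000_000 // self.bin_size)
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        for lp in self.loop_set:
            if not (0 <= lp.i < self.n_bins and 0 <= lp.j < self.n_bins):
                raise ValueError(f"loop anchor out of range: {lp}")
            if abs(lp.j - lp.i) > self.max_distance_bins:
                raise ValueError(f"loop outside band: {lp}")

    @classmethod
    def random(cls, n_bins: int, n_loops: int = 40, seed: int = 0, **kw) -> "GenomeSpec":
        """Backbone with randomly placed loops (anchors >= 5 bins apart in distance)."""
        spec = cls(n_bins=n_bins, seed=seed, **kw)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
        loops = []
        for _ in range(n_loops):
            i = int(rng.integers(0, n_bins - 6))
            span = int(rng.integers(5, min(spec.max_distance_bins, n_bins - 1 - i) + 1))
            loops.append(Loop(i, i + span))
        spec.loop_set = loops
        return spec


@dataclass
class CellTypeSpec:
    """Per-cell-type variation around a shared backbone."""

    base: GenomeSpec
    dropped_loop_fraction: float = 0.0
    added_loops: list[Loop] = field(default_factory=list)
    boundary_shift_sd: float = 0.0       # bins
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropped_loop_fraction <= 1.0:
            raise ValueError("dropped_loop_fraction must be in [0, 1]")
        for lp in self.added_loops:
            if abs(lp.j - lp.i) > self.base.max_distance_bins:
                raise ValueError(f"added loop outside band: {lp}")


# ---------------------------------------------------------------------------
# Structure realization
# ---------------------------------------------------------------------------

def base_tads(spec: GenomeSpec) -> list[tuple[int, int]]:
    """Deterministic half-open TAD intervals tiling [0, n_bins)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7AD]))
    lo, hi = spec.tad_length_range
    bounds = [0]
    while bounds[-1] < spec.n_bins:
        bounds.append(bounds[-1] + int(rng.integers(lo, hi + 1)))
    bounds[-1] = spec.n_bins
    return list(zip(bounds[:-1], bounds[1:]))


def cell_type_structures(ct: CellTypeSpec) -> tuple[list[tuple[int, int]], list[Loop]]:
    """Realize one cell type's TADs and loops from the shared backbone.

    Internal TAD boundaries are shifted by rounded Gaussian jitter; an exact
    ``round(f * n)`` subset of backbone loops is dropped, then the type's own
    added loops appended. Deterministic given ``ct.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([ct.seed, 0xCE11]))
    tads = base_tads(ct.base)
    bounds = [a for a, _ in tads] + [ct.base.n_bins]
    if ct.boundary_shift_sd > 0:
        shifted = [0]
        for b in bounds[1:-1]:
            nb = b + int(round(rng.normal(0, ct.boundary_shift_sd)))
            shifted.append(int(np.clip(nb, shifted[-1] + 2, ct.base.n_bins - 1)))
        shifted.append(ct.base.n_bins)
        bounds = shifted
    tads = list(zip(bounds[:-1], bounds[1:]))

    loops = list(ct.base.loop_set)
    n_drop = int(round(ct.dropped_loop_fraction * len(loops)))
    if n_drop:
        drop_idx = set(rng.choice(len(loops), size=n_drop, replace=False).tolist())
        loops = [lp for k, lp in enumerate(loops) if k not in drop_idx]
    loops = loops + list(ct.added_loops)
    return tads, loops


# ---------------------------------------------------------------------------
# Expected contact intensity
# ---------------------------------------------------------------------------

def expected_map(ct: CellTypeSpec, tads=None, loops=None) -> ContactMap:
    """Expected (noise-jittered Poisson intensity) contact map for one cell type.

    lambda(i, j) = decay(|i-j|) * tad_factor(i, j) * loop_factor(i, j) with
    decay(s) = (1+s)^-gamma; TADs multiply the decay by a constant fold inside
    each block; each loop adds a Gaussian-shaped dot of the given fold and
    radius. Multiplicative log-normal jitter with sd ``noise_dispersion``
    models bin-level visibility variation; it is seeded by the cell-type seed
    and therefore deterministic.

    ``tads``/``loops`` override the realized structures (mainly for tests
    that need a single known TAD or loop).
    """
    spec = ct.base
    n, band = spec.n_bins, spec.max_distance_bins
    i, j = np.indices((n, n), sparse=True)
    d = j - i
    in_band = (d >= 0) & (d <= band)
    lam = np.where(in_band, (1.0 + np.abs(d)) ** (-spec.decay_exponent), 0.0)

    auto_tads, auto_loops = cell_type_structures(ct)
    tads = auto_tads if tads is None else tads
    loops = auto_loops if loops is None else loops
    tad_factor = np.ones((n, n))
    for a, b in tads:
        tad_factor[a:b, a:b] = spec.tad_enrichment
    lam = lam * tad_factor

    loop_factor = np.ones((n, n))
    for lp in loops:
        r = max(lp.radius, 1)
        half = 3 * r
        ii = np.arange(max(lp.i - half, 0), min(lp.i + half + 1, n))
        jj = np.arange(max(lp.j - half, 0), min(lp.j + half + 1, n))
        di = (ii - lp.i)[:, None]
        dj = (jj - lp.j)[None, :]
        bump = (lp.strength - 1.0) * np.exp(-(di ** 2 + dj ** 2) / (2.0 * r ** 2))
        loop_factor[np.ix_(ii, jj)] += bump
    # loops are specified in the upper triangle; mirror so factor is symmetric
    loop_factor = np.maximum(loop_factor, loop_factor.T)
    lam = lam * loop_factor

    if spec.noise_dispersion > 0:
        rng = np.random.default_rng(np.random.SeedSequence([ct.seed, 0x015E]))
        jitter = np.exp(rng.normal(0.0, spec.noise_dispersion, size=n))
        lam = lam * jitter[:, None] * jitter[None, :]

    lam = np.where(in_band, lam, 0.0)
    return ContactMap(chrom="chrS", bin_size=spec.bin_size, counts=lam,
                      max_distance_bins=band)


def sample_counts(expected: ContactMap, total_pairs: int, seed: int,
                  method: str = "multinomial") -> ContactMap:
    """Draw integer counts from an expected map.

    ``multinomial`` (default) distributes exactly ``total_pairs`` read pairs
    over band pixels with probability lambda / sum(lambda); ``poisson`` draws
    each pixel independently with mean lambda * total / sum(lambda).
    """
    lam = expected.counts
    total = float(lam.sum())
    if total <= 0:
        raise ValueError("expected map is identically zero; cannot sample counts")
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(lam)
    p = lam[iu, ju] / total
    counts = np.zeros_like(lam)
    if method == "multinomial":
        if total_pairs <= 0:
            raise ValueError("total_pairs must be positive for multinomial sampling")
        draw = rng.multinomial(int(total_pairs), p)
    elif method == "poisson":
        draw = rng.poisson(p * total_pairs)
    else:
        raise ValueError(f"unknown sampling method: {method!r}")
    counts[iu, ju] = draw
    return ContactMap(chrom=expected.chrom, bin_size=expected.bin_size,
                      counts=counts, max_distance_bins=expected.max_distance_bins)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def make_panel(base: GenomeSpec, n_types: int, samples_per_type: int,
               coverage: int, seed: int, out_dir,
               dropped_loop_fraction: float = 0.1,
               added_loops_per_type: int = 3,
               boundary_shift_sd: float = 0.5,
               chrom: str = "chrS") -> Path:
    """Write a multi-cell-type synthetic panel: coolers, manifest, truth record.

    Each cell type perturbs the shared backbone (dropping an exact fraction
    of backbone loops, adding its own, jittering TAD boundaries); each sample
    of a type redraws multinomial counts at the given coverage. Returns the
    manifest path; ``truth.json`` alongside it records the realized
    structures for assertions.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    type_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_types)]
    entries: list[PanelEntry] = []
    truth: dict = {"base": {"n_bins": base.n_bins, "seed": base.seed,
                            "loops": [dataclasses.astuple(lp) for lp in base.loop_set]},
                   "cell_types": []}
    count_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    for t, ts in enumerate(type_seeds):
        add_rng = np.random.default_rng(np.random.SeedSequence([ts, 0xADD]))
        added = []
        for _ in range(added_loops_per_type):
            i = int(add_rng.integers(0, base.n_bins - 6))
            span = int(add_rng.integers(5, min(base.max_distance_bins,
                                               base.n_bins - 1 - i) + 1))
            added.append(Loop(i, i + span))
        ct = CellTypeSpec(base=base, dropped_loop_fraction=dropped_loop_fraction,
                          added_loops=added, boundary_shift_sd=boundary_shift_sd,
                          seed=ts)
        exp = expected_map(ct)
        exp.chrom = chrom
        tads, loops = cell_type_structures(ct)
        truth["cell_types"].append({
            "name": f"celltype{t:02d}", "seed": ts,
            "tads": [list(x) for x in tads],
            "loops": [dataclasses.astuple(lp) for lp in loops],
        })
        for k in range(samples_per_type):
            cseed = int(count_rng.integers(0, 2 ** 31))
            cm = sample_counts(exp, coverage, seed=cseed)
            fname = f"celltype{t:02d}_s{k}.cool"
            write_cooler(cm, out_dir / fname)
            entries.append(PanelEntry(f"celltype{t:02d}_s{k}", f"celltype{t:02d}", Path(fname)))
    manifest = write_manifest(entries, out_dir / "manifest.tsv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
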