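"""Contact-map containers and file I/O (cooler HDF5 schema, panel manifests).

All file-format knowledge lives here. Contact maps are stored
upper-triangle-only within a diagonal band (``0 <= j - i <= max_distance_bins``),
matching the symmetric-upper convention of the cooler format; consumers that
need the full square mirror on the fly. Bins are 0-based, genomic intervals
0-based half-open.

The cooler reader/writer speaks the standard single-resolution cooler HDF5
layout (format-version 3: ``chroms``, ``bins``, ``pixels``, ``indexes``
tables plus root attributes) via h5py, so files written here are readable by
ordinary cooler tooling, and `.cool`/`.mcool` files produced elsewhere are
readable here.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "PanelEntry",
    "ReferencePanel",
    "read_cooler",
    "write_cooler",
    "load_panel",
    "write_manifest",
    "read_dense_text",
]

_FORMAT = "HDF5::Cooler"
_FORMAT_VERSION = 3


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    """Banded upper-triangular contact matrix for one chromosome.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    bin_size : int
        Bin width in bp.
    counts : ndarray, shape (n_bins, n_bins)
        Contact values; nonzero only for ``0 <= j - i <= max_distance_bins``.
        Integer-valued for raw maps, float for balanced/enhanced maps.
    weights : ndarray or None
        Per-bin balancing weights (cooler convention: balanced value =
        ``w[i] * w[j] * counts[i, j]``); NaN marks masked bins.
    max_distance_bins : int
        Band half-width in bins (3 Mb / bin_size = 600 at 5 kb).
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    max_distance_bins: int
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be nonnegative")
        n = self.n_bins
        i, j = np.nonzero(self.counts)
        if np.any(j < i) or np.any(j - i > self.max_distance_bins):
            raise ValueError("counts must be upper-triangular within the band")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights must have one entry per bin")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def band_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of the stored upper band."""
        i, j = np.indices(self.counts.shape, sparse=True)
        d = j - i
        return (d >= 0) & (d <= self.max_distance_bins)

    def bin_mask(self) -> np.ndarray:
        """True for usable bins (finite balancing weight, or all if unbalanced)."""
        if self.weights is None:
            return np.ones(self.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def balanced(self) -> np.ndarray:
        """Balanced upper-band matrix; masked bins yield NaN rows/cols."""
        if self.weights is None:
            raise ValueError("contact map has no balancing weights")
        b = self.counts * self.weights[:, None] * self.weights[None, :]
        return np.where(self.band_mask(), b, 0.0)

    def dense(self, balanced: bool = False) -> np.ndarray:
        """Full symmetric matrix (band mirrored; outside-band pixels zero).

        Masked bins are zero-filled in the balanced view.
        """
        m = self.balanced() if balanced else self.counts.astype(float)
        if balanced:
            m = np.nan_to_num(m)
        full = m + np.triu(m, 1).T
        return full

    def copy_with(self, counts=None, weights="keep") -> "ContactMap":
        keep = isinstance(weights, str) and weights == "keep"
        return ContactMap(
            chrom=self.chrom,
            bin_size=self.bin_size,
            counts=self.counts.copy() if counts is None else counts,
            max_distance_bins=self.max_distance_bins,
            weights=self.weights if keep else weights,
        )


@dataclass(frozen=True)
class PanelEntry:
    sample_id: str
    cell_type: str
    source: Path


@dataclass
class ReferencePanel:
    """Ordered collection of reference contact-map sources with cell-type labels."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def load_maps(self, chrom: str, bin_size: int, max_distance_bins: int) -> list[ContactMap]:
        return [read_cooler(e.source, chrom, bin_size, max_distance_bins) for e in self.entries]


# ---------------------------------------------------------------------------
# Cooler I/O
# ---------------------------------------------------------------------------

def _open_data_group(f: h5py.File, bin_size: int, path: Path) -> h5py.Group:
    if "resolutions" in f:  # multi-resolution (.mcool) layout
        key = str(bin_size)
        if key not in f["resolutions"]:
            avail = ", ".join(sorted(f["resolutions"].keys()))
            raise KeyError(f"{path}: resolution {bin_size} not present (available: {avail})")
        return f["resolutions"][key]
    grp = f["/"]
    stored = int(grp.attrs.get("bin-size", bin_size))
    if stored != bin_size:
        raise KeyError(f"{path}: file bin size is {stored}, requested {bin_size}")
    return grp


def read_cooler(path, chrom: str, bin_size: int, max_distance_bins: int) -> ContactMap:
    """Read one chromosome's banded contact map from a .cool/.mcool file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cooler file not found: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"cannot open cooler container {path}: {e}") from e
    with f:
        grp = _open_data_group(f, bin_size, path)
        for key in ("chroms", "bins", "pixels", "indexes"):
            if key not in grp:
                raise OSError(f"corrupted cooler container {path}: missing '{key}' table")
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        if chrom not in names:
            raise KeyError(f"{path}: chromosome {chrom!r} not in file (has: {', '.join(names)})")
        cid = names.index(chrom)
        chrom_offset = grp["indexes/chrom_offset"][:]
        lo, hi = int(chrom_offset[cid]), int(chrom_offset[cid + 1])
        n = hi - lo
        bin1_offset = grp["indexes/bin1_offset"][:]
        plo, phi = int(bin1_offset[lo]), int(bin1_offset[hi])
        b1 = grp["pixels/bin1_id"][plo:phi] - lo
        b2 = grp["pixels/bin2_id"][plo:phi] - lo
        val = grp["pixels/count"][plo:phi]
        keep = (b2 >= lo - lo) & (b2 < n) & (b2 - b1 <= max_distance_bins)
        counts = np.zeros((n, n), dtype=val.dtype if np.issubdtype(val.dtype, np.floating) else np.float64)
        counts[b1[keep], b2[keep]] = val[keep]
        weights = None
        if "weight" in grp["bins"]:
            weights = grp["bins/weight"][lo:hi].astype(float)
    return ContactMap(chrom=chrom, bin_size=bin_size, counts=counts,
                      max_distance_bins=max_distance_bins, weights=weights)


def write_cooler(cms, path) -> Path:
    """Write one or more ContactMaps as a standard single-resolution .cool file.

    Multiple maps (one per chromosome) must share bin size; integer-valued
    counts are stored as int32, otherwise as float64.
    """
    if isinstance(cms, ContactMap):
        cms = [cms]
    if not cms:
        raise ValueError("no contact maps to write")
    bin_size = cms[0].bin_size
    if any(cm.bin_size != bin_size for cm in cms):
        raise ValueError("all contact maps in one cooler must share a bin size")
    path = Path(path)

    b1_all, b2_all, v_all = [], [], []
    offset = 0
    chrom_offsets = [0]
    have_weights = any(cm.weights is not None for cm in cms)
    weights_all = []
    for cm in cms:
        i, j = np.nonzero(cm.counts)
        order = np.lexsort((j, i))
        b1_all.append(i[order] + offset)
        b2_all.append(j[order] + offset)
        v_all.append(cm.counts[i[order], j[order]])
        if have_weights:
            w = cm.weights if cm.weights is not None else np.full(cm.n_bins, np.nan)
            weights_all.append(np.asarray(w, dtype=float))
        offset += cm.n_bins
        chrom_offsets.append(offset)
    n_bins = offset
    b1 = np.concatenate(b1_all).astype(np.int64)
    b2 = np.concatenate(b2_all).astype(np.int64)
    vals = np.concatenate(v_all)
    integral = vals.size == 0 or (np.issubdtype(vals.dtype, np.integer)
                                  or np.allclose(vals, np.round(vals)))
    vals = vals.astype(np.int32) if integral else vals.astype(np.float64)

    try:
        f = h5py.File(path, "w")
    except OSError as e:
        raise OSError(f"cannot write cooler file {path}: {e}") from e
    with f:
        f.attrs["format"] = _FORMAT
        f.attrs["format-version"] = _FORMAT_VERSION
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = bin_size
        f.attrs["storage-mode"] = "symmetric-upper"
        f.attrs["nbins"] = n_bins
        f.attrs["nchroms"] = len(cms)
        f.attrs["nnz"] = int(b1.size)
        f.attrs["sum"] = float(vals.sum())
        f.attrs["generated-by"] = "panelhic-0.1.0"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()

        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([cm.chrom for cm in cms], dtype="S32"))
        g.create_dataset("length", data=np.array([cm.n_bins * bin_size for cm in cms],
                                                 dtype=np.int32))

        chrom_ids = np.repeat(np.arange(len(cms), dtype=np.int32),
                              [cm.n_bins for cm in cms])
        starts = np.concatenate([np.arange(cm.n_bins, dtype=np.int64) * bin_size
                                 for cm in cms])
        g = f.create_group("bins")
        g.create_dataset("chrom", data=chrom_ids)
        g.create_dataset("start", data=starts.astype(np.int32))
        g.create_dataset("end", data=(starts + bin_size).astype(np.int32))
        if have_weights:
            g.create_dataset("weight", data=np.concatenate(weights_all))

        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=b1)
        g.create_dataset("bin2_id", data=b2)
        g.create_dataset("count", data=vals)

        g = f.create_group("indexes")
        g.create_dataset("chrom_offset", data=np.array(chrom_offsets, dtype=np.int64))
        bin1_offset = np.zeros(n_bins + 1, dtype=np.int64)
        np.add.at(bin1_offset, b1 + 1, 1)
        g.create_dataset("bin1_offset", data=np.cumsum(bin1_offset))
    return path


# ---------------------------------------------------------------------------
# Panel manifest
# ---------------------------------------------------------------------------

def load_panel(manifest_path, exclude_cell_type: str | None = None) -> ReferencePanel:
    """Load a reference panel from a 3-column TSV (sample_id, cell_type, path).

    Samples of ``exclude_cell_type`` are dropped (cell-type holdout guards
    against leakage between the study sample and the panel); original order
    is preserved. Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", header=None,
                     names=["sample_id", "cell_type", "path"], comment="#",
                     dtype=str)
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate sample_id in panel manifest: "
                         f"{sorted(df.loc[dup, 'sample_id'])}")
    if exclude_cell_type is not None:
        df = df[df["cell_type"] != exclude_cell_type]
    if df.empty:
        raise ValueError(
            "reference panel is empty after cell-type exclusion; provide a "
            "manifest containing samples from at least one other cell type")
    entries = [
        PanelEntry(r.sample_id, r.cell_type,
                   (manifest_path.parent / r.path) if not Path(r.path).is_absolute()
                   else Path(r.path))
        for r in df.itertuples()
    ]
    return ReferencePanel(entries)


def write_manifest(entries: list[PanelEntry], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.sample_id}\t{e.cell_type}\t{e.source}\n")
    return path


# ---------------------------------------------------------------------------
# Plain-text fixtures
# ---------------------------------------------------------------------------

def read_dense_text(path, chrom: str, bin_size: int, max_distance_bins: int) -> ContactMap:
    """Read a whitespace-delimited dense square matrix as a banded ContactMap."""
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: dense matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError(f"{path}: dense matrix must be symmetric")
    i, j = np.indices(m.shape, sparse=True)
    band = (j - i >= 0) & (j - i <= max_distance_bins)
    return ContactMap(chrom=chrom, bin_size=bin_size, counts=np.where(band, m, 0.0),
                      max_distance_bins=max_distance_bins)
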