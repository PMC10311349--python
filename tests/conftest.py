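"""Shared fixtures: small synthetic maps, balanced maps, toy panels.

Everything is generated programmatically; sizes are desk-scale so the whole
suite runs on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

import panelhic as ph


@pytest.fixture(scope="session")
def small_spec() -> ph.GenomeSpec:
    return ph.GenomeSpec.random(n_bins=200, n_loops=12, seed=11)


@pytest.fixture(scope="session")
def small_counts(small_spec) -> ph.ContactMap:
    ct = ph.CellTypeSpec(base=small_spec, seed=7)
    return ph.sample_counts(ph.expected_map(ct), 400_000, seed=5)


@pytest.fixture(scope="session")
def small_balanced(small_counts) -> ph.ContactMap:
    return ph.ice_balance(small_counts)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_banded_map(rng, n_bins=60, band=30, density=0.3,
                      float_values=False) -> ph.ContactMap:
    """Random upper-banded ContactMap for round-trip style tests."""
    counts = np.zeros((n_bins, n_bins))
    i, j = np.indices((n_bins, n_bins))
    sel = (j >= i) & (j - i <= band) & (rng.random((n_bins, n_bins)) < density)
    if float_values:
        counts[sel] = rng.random(sel.sum()) * 5
    else:
        counts[sel] = rng.integers(1, 100, sel.sum())
    return ph.ContactMap(chrom="chrT", bin_size=5000, counts=counts,
                         max_distance_bins=band)
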