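"""Shared fixtures and small genotype-matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeMatrix, PopulationMap


def make_gm(
    calls,
    positions=None,
    chrom: str = "chr1",
    sample_ids=None,
    **site_columns,
) -> GenotypeMatrix:
    """GenotypeMatrix from a (n_samples, n_sites) array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A",
        "alt": "G",
    })
    for col, vals in site_columns.items():
        sites[col] = vals
    return GenotypeMatrix(list(sample_ids), sites, calls)


def random_gm(rng, n_samples=6, n_sites=30, missing_rate=0.05, span=100_000):
    """Random biallelic genotypes with some missing calls."""
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    miss = rng.uniform(size=calls.shape) < missing_rate
    calls[miss] = -1
    positions = np.sort(
        rng.choice(np.arange(1, span + 1), size=n_sites, replace=False)
    )
    return make_gm(calls, positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_pop_map():
    def build(gm: GenotypeMatrix, n_first: int) -> PopulationMap:
        return PopulationMap({
            s: ("sport" if i < n_first else "non_sport")
            for i, s in enumerate(gm.sample_ids)
        })
    return build
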