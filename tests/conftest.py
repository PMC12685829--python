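"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sweeproh import GenomeLayout, VariantMatrix


@pytest.fixture
def layout_1mb() -> GenomeLayout:
    return GenomeLayout(("chr1",), (1_000_000,), (True,))


@pytest.fixture
def layout_two() -> GenomeLayout:
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 800_000), (True, True))


def make_matrix(
    genotypes,
    pos=None,
    chrom="chr1",
    sample_ids=None,
    haplotypes=None,
) -> VariantMatrix:
    """Build a single-chromosome VariantMatrix from a genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samples = g.shape
    if pos is None:
        pos = np.arange(n_var) * 1000 + 100
    if sample_ids is None:
        sample_ids = tuple(f"s{i + 1}" for i in range(n_samples))
    return VariantMatrix(
        sample_ids=tuple(sample_ids),
        chrom=np.full(n_var, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=np.full(n_var, "A", dtype=object),
        alt_allele=np.full(n_var, "G", dtype=object),
        genotypes=g,
        haplotypes=haplotypes,
    )


def random_phased_matrix(rng, n_samples=6, n_sites=50, span=100_000) -> VariantMatrix:
    """Random fully-phased matrix (no missing data) on one chromosome."""
    pos = np.sort(rng.choice(span - 1, size=n_sites, replace=False))
    haps = rng.integers(0, 2, size=(n_sites, n_samples, 2), dtype=np.int8)
    return make_matrix(
        haps.sum(axis=2), pos=pos, haplotypes=haps
    )
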