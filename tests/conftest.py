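"""Shared fixtures: small deterministic genomes and libraries."""

from __future__ import annotations

import pytest

import rindseq as rs


@pytest.fixture(scope="session")
def toy_genome() -> rs.Genome:
    """50 kb, 16 chromosomes, yeast-like base composition."""
    return rs.generate_genome(16, rs.yeast_like_lengths(50000), seed=1)


@pytest.fixture(scope="session")
def small_genome() -> rs.Genome:
    """10 kb, 3 chromosomes — for brute-force comparisons."""
    return rs.generate_genome(3, [5000, 3000, 2000], seed=7)


@pytest.fixture(scope="session")
def planted_library(toy_genome):
    """Error-free library with breaks enriched after ACGT (~11.5%)."""
    w = rs.motif_weight_for_fraction(toy_genome, "ACGT", 124 / 1080)
    breaks = rs.plant_breaks(toy_genome, 1080, {"ACGT": w}, seed=2)
    lib = rs.simulate_library(
        toy_genome, breaks, params=rs.LibraryParams(n_products=4000, seed=3)
    )
    return breaks, lib


@pytest.fixture(scope="session")
def type1_library(toy_genome):
    """Pure type-1, error-free library for round-trip checks."""
    breaks = rs.plant_breaks(toy_genome, 400, seed=5)
    lib = rs.simulate_library(
        toy_genome,
        breaks,
        params=rs.LibraryParams(
            n_products=600, product_mix=(1, 0, 0, 0, 0), seed=6
        ),
    )
    return breaks, lib
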