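import numpy as np
import pandas as pd
import pytest

from spliceqtl.core_io import GenotypeMatrix, Variant
from spliceqtl.synthetic_data import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """400-sample block-LD panel used across LD/QTL tests."""
    cfg = SimConfig(n_samples=400, n_chrom=1, n_blocks_per_chrom=5,
                    block_size=10, within_block_rho=0.9,
                    variant_spacing=1_000, block_spacing=200_000,
                    chrom_len=2_000_000, seed=7)
    return simulate_genotypes(cfg)


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    """Hand-written 6-sample, 4-variant matrix with one missing call."""
    variants = [
        Variant("v1", "chr1", 100, "A", "G"),
        Variant("v2", "chr1", 200, "C", "T"),
        Variant("v3", "chr1", 5_000, "G", "A"),
        Variant("v4", "chr2", 100, "T", "C"),
    ]
    dosage = np.array([
        [0, 0, 2, 1],
        [1, 0, 1, 1],
        [2, 1, 0, 0],
        [0, 1, 2, 2],
        [1, 2, 1, 0],
        [np.nan, 0, 0, 1],
    ], dtype=float)
    return GenotypeMatrix(variants, [f"s{i}" for i in range(6)], dosage)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
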