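import numpy as np
import pandas as pd
import pytest

import aneudose as ad


@pytest.fixture(scope="session")
def small_layout():
    """600-gene genome: one 500-gene target chromosome plus a euploid one."""
    return ad.genome_layout({"XII": 500, "I": 100})


@pytest.fixture(scope="session")
def null_trisomy(small_layout):
    """Trisomy XII strain with no compensation, sigma_rna fixed at 0.5."""
    noise = ad.NoiseModel(sigma_dna=0.1, sigma_rna_range=(0.5, 0.5))
    return ad.simulate_strain(
        small_layout, ad.KaryotypeSpec(2, {"XII": 3}), noise, seed=1
    )


@pytest.fixture(scope="session")
def null_series(small_layout):
    """2n/3n/4n chromosome-XII series, no compensation, sigma_rna 0.5."""
    noise = ad.NoiseModel(sigma_dna=0.1, sigma_rna_range=(0.5, 0.5))
    sims = ad.simulate_ploidy_series(
        small_layout, "XII", [2, 3, 4], noise, n_replicates=3, seed=1
    )
    return [(c, table) for c, (table, _) in zip([2, 3, 4], sims)]


def make_table(rows, **kw):
    """GeneTable from (gene, chrom, strain, rep, dna, rna) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome", "strain", "replicate", "dna_log2", "rna_log2"],
    )
    return ad.GeneTable(df, **kw)
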