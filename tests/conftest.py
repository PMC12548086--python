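import numpy as np
import pandas as pd
import pytest

import cistrans as ct


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete study: couplings, planted effects, one chromosome."""
    return ct.SimulationConfig(
        seed=11,
        n_chroms=1,
        n_genes=40,
        n_peaks=80,
        n_dmrs=12,
        n_dars=12,
        n_degs=20,
        n_cis_meth=3,
        n_trans_meth=3,
        n_cis_atac=3,
        n_trans_atac=3,
        n_rhythm_genes=4,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return ct.make_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, tiny_genome):
    return ct.simulate_omics(tiny_genome, tiny_config)


@pytest.fixture()
def toy_annotation():
    """Two genes on one chromosome, one enhancer, hand-placed partitions."""
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "tss": [10_000, 52_000],
            "start": [10_000, 50_000],
            "end": [14_000, 52_000],
        }
    )
    partitions = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr1"],
            "start": [9_000, 10_100, 30_000, 9_900],
            "end": [9_900, 11_000, 31_000, 10_100],
            "label": ["Promoter", "Intron", "LINE", "TSS"],
        }
    )
    enhancers = pd.DataFrame(
        {"chrom": ["chr1"], "start": [90_000], "end": [90_500], "target": ["gA"]}
    )
    return ct.GenomeAnnotation(
        chrom_sizes={"chr1": 200_000},
        genes=genes,
        partitions=partitions,
        enhancers=enhancers,
    )


@pytest.fixture()
def small_meth_matrix():
    """Hand-built site matrix: 4 sites, 2+2 samples."""
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "start": [100, 150, 210, 400], "end": [101, 151, 211, 401]}
    )
    samples = pd.DataFrame(
        {"sample_id": ["FA_1", "FA_2", "PM_1", "PM_2"], "group": ["FA", "FA", "PM", "PM"]}
    )
    meth = pd.DataFrame(
        {"FA_1": [9, 8, 5, 1], "FA_2": [7, 9, 4, 2], "PM_1": [2, 1, 5, 1], "PM_2": [1, 2, 6, 2]}
    )
    total = pd.DataFrame(
        {"FA_1": [10, 10, 10, 10], "FA_2": [10, 10, 10, 10],
         "PM_1": [10, 10, 10, 10], "PM_2": [10, 10, 10, 10]}
    )
    return ct.MethylSiteMatrix(sites=sites, meth=meth, total=total, samples=samples)
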