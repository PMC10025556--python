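import numpy as np
import pandas as pd
import pytest

import regcis as rc


@pytest.fixture(scope="session")
def genome_1mb():
    return rc.make_genome(1, [1_000_000], ttaa_density=1 / 300, seed=7)


@pytest.fixture(scope="session")
def genome_2chrom():
    return rc.make_genome(2, [500_000, 300_000], ttaa_density=1 / 300, seed=11)


@pytest.fixture()
def toy_table():
    """Hand-built 6-insertion table over 2 samples and 2 chromosomes."""
    df = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr1"],
        "pos": [100, 5000, 100, 700, 900, 200_000],
        "strand": ["+", "-", "+", "+", "-", "+"],
        "sample": ["S1", "S1", "S2", "S1", "S2", "S2"],
        "reads": [10_000, 500, 2, 50, 7, 3],
    })
    return rc.InsertionTable(df.copy())


@pytest.fixture(scope="session")
def toy_genes():
    genes = pd.DataFrame({
        "name": ["Pcg1", "Pcg2", "Linc1", "Igk", "Sfi1"],
        "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
        "start": [10_000, 200_000, 400_000, 50_000, 150_000],
        "end": [60_000, 260_000, 420_000, 80_000, 180_000],
        "strand": ["+", "-", "+", "+", "+"],
        "biotype": ["protein_coding", "protein_coding", "lncRNA", "IG", "protein_coding"],
    })
    return rc.GeneModel(genes, expression={"Pcg1": 0.0, "Pcg2": 30.0, "Linc1": 5.0})


def make_cis(chrom="chr1", start=0, end=10_000, peak=None, n_ins=10, n_samp=5,
             p=0.001, height=1e-3, scale=5_000):
    return rc.CIS(chrom=chrom, start=start, end=end,
                  peak_pos=peak if peak is not None else (start + end) // 2,
                  peak_height=height, p_value=p, n_insertions=n_ins,
                  n_samples=n_samp, scale=scale)


@pytest.fixture()
def cis_factory():
    return make_cis
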