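import numpy as np
import pandas as pd
import pytest

from methexpr.io import AnnotationTable, GeneModel, Transcript
from methexpr.simulate import CohortSpec, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Three small cohorts (one sparse) with strong planted effects."""
    return SimConfig(
        seed=11,
        n_genes=80,
        probes_per_gene_sparse=2,
        probes_per_gene_dense=6,
        cohorts=[
            CohortSpec("A", 20, 20, "sparse"),
            CohortSpec("B", 20, 20, "dense"),
            CohortSpec("C", 40, 40, "dense"),
        ],
        beta_noise_sd=0.3,
        frac_inconsistent=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def make_annotation(rows):
    """rows: (probe_id, chrom, pos0, gene, cgi, on_sparse, on_dense)."""
    probes = pd.DataFrame(
        [
            {"probe_id": r[0], "chrom": r[1], "pos": r[2], "cgi_relation": r[4],
             "on_sparse": r[5], "on_dense": r[6]}
            for r in rows
        ]
    )
    assoc = pd.DataFrame(
        [{"probe_id": r[0], "gene": r[3], "region_tag": ""} for r in rows if r[3]]
    )
    if assoc.empty:
        assoc = pd.DataFrame(columns=["probe_id", "gene", "region_tag"])
    return AnnotationTable(probes, assoc)


def plus_gene(symbol="GPLUS", tss=1000):
    """3-exon coding + strand toy gene starting at ``tss``."""
    tx = Transcript(
        name=f"{symbol}|tx1", chrom="chr1", strand="+",
        start=tss, end=tss + 2400,
        exons=((tss, tss + 300), (tss + 800, tss + 1100), (tss + 1900, tss + 2400)),
        thick_start=tss + 150, thick_end=tss + 2100,
    )
    return GeneModel(symbol, [tx])


def minus_gene(symbol="GMINUS", tss=5000):
    """3-exon coding - strand toy gene whose TSS (= end-1) is ``tss``."""
    end = tss + 1
    start = end - 2400
    tx = Transcript(
        name=f"{symbol}|tx1", chrom="chr1", strand="-",
        start=start, end=end,
        exons=((start, start + 500), (start + 1300, start + 1600),
               (start + 2100, end)),
        thick_start=start + 300, thick_end=start + 2250,
    )
    return GeneModel(symbol, [tx])


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
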