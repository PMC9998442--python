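import numpy as np
import pytest
import scipy.sparse as sp

import peaklinks as pl


@pytest.fixture(scope="session")
def small_sim():
    """A reduced structured simulation shared across tests: one dominant and
    one rare cell type, quick to generate and score."""
    cfg = pl.SimulationConfig(
        seed=7,
        n_cells=500,
        n_genes=24,
        n_cis_peaks_per_gene=3,
        n_trans_peaks=260,
    )
    dataset, truth = pl.simulate_multiome(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_scored(small_sim):
    cfg, dataset, truth = small_sim
    scorer = pl.LinkScorer(dataset, seed=11, n_draws=100)
    links = scorer.score(pl.cis_candidates(dataset.peaks, dataset.genes),
                         r_threshold=0.0, min_both_nonzero=0)
    return scorer, links


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-cell dataset with known counts."""
    atac = sp.csc_matrix(np.array([[3, 0], [1, 2], [0, 0], [2, 5]]))
    rna = sp.csc_matrix(np.array([[1, 0, 4], [0, 0, 1], [2, 1, 0], [3, 0, 2]]))
    peaks = [
        pl.PeakAnnotation(pl.GenomicInterval("chr1", 100, 600, id="pk1"), gc=0.4),
        pl.PeakAnnotation(pl.GenomicInterval("chr2", 100, 600, id="pk2"), gc=0.6),
    ]
    genes = [
        pl.GeneAnnotation("g1", "chr1", 1000),
        pl.GeneAnnotation("g2", "chr1", 300000),
        pl.GeneAnnotation("g3", "chr2", 2000),
    ]
    return pl.MultiomeDataset(
        atac=atac, rna=rna, peaks=peaks, genes=genes,
        barcodes=[f"bc{i}" for i in range(4)],
        cell_types=np.array(["a", "a", "b", "b"], dtype=object),
    )
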