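import numpy as np
import pytest

from paleoexpr.datatypes import GeneMatrix
from paleoexpr.diffexpr import TimecourseModel
from paleoexpr.preprocess import quantile_normalize, summarize_genes
from paleoexpr.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Sequence-free autogamy dataset: 400 ancestral genes, clean noise."""
    cfg = SimConfig(
        n_ancestral=400,
        seed=101,
        frac_pseudogene=0.0,
        crosshyb_weight=0.0,
        noise_sd=0.15,
    )
    return simulate_dataset(cfg, "autogamy", with_sequences=False)


@pytest.fixture(scope="session")
def small_gene_matrix(small_dataset) -> GeneMatrix:
    pm = small_dataset.probe_matrix
    values = quantile_normalize(pm.values)
    pm = type(pm)(values=values, probe_genes=pm.probe_genes)
    return summarize_genes(pm, small_dataset.sample_sheet)


@pytest.fixture(scope="session")
def plain_gene_matrix(small_dataset) -> GeneMatrix:
    """Gene matrix summarized without quantile normalization.

    Used by tests of the DE/enrichment statistics themselves: with 30% of
    genes strongly DE, quantile normalization redistributes mass across
    samples and perturbs flat genes' profiles, which would confound null
    calibration checks.
    """
    return summarize_genes(small_dataset.probe_matrix, small_dataset.sample_sheet)


@pytest.fixture(scope="session")
def small_de_results(small_gene_matrix):
    return TimecourseModel(small_gene_matrix).fit(method="treat", fold_change=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
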