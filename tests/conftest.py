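import numpy as np
import pandas as pd
import pytest

from gfblup import (ArchitectureSpec, GeneLexicon, GenotypePanel, SNPPartition,
                    simulate_genotypes, simulate_phenotype)


@pytest.fixture
def toy_panel():
    """Hand-built 3-sample, 4-SNP panel on two chromosomes."""
    snps = pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3", "rs4"],
        "chrom": ["1", "1", "2", "2"],
        "pos": [100, 200, 100, 300],
        "a1": ["A"] * 4, "a2": ["B"] * 4,
    })
    dosage = np.array([[0, 1, 2, 0],
                       [1, 1, 0, 1],
                       [2, 0, 1, 2]], dtype=np.int8)
    return GenotypePanel(["i1", "i2", "i3"], snps, dosage)


@pytest.fixture
def sim_panel():
    """Moderate simulated panel with annotation (seeded)."""
    return simulate_genotypes(n=120, m=600, n_chrom=4, seed=11)


@pytest.fixture
def sim_dataset(sim_panel):
    """Panel + partition + phenotype with a feature-enriched architecture."""
    panel, ann = sim_panel
    part = SNPPartition(panel.n_snps, tm=np.arange(0, panel.n_snps, 7))
    spec = ArchitectureSpec(h2=0.5, n_qtl=60, f_tm=0.5)
    pheno, truth = simulate_phenotype(panel, part, spec, seed=7)
    return panel, part, pheno, truth


@pytest.fixture
def lexicon():
    return GeneLexicon({"IGF1", "CAST", "SCD", "MSTN", "MSC"},
                       aliases={"GDF8": "MSTN"})
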