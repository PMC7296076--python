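import numpy as np
import pandas as pd
import pytest

from pigpopgen import GenotypePanel, SimConfig, simulate_structured


def make_panel(geno, breeds=None, chroms=None, pos=None, alleles=None):
    """Hand-built panel from a genotype code matrix (-1 = missing)."""
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    breeds = breeds if breeds is not None else ["B1"] * n
    chroms = chroms if chroms is not None else ["1"] * m
    pos = pos if pos is not None else [100 * (j + 1) for j in range(m)]
    alleles = alleles if alleles is not None else [("A", "G")] * m
    samples = pd.DataFrame(
        {"sample_id": [f"S{i}" for i in range(n)], "breed": breeds, "farm": ""}
    )
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chroms,
            "pos_bp": pos,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    return GenotypePanel(samples, variants, geno)


def flip_variants(panel, idx):
    """Recode allele_b -> allele_a at the given variant columns (dosage 2-g)."""
    geno = panel.genotypes.copy()
    cols = geno[:, idx]
    geno[:, idx] = np.where(cols == -1, -1, 2 - cols)
    variants = panel.variants.copy()
    a = variants.loc[idx, "allele_a"].copy()
    variants.loc[idx, "allele_a"] = variants.loc[idx, "allele_b"].to_numpy()
    variants.loc[idx, "allele_b"] = a.to_numpy()
    return GenotypePanel(panel.samples, variants, geno)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two populations at drift 0.15, moderate size; shared across tests."""
    panel, truth = simulate_structured(
        SimConfig(n_pops=2, samples_per_pop=60, n_snps=2000, drift=0.15, seed=42)
    )
    return panel, truth
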