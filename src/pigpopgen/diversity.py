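"""Observed/expected heterozygosity and the homozygote-excess inbreeding coefficient.

Fis follows the method-of-moments form used by SNP-array toolchains:

    Fis = (O(HOM) - E(HOM)) / (N(NM) - E(HOM))

where, per individual, O(HOM) is the observed homozygote count over its
non-missing genotypes, N(NM) the non-missing count, and E(HOM) the expected
homozygote count sum(1 - 2 p (1-p) N/(N-1)) with p the allele-B frequency in a
chosen reference set of N genotyped samples.  The frequency reference is an
explicit parameter: ``"pooled_panel"`` (default) computes p over the whole
panel, which makes Fis absorb between-breed differentiation (Wahlund effect);
``"within_group"`` is the statistically conventional within-breed estimate.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .plink import MISSING, GenotypePanel

FREQ_REFERENCES = ("within_group", "pooled_panel")


def _freq_and_n(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Allele-B frequency and genotyped-sample count per variant column."""
    called = geno != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, geno, 0).sum(axis=0) / (2.0 * n)
    return p, n


def observed_heterozygosity(panel: GenotypePanel, group_col: str = "breed") -> dict[str, float]:
    """Mean per-individual heterozygous fraction for each group.

    Individuals with zero non-missing calls are excluded with a warning.
    """
    geno = panel.genotypes
    het = (geno == 1).sum(axis=1)
    nm = (geno != MISSING).sum(axis=1)
    out: dict[str, float] = {}
    for label, idx in panel.sample_groups(group_col).items():
        ok = nm[idx] > 0
        if not ok.all():
            warnings.warn(f"group {label}: {np.sum(~ok)} sample(s) with no calls excluded")
        idx = idx[ok]
        if idx.size == 0:
            raise ValueError(f"group {label} has no sample with called genotypes")
        out[label] = float(np.mean(het[idx] / nm[idx]))
    return out


def expected_heterozygosity(
    panel: GenotypePanel, group_col: str = "breed", bias_correct: bool = True
) -> dict[str, float]:
    """Within-group Hardy–Weinberg heterozygosity, averaged over SNPs.

    Per SNP, He = 2 p (1-p), multiplied by N/(N-1) when ``bias_correct``
    (N = genotyped group members at the SNP).  The average runs over SNPs
    polymorphic in the whole panel; SNPs monomorphic within the group
    contribute 0.
    """
    p_all, _ = _freq_and_n(panel.genotypes)
    poly = (p_all > 0) & (p_all < 1)
    out: dict[str, float] = {}
    for label, idx in panel.sample_groups(group_col).items():
        p, n = _freq_and_n(panel.genotypes[idx])
        he = 2.0 * p * (1.0 - p)
        if bias_correct:
            with np.errstate(invalid="ignore", divide="ignore"):
                he = he * n / (n - 1.0)
            he[n < 2] = np.nan
        he = he[poly]
        out[label] = float(np.nanmean(he)) if he.size else np.nan
    return out


def inbreeding_fis(
    panel: GenotypePanel,
    group_col: str = "breed",
    freq_reference: str = "pooled_panel",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual Fis and per-group summaries.

    Returns
    -------
    per_individual
        DataFrame with ``sample_id``, group label, ``o_hom``, ``e_hom``,
        ``n_nm``, ``fis`` and a ``degenerate`` flag (True where
        N(NM) = E(HOM) leaves Fis undefined).
    per_group
        DataFrame indexed by group with ``n``, ``fis_mean`` and
        ``fis_cv_percent`` (population-SD coefficient of variation).
    """
    if freq_reference not in FREQ_REFERENCES:
        raise ValueError(f"freq_reference must be one of {FREQ_REFERENCES}")
    geno = panel.genotypes
    called = geno != MISSING

    if freq_reference == "pooled_panel":
        p, n_ref = _freq_and_n(geno)

    rows = []
    for label, idx in panel.sample_groups(group_col).items():
        if freq_reference == "within_group":
            p, n_ref = _freq_and_n(geno[idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_hom_snp = 1.0 - 2.0 * p * (1.0 - p) * n_ref / (n_ref - 1.0)
        usable = n_ref >= 2  # the correction needs at least two reference genotypes
        for i in idx:
            use = called[i] & usable
            n_nm = int(use.sum())
            o_hom = int(np.sum((geno[i][use] == 0) | (geno[i][use] == 2)))
            e_hom = float(exp_hom_snp[use].sum())
            denom = n_nm - e_hom
            degenerate = abs(denom) < 1e-12
            fis = np.nan if degenerate else (o_hom - e_hom) / denom
            rows.append((panel.samples.loc[i, "sample_id"], label, o_hom, e_hom, n_nm, fis, degenerate))

    per_individual = pd.DataFrame(
        rows, columns=["sample_id", group_col, "o_hom", "e_hom", "n_nm", "fis", "degenerate"]
    )
    summaries = []
    for label, grp in per_individual.groupby(group_col, sort=False):
        vals = grp["fis"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        mean = float(np.mean(vals)) if vals.size else np.nan
        sd = float(np.std(vals)) if vals.size else np.nan  # population SD
        cv = 100.0 * sd / mean if vals.size and mean != 0 else np.nan
        summaries.append((label, len(grp), mean, cv))
    per_group = pd.DataFrame(
        summaries, columns=[group_col, "n", "fis_mean", "fis_cv_percent"]
    ).set_index(group_col)
    return per_individual, per_group


def breed_diversity(
    panel: GenotypePanel,
    group_col: str = "breed",
    freq_reference: str = "pooled_panel",
    bias_correct: bool = True,
) -> pd.DataFrame:
    """Combined per-breed table: n, Ho, He, mean Fis and its CV (percent)."""
    ho = observed_heterozygosity(panel, group_col)
    he = expected_heterozygosity(panel, group_col, bias_correct=bias_correct)
    _, per_group = inbreeding_fis(panel, group_col, freq_reference=freq_reference)
    per_group = per_group.copy()
    per_group.insert(1, "ho", pd.Series(ho))
    per_group.insert(2, "he", pd.Series(he))
    return per_group
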