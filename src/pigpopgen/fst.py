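"""Between-group genetic differentiation (Fst): per-locus tracks, aggregates,
pairwise matrices and the conventional qualitative bands.

Two estimators are exposed.  The default is the Weir–Cockerham (1984)
two-population diploid variance-components estimator: per locus the components
a (among populations), b (among individuals within populations) and c (within
individuals) are computed from sample sizes, allele frequencies and observed
heterozygosities, and the multi-locus aggregate is the ratio of sums
sum(a) / sum(a+b+c) — not the mean of per-locus ratios.  A plain Nei-style
(Ht - Hs)/Ht estimator is provided for comparison in selection scans.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .plink import MISSING, GenotypePanel

ESTIMATORS = ("weir_cockerham", "nei")


@dataclass
class FstResult:
    """Per-locus Fst track plus its ratio-of-sums aggregate for one group pair."""

    per_locus: np.ndarray
    aggregate: float
    groups: tuple[str, str]
    estimator: str
    variant_ids: list


def group_allele_stats(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n genotyped, allele-B frequency, observed het frequency) per variant."""
    called = geno != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, geno, 0).sum(axis=0) / (2.0 * n)
        h = np.where(called, geno == 1, 0).sum(axis=0) / n
    return n.astype(float), p, h


def weir_cockerham_components(
    geno1: np.ndarray, geno2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) of the two-population estimator.

    Loci where either group has fewer than one genotyped diploid, or where the
    pooled sample is monomorphic, yield NaN components.
    """
    n1, p1, h1 = group_allele_stats(geno1)
    n2, p2, h2 = group_allele_stats(geno2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _nei_per_locus(geno1: np.ndarray, geno2: np.ndarray) -> np.ndarray:
    _, p1, _ = group_allele_stats(geno1)
    _, p2, _ = group_allele_stats(geno2)
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 1.0 - hs / ht
    fst[ht == 0] = np.nan
    return fst


def fst_weir_cockerham(
    panel: GenotypePanel,
    pair: tuple[str, str],
    group_col: str = "breed",
    estimator: str = "weir_cockerham",
) -> FstResult:
    """Fst between two labeled groups: per-locus track + ratio-of-sums aggregate."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    groups = panel.sample_groups(group_col)
    for g in pair:
        if g not in groups:
            raise ValueError(f"group {g!r} not present in column {group_col!r}")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
    geno1 = panel.genotypes[groups[pair[0]]]
    geno2 = panel.genotypes[groups[pair[1]]]

    if estimator == "weir_cockerham":
        a, b, c = weir_cockerham_components(geno1, geno2)
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus = a / denom
        per_locus[np.nan_to_num(denom) == 0] = np.nan
        ok = ~np.isnan(denom) & (denom != 0)
        aggregate = float(np.nansum(a[ok]) / np.nansum(denom[ok])) if ok.any() else np.nan
    else:
        per_locus = _nei_per_locus(geno1, geno2)
        aggregate = float(np.nanmean(per_locus))
    return FstResult(
        per_locus=per_locus,
        aggregate=aggregate,
        groups=(pair[0], pair[1]),
        estimator=estimator,
        variant_ids=list(panel.variants["id"]),
    )


def pairwise_fst_matrix(
    panel: GenotypePanel, group_col: str = "breed", estimator: str = "weir_cockerham"
) -> DistanceMatrix:
    """Symmetric matrix of aggregate Fst between every pair of groups."""
    labels = list(panel.sample_groups(group_col))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            f = fst_weir_cockerham(panel, (labels[i], labels[j]), group_col, estimator)
            values[i, j] = values[j, i] = f.aggregate
    return DistanceMatrix(ids=labels, values=values)


#: Qualitative differentiation bands (lower-inclusive half-open intervals).
FST_BANDS = (
    (0.05, "low"),
    (0.15, "moderate"),
    (0.25, "great"),
    (np.inf, "high"),
)


def classify_fst(value: float) -> str:
    """Band a differentiation coefficient: [0,0.05) low, [0.05,0.15) moderate,
    [0.15,0.25) great, >= 0.25 high.  Small negatives clamp to "low"."""
    if value < -0.05:
        raise ValueError("Fst below -0.05 is outside the estimator's plausible range")
    v = max(value, 0.0)
    for upper, name in FST_BANDS:
        if v < upper:
            return name
    return "high"
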