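"""Allele-sharing distances, breed-average distances and PCA coordinates.

The individual-level distance is 1 - Dst, where Dst is the average proportion
of alleles shared over pairwise-complete SNPs: per SNP a pair scores 1 for
identical genotypes, 0.5 for one shared allele and 0 for opposite homozygotes
(equivalently 1 - |g_i - g_j| / 2 on allele-B dosages).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plink import GenotypePanel


@dataclass
class DistanceMatrix:
    """Symmetric labeled distance (or Fst) matrix."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        """Square tab-separated export (heatmap input)."""
        self.to_frame().to_csv(path, sep="\t")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def lookup(self, a, b) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def allele_sharing_distance(panel: GenotypePanel) -> DistanceMatrix:
    """(1 - Dst) over pairwise-complete SNPs for every pair of individuals.

    Pairs with zero co-nonmissing SNPs get NaN and trigger a warning.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    d = panel.dosages()
    n = panel.n_samples
    values = np.zeros((n, n))
    n_undefined = 0
    for i in range(n - 1):
        diff = np.abs(d[i + 1:] - d[i])  # NaN where either is missing
        counts = np.sum(~np.isnan(diff), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = np.nanmean(diff, axis=1) / 2.0
        dist[counts == 0] = np.nan
        n_undefined += int((counts == 0).sum())
        values[i, i + 1:] = dist
        values[i + 1:, i] = dist
    if n_undefined:
        warnings.warn(f"{n_undefined} pair(s) with zero co-nonmissing SNPs (distance NaN)")
    return DistanceMatrix(ids=list(panel.samples["sample_id"]), values=values)


def breed_average_distance(dist: DistanceMatrix, labels: dict) -> DistanceMatrix:
    """Average the individual matrix into a breed-level matrix.

    Off-diagonal cells average all cross-breed pairs; the diagonal averages
    distinct within-breed pairs (NaN for singleton breeds, with a warning).
    """
    missing = [i for i in dist.ids if i not in labels]
    if missing:
        raise ValueError(f"unlabeled ids: {missing[:5]}")
    breeds = list(dict.fromkeys(labels[i] for i in dist.ids))
    idx = {b: [k for k, i in enumerate(dist.ids) if labels[i] == b] for b in breeds}
    k = len(breeds)
    values = np.zeros((k, k))
    for ai, a in enumerate(breeds):
        ia = idx[a]
        if len(ia) < 2:
            warnings.warn(f"breed {a}: single member, within-breed distance undefined")
            values[ai, ai] = np.nan
        else:
            sub = dist.values[np.ix_(ia, ia)]
            values[ai, ai] = sub[np.triu_indices(len(ia), k=1)].mean()
        for bi in range(ai + 1, k):
            cross = dist.values[np.ix_(ia, idx[breeds[bi]])]
            values[ai, bi] = values[bi, ai] = cross.mean()
    return DistanceMatrix(ids=breeds, values=values)


def pca_coordinates(
    panel: GenotypePanel, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of column-standardized genotypes.

    Missing dosages are mean-imputed per SNP; columns are centered and scaled
    by their empirical SD (zero-variance columns dropped).  Returns per-sample
    coordinates (columns PC1..PCk) and the variance fractions.
    """
    if n_components > min(panel.n_samples, panel.n_variants):
        raise ValueError("n_components exceeds matrix rank bound")
    x = panel.dosages()
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("zero-variance panel: PCA undefined")
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    var_frac = (s**2 / np.sum(s**2))[:n_components]
    df = pd.DataFrame(
        coords,
        columns=[f"PC{i + 1}" for i in range(n_components)],
        index=panel.samples["sample_id"],
    )
    return df, var_frac
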