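"""The three-population admixture test f3(target; A, B) with block-jackknife Z.

Per usable SNP the statistic is (x - p_a)(x - p_b) minus the small-sample bias
term x(1-x)/(2 n_x - 1), where x, p_a, p_b are sample allele frequencies and
n_x is the number of genotyped target diploids; the subtraction is the
unbiased estimator of Var(x) and removes the positive bias of the raw product.
A significantly negative f3 (Z < -2, standard error from a delete-one-block
jackknife over consecutive map blocks of SNPs) indicates the target is an
admixture of populations related to the two sources.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fst import group_allele_stats
from .plink import GenotypePanel


@dataclass
class F3Result:
    target: str
    source_a: str
    source_b: str
    f3: float
    se: float
    z: float
    n_blocks: int
    block_size_snps: int
    n_snps_used: int

    @property
    def significant(self) -> bool:
        """The admixture call: Z < -2."""
        return bool(self.z < -2.0)


def _per_snp_f3(panel: GenotypePanel, group_col, target, a, b):
    groups = panel.sample_groups(group_col)
    for g in (target, a, b):
        if g not in groups or len(groups[g]) < 2:
            raise ValueError(f"group {g!r} absent or has fewer than 2 samples")
    n_x, x, _ = group_allele_stats(panel.genotypes[groups[target]])
    _, p_a, _ = group_allele_stats(panel.genotypes[groups[a]])
    _, p_b, _ = group_allele_stats(panel.genotypes[groups[b]])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (x - p_a) * (x - p_b) - x * (1.0 - x) / (2.0 * n_x - 1.0)
    usable = ~(np.isnan(x) | np.isnan(p_a) | np.isnan(p_b)) & (n_x >= 1)
    vals[~usable] = np.nan
    return vals


def f3_statistic(
    panel: GenotypePanel, target: str, a: str, b: str, group_col: str = "breed"
) -> float:
    """Mean bias-corrected f3 over usable SNPs (symmetric in the sources)."""
    vals = _per_snp_f3(panel, group_col, target, a, b)
    if np.all(np.isnan(vals)):
        raise ValueError("no usable SNPs for the f3 statistic")
    return float(np.nanmean(vals))


def block_jackknife_z(
    panel: GenotypePanel,
    target: str,
    a: str,
    b: str,
    group_col: str = "breed",
    block_size_snps: int = 200,
) -> F3Result:
    """f3 with delete-one-block jackknife SE over consecutive map blocks.

    SNPs are partitioned along the sorted (chrom, pos) map into blocks of
    ``block_size_snps``; a trailing partial block is kept if it holds at least
    half that many SNPs, otherwise it is folded into the previous block.  The
    SE uses the weighted delete-one jackknife, so unequal block sizes are
    handled exactly.
    """
    v = panel.variants
    order = np.lexsort((v["pos_bp"].to_numpy(), v["chrom"].to_numpy()))
    vals = _per_snp_f3(panel, group_col, target, a, b)[order]
    usable = ~np.isnan(vals)
    vals = vals[usable]
    n = vals.size
    if n < block_size_snps:
        raise ValueError("fewer usable SNPs than one jackknife block")

    starts = list(range(0, n, block_size_snps))
    if len(starts) > 1 and n - starts[-1] < block_size_snps / 2.0:
        starts.pop()  # fold the short tail into the previous block
    bounds = starts + [n]
    blocks = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(starts))]
    g = len(blocks)
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks")

    total = vals.sum()
    theta = total / n
    m = np.array([len(bk) for bk in blocks], dtype=float)
    theta_del = np.array([(total - vals[bk].sum()) / (n - len(bk)) for bk in blocks])

    # weighted delete-one jackknife (Busing, Meijer & van der Leeden 1999)
    h = n / m
    theta_jack = g * theta - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta - (h - 1.0) * theta_del
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = float(theta / se) if se > 0 else float(np.sign(theta) * np.inf) if theta else np.nan
    return F3Result(
        target=target, source_a=a, source_b=b,
        f3=float(theta), se=se, z=z,
        n_blocks=g, block_size_snps=block_size_snps, n_snps_used=n,
    )
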