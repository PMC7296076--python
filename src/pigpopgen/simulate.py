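"""Synthetic genotype panels with known structure for estimator-recovery testing.

Four generators cover the analysis surface:

* :func:`simulate_structured` — multi-population panels under the
  Balding–Nichols drift model with tunable within-population inbreeding,
  emulating a merged multi-breed SNP-array panel.
* :func:`simulate_families` — founder families with Mendelian offspring, the
  substrate for subfamily-partition recovery.
* :func:`simulate_wright_fisher_ld` — forward Wright–Fisher haplotypes with
  Haldane recombination, producing LD consistent with a known Ne.
* :func:`simulate_admixed` — a two-source admixed population for the f3 test.

Every generator is deterministic under a fixed seed and returns a
(:class:`~pigpopgen.plink.GenotypePanel`, :class:`SimTruth`) pair.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plink import MISSING, GenotypePanel


@dataclass
class SimConfig:
    """Parameters of a structured-panel simulation.

    ``drift`` is the Balding–Nichols drift parameter per population (scalar or
    per-population sequence, each in [0, 1)); the expected pairwise Fst between
    two populations is approximately the mean of their drift parameters.
    ``fis`` is within-population inbreeding in [0, 1).
    """

    n_pops: int = 2
    samples_per_pop: int | list = 50
    n_snps: int = 1000
    drift: float | list = 0.1
    fis: float | list = 0.0
    ancestral_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic panel."""

    pop_labels: np.ndarray
    true_fst: np.ndarray | None = None
    true_fis: np.ndarray | None = None
    family_labels: np.ndarray | None = None
    true_ne: int | None = None
    admixture_proportions: np.ndarray | None = None
    n_monomorphic: int = 0
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"pop": self.pop_labels})
        if self.family_labels is not None:
            df["family"] = self.family_labels
        if self.admixture_proportions is not None:
            df["admixture"] = self.admixture_proportions
        return df

    def write(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def _as_list(x, n: int, name: str) -> list:
    if np.isscalar(x):
        return [x] * n
    x = list(x)
    if len(x) != n:
        raise ValueError(f"{name} must be scalar or length {n}")
    return x


def _balding_nichols(rng, p_anc: np.ndarray, drift: float) -> np.ndarray:
    """Population frequencies around ``p_anc`` with drift parameter F.

    Beta(p(1-F)/F, (1-p)(1-F)/F), so E[p_pop] = p and
    Var[p_pop] = F p (1-p).  F = 0 returns the ancestral frequencies.
    """
    if drift <= 0:
        return p_anc.copy()
    lam = (1.0 - drift) / drift
    return rng.beta(p_anc * lam, (1.0 - p_anc) * lam)


def _draw_genotypes(rng, p: np.ndarray, n: int, fis: float) -> np.ndarray:
    """Sample n diploid genotypes at each frequency with inbreeding ``fis``.

    Genotype probabilities: P(0) = (1-p)^2 + F p(1-p), P(1) = 2p(1-p)(1-F),
    P(2) = p^2 + F p(1-p), i.e. HWE deformed by the within-population
    inbreeding coefficient.
    """
    pq = p * (1.0 - p)
    p0 = (1.0 - p) ** 2 + fis * pq
    p1 = 2.0 * pq * (1.0 - fis)
    u = rng.random((n, p.size))
    g = (u > p0).astype(np.int8) + (u > p0 + p1).astype(np.int8)
    return g


def _variant_frame(n_snps: int, n_chroms: int = 18, spacing_bp: int = 150_000) -> pd.DataFrame:
    """A variant map spreading SNPs over contiguous blocks of the pig autosomes."""
    per = int(np.ceil(n_snps / n_chroms))
    idx = np.arange(n_snps)
    chroms = [str(j // per + 1) for j in idx]
    pos = (idx % per + 1) * spacing_bp
    return pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_snps)],
            "chrom": chroms,
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "G",
        }
    )


def _inject_missing(rng, geno: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(geno.shape) < rate
        geno = geno.copy()
        geno[mask] = MISSING
    return geno


def simulate_structured(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a multi-population Balding–Nichols panel with known Fst/Fis."""
    sizes = _as_list(config.samples_per_pop, config.n_pops, "samples_per_pop")
    drifts = _as_list(config.drift, config.n_pops, "drift")
    fises = _as_list(config.fis, config.n_pops, "fis")
    if any(s <= 0 for s in sizes):
        raise ValueError("samples_per_pop must be positive")
    if any(not 0.0 <= d < 1.0 for d in drifts):
        raise ValueError("drift parameters must be in [0, 1)")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, config.n_snps)

    blocks, labels = [], []
    for k in range(config.n_pops):
        p_k = _balding_nichols(rng, p_anc, drifts[k])
        blocks.append(_draw_genotypes(rng, p_k, sizes[k], fises[k]))
        labels += [f"POP{k + 1}"] * sizes[k]
    geno = np.vstack(blocks)
    geno = _inject_missing(rng, geno, config.missing_rate)

    labels = np.asarray(labels)
    samples = pd.DataFrame(
        {"sample_id": [f"{lab}_{i}" for i, lab in enumerate(labels)],
         "breed": labels, "farm": ""}
    )
    panel = GenotypePanel(samples, _variant_frame(config.n_snps), geno)
    drifts_arr = np.asarray(drifts, dtype=float)
    true_fst = (drifts_arr[:, None] + drifts_arr[None, :]) / 2.0
    np.fill_diagonal(true_fst, 0.0)
    truth = SimTruth(
        pop_labels=labels,
        true_fst=true_fst,
        true_fis=np.asarray(fises, dtype=float),
        n_monomorphic=int((_maf(geno) == 0).sum()),
        params=vars(config).copy(),
    )
    return panel, truth


def _maf(geno: np.ndarray) -> np.ndarray:
    called = geno != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, geno, 0).sum(axis=0) / (2.0 * n)
    return np.minimum(p, 1 - p)


def simulate_families(
    n_families: int,
    founders_per_family: int,
    offspring_per_family: int,
    n_snps: int,
    seed: int = 0,
    founder_drift: float = 0.4,
) -> tuple[GenotypePanel, SimTruth]:
    """Families with distinct drifted founder pools and Mendelian offspring.

    Each family's allele-frequency pool is an independent Balding–Nichols draw
    with ``founder_drift``; founders are HWE draws from the pool and each
    offspring results from a random within-family founder pair.  The panel
    contains founders followed by offspring; family labels are recorded both
    in the truth object and in a ``family`` sample column.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    if founders_per_family < 2:
        raise ValueError("founders_per_family must be >= 2")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, n_snps)

    geno_rows, sample_ids, fam_labels = [], [], []
    for f in range(n_families):
        p_f = _balding_nichols(rng, p_anc, founder_drift)
        founders = _draw_genotypes(rng, p_f, founders_per_family, 0.0)
        for i in range(founders_per_family):
            geno_rows.append(founders[i])
            sample_ids.append(f"fam{f}_f{i}")
            fam_labels.append(f"F{f}")
        for o in range(offspring_per_family):
            pa, pb = rng.choice(founders_per_family, 2, replace=False)
            t1 = rng.random(n_snps) < founders[pa] / 2.0
            t2 = rng.random(n_snps) < founders[pb] / 2.0
            geno_rows.append((t1.astype(np.int8) + t2.astype(np.int8)))
            sample_ids.append(f"fam{f}_o{o}")
            fam_labels.append(f"F{f}")

    geno = np.vstack(geno_rows)
    fam_labels = np.asarray(fam_labels)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "breed": "FARM", "farm": "FARM", "family": fam_labels}
    )
    panel = GenotypePanel(samples, _variant_frame(n_snps), geno)
    truth = SimTruth(
        pop_labels=np.asarray(["FARM"] * len(sample_ids)),
        family_labels=fam_labels,
        params={
            "n_families": n_families,
            "founders_per_family": founders_per_family,
            "offspring_per_family": offspring_per_family,
            "founder_drift": founder_drift,
            "seed": seed,
        },
    )
    return panel, truth


def _meiosis(rng, hap_a: np.ndarray, hap_b: np.ndarray, pos_cm: np.ndarray, length_cm: float) -> np.ndarray:
    """One gamete from a diploid parent under the Haldane (no-interference) map."""
    n_cx = rng.poisson(length_cm / 100.0)
    start = rng.integers(2)
    if n_cx == 0:
        return hap_a if start == 0 else hap_b
    breaks = np.sort(rng.uniform(0.0, length_cm, n_cx))
    phase = (start + np.searchsorted(breaks, pos_cm)) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_wright_fisher_ld(
    ne: int,
    n_generations: int,
    n_snps: int,
    chrom_length_cm: float,
    n_sampled: int,
    seed: int = 0,
    n_chroms: int = 1,
) -> tuple[GenotypePanel, SimTruth]:
    """Forward Wright–Fisher simulation of 2*ne haplotypes with recombination.

    Sites start in linkage equilibrium at Uniform(0.1, 0.9) frequencies; drift
    with recombination then builds up LD whose decay with distance reflects
    ``ne``.  Positions are mapped to bp at 1 cM/Mb.  Chromosomes are simulated
    independently.
    """
    if ne < 10:
        raise ValueError("ne must be >= 10")
    if n_sampled > ne:
        raise ValueError("cannot sample more diploids than the population holds")
    rng = np.random.default_rng(seed)
    snps_per_chrom = [n_snps // n_chroms + (1 if c < n_snps % n_chroms else 0)
                      for c in range(n_chroms)]

    geno_cols, var_rows = [], []
    for c, m in enumerate(snps_per_chrom):
        pos_cm = np.sort(rng.uniform(0.0, chrom_length_cm, m))
        haps = (rng.random((2 * ne, m)) < rng.uniform(0.1, 0.9, m)).astype(np.int8)
        for _ in range(n_generations):
            parents = rng.integers(ne, size=2 * ne)
            new = np.empty_like(haps)
            for k in range(2 * ne):
                j = parents[k]
                new[k] = _meiosis(rng, haps[2 * j], haps[2 * j + 1], pos_cm, chrom_length_cm)
            haps = new
        picked = rng.choice(ne, n_sampled, replace=False)
        geno_cols.append(haps[2 * picked] + haps[2 * picked + 1])
        pos_bp = np.round(pos_cm * 1e6).astype(np.int64) + 1
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(m))  # strictly increasing
        for j in range(m):
            var_rows.append((f"c{c + 1}snp{j}", str(c + 1), int(pos_bp[j]), "A", "G"))

    geno = np.hstack(geno_cols).astype(np.int8)
    n_mono = int((_maf(geno) == 0).sum())
    if n_mono == geno.shape[1]:
        warnings.warn(f"all {n_mono} sites fixed at the end of the simulation; resimulate")
    samples = pd.DataFrame(
        {"sample_id": [f"wf_{i}" for i in range(n_sampled)], "breed": "WF", "farm": ""}
    )
    variants = pd.DataFrame(var_rows, columns=["id", "chrom", "pos_bp", "allele_a", "allele_b"])
    panel = GenotypePanel(samples, variants, geno)
    truth = SimTruth(
        pop_labels=np.asarray(["WF"] * n_sampled),
        true_ne=ne,
        n_monomorphic=n_mono,
        params={"ne": ne, "n_generations": n_generations, "n_snps": n_snps,
                "chrom_length_cm": chrom_length_cm, "n_sampled": n_sampled,
                "n_chroms": n_chroms, "seed": seed},
    )
    return panel, truth


def random_additive_matrix(n_taxa: int, seed: int = 0):
    """A random binary tree's additive distance matrix plus its bipartitions.

    Branch lengths are Uniform(0.5, 2).  Returns (DistanceMatrix, set of
    canonical bipartitions), the ground truth for neighbor-joining recovery
    tests (NJ is consistent on additive metrics).
    """
    from .distance import DistanceMatrix

    rng = np.random.default_rng(seed)
    labels = [f"T{i}" for i in range(n_taxa)]
    ref = min(labels)
    groups = [[l] for l in labels]
    depth = {l: 0.0 for l in labels}
    dist: dict = {}
    bipartitions: set = set()
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        gi, gj = groups[i], groups[j]
        bi, bj = rng.uniform(0.5, 2.0, 2)
        for a in gi:
            depth[a] += bi
        for b in gj:
            depth[b] += bj
        for a in gi:
            for b in gj:
                dist[frozenset((a, b))] = depth[a] + depth[b]
        merged = gi + gj
        if 1 < len(merged) < n_taxa - 1:
            side = set(merged) if ref not in merged else set(labels) - set(merged)
            bipartitions.add(frozenset(side))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    m = np.zeros((n_taxa, n_taxa))
    for ii in range(n_taxa):
        for jj in range(ii + 1, n_taxa):
            m[ii, jj] = m[jj, ii] = dist[frozenset((labels[ii], labels[jj]))]
    return DistanceMatrix(labels, m), bipartitions


def plant_extra_drift(
    panel: GenotypePanel,
    group: str,
    n_loci: int,
    extra_drift: float = 0.6,
    seed: int = 0,
) -> tuple[GenotypePanel, np.ndarray]:
    """Re-draw one group's genotypes at ``n_loci`` random loci with strong
    additional drift, marking them as planted selection signals.

    Returns the modified panel and the planted locus indices; the substrate
    for locus-specific branch-length enrichment tests.
    """
    rng = np.random.default_rng(seed)
    marked = np.sort(rng.choice(panel.n_variants, n_loci, replace=False))
    idx = panel.group_indices(group)
    p_anc = rng.uniform(0.1, 0.9, n_loci)
    p_sel = _balding_nichols(rng, p_anc, extra_drift)
    geno = panel.genotypes.copy()
    geno[np.ix_(idx, marked)] = _draw_genotypes(rng, p_sel, idx.size, 0.0)
    return GenotypePanel(panel.samples, panel.variants, geno), marked


def simulate_admixed(
    n_source_samples: int = 40,
    n_admixed_samples: int = 40,
    n_snps: int = 5000,
    alpha: float = 0.5,
    source_drift: float = 0.3,
    post_admixture_drift: float = 0.02,
    seed: int = 0,
) -> tuple[GenotypePanel, SimTruth]:
    """Two deeply split sources A and B plus a target mixing them alpha:(1-alpha).

    The admixed population's frequencies are alpha*p_A + (1-alpha)*p_B followed
    by a small post-admixture drift.  ``alpha`` = 0 or 1 gives the unadmixed
    null.  Groups are labeled SRC_A, SRC_B and ADM.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.1, 0.9, n_snps)
    p_a = _balding_nichols(rng, p_anc, source_drift)
    p_b = _balding_nichols(rng, p_anc, source_drift)
    p_mix = alpha * p_a + (1.0 - alpha) * p_b
    p_adm = _balding_nichols(rng, np.clip(p_mix, 1e-6, 1 - 1e-6), post_admixture_drift)

    blocks = [
        _draw_genotypes(rng, p_a, n_source_samples, 0.0),
        _draw_genotypes(rng, p_b, n_source_samples, 0.0),
        _draw_genotypes(rng, p_adm, n_admixed_samples, 0.0),
    ]
    labels = (["SRC_A"] * n_source_samples + ["SRC_B"] * n_source_samples
              + ["ADM"] * n_admixed_samples)
    labels = np.asarray(labels)
    props = np.concatenate([
        np.ones(n_source_samples), np.zeros(n_source_samples),
        np.full(n_admixed_samples, alpha),
    ])
    samples = pd.DataFrame(
        {"sample_id": [f"{lab}_{i}" for i, lab in enumerate(labels)],
         "breed": labels, "farm": ""}
    )
    panel = GenotypePanel(samples, _variant_frame(n_snps), np.vstack(blocks))
    truth = SimTruth(
        pop_labels=labels,
        admixture_proportions=props,
        params={"alpha": alpha, "source_drift": source_drift,
                "post_admixture_drift": post_admixture_drift, "seed": seed},
    )
    return panel, truth
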