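"""Selection scans: two-population per-SNP Fst ranking, the three-group
locus-specific branch length (LSBL), empirical top-quantile thresholds,
candidate flanking windows, and haplotype-fixation diagnostics.

LSBL isolates the branch length private to a focal group g1 from the three
pairwise per-locus Fst values:

    LSBL(g1) = (Fst(g1,g2) + Fst(g1,g3) - Fst(g2,g3)) / 2

so that LSBL(g1) + LSBL(g2) = Fst(g1,g2) at every locus.  Negative per-locus
Fst inputs are clamped to zero by default so estimator noise does not dominate
the scan's tails.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .fst import fst_weir_cockerham
from .plink import MISSING, GenotypePanel


@dataclass
class ScanResult:
    """Per-locus statistic track with an empirical threshold and hit list."""

    statistic_name: str
    variant_ids: list
    per_locus: np.ndarray
    threshold_value: float
    top_quantile: float | None
    hits: list

    def to_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        df = variants[["chrom", "pos_bp", "id"]].copy()
        df[self.statistic_name] = self.per_locus
        return df


def empirical_threshold(values: np.ndarray, top_quantile: float) -> tuple[float, int]:
    """Top-quantile cut: floor(q*n) hits plus every tie at the threshold.

    Returns (threshold_value, n_hits); the threshold is the smallest included
    value.  NaNs are ignored.  floor(q*n) = 0 yields no hits (threshold NaN).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("empty value vector")
    k = int(np.floor(top_quantile * vals.size))
    if k <= 0:
        return np.nan, 0
    order = np.sort(vals)[::-1]
    threshold = order[k - 1]
    n_hits = int(np.sum(vals >= threshold))
    return float(threshold), n_hits


def _rank_order(panel: GenotypePanel, per_locus: np.ndarray) -> np.ndarray:
    """Descending statistic, ties broken by (chrom, pos)."""
    v = panel.variants
    chrom_key = v["chrom"].to_numpy()
    pos_key = v["pos_bp"].to_numpy()
    neg = -np.nan_to_num(per_locus, nan=-np.inf)
    return np.lexsort((pos_key, chrom_key, neg))


def fst_scan(
    panel: GenotypePanel,
    pair: tuple[str, str],
    group_col: str = "breed",
    top_n: int = 10,
    estimator: str = "weir_cockerham",
) -> ScanResult:
    """Per-locus Fst between two groups, ranked; hits = the top_n variant ids."""
    res = fst_weir_cockerham(panel, pair, group_col, estimator)
    order = _rank_order(panel, res.per_locus)
    defined = order[~np.isnan(res.per_locus[order])]
    top = defined[: min(top_n, defined.size)]
    hits = list(panel.variants["id"].to_numpy()[top])
    threshold = float(res.per_locus[top[-1]]) if top.size else np.nan
    return ScanResult(
        statistic_name="fst",
        variant_ids=list(panel.variants["id"]),
        per_locus=res.per_locus,
        threshold_value=threshold,
        top_quantile=None,
        hits=hits,
    )


def lsbl_values(
    panel: GenotypePanel,
    g1: str,
    g2: str,
    g3: str,
    group_col: str = "breed",
    clamp_negative: bool = True,
    estimator: str = "weir_cockerham",
) -> np.ndarray:
    """Per-locus LSBL for g1 from the three pairwise Fst tracks."""
    f12 = fst_weir_cockerham(panel, (g1, g2), group_col, estimator).per_locus
    f13 = fst_weir_cockerham(panel, (g1, g3), group_col, estimator).per_locus
    f23 = fst_weir_cockerham(panel, (g2, g3), group_col, estimator).per_locus
    if clamp_negative:
        f12, f13, f23 = (np.maximum(f, 0.0) for f in (f12, f13, f23))
    return (f12 + f13 - f23) / 2.0


def lsbl_scan(
    panel: GenotypePanel,
    g1: str,
    g2: str,
    g3: str,
    group_col: str = "breed",
    top_quantile: float = 0.005,
    clamp_negative: bool = True,
    estimator: str = "weir_cockerham",
) -> ScanResult:
    """Three-group LSBL scan for g1 with an empirical top-quantile threshold."""
    per_locus = lsbl_values(panel, g1, g2, g3, group_col, clamp_negative, estimator)
    threshold, _ = empirical_threshold(per_locus, top_quantile)
    ids = panel.variants["id"].to_numpy()
    if np.isnan(threshold):
        hits: list = []
    else:
        mask = np.nan_to_num(per_locus, nan=-np.inf) >= threshold
        order = _rank_order(panel, per_locus)
        hits = [ids[k] for k in order if mask[k]]
    return ScanResult(
        statistic_name="lsbl",
        variant_ids=list(ids),
        per_locus=per_locus,
        threshold_value=threshold,
        top_quantile=top_quantile,
        hits=hits,
    )


# ---------------------------------------------------------------------------
# candidate windows
# ---------------------------------------------------------------------------

@dataclass
class CandidateWindow:
    center_variant: str
    chrom: str
    start_bp: int
    end_bp: int
    flank_bp: int
    overlapping_features: list  # (name, start, end)


def read_features(path) -> pd.DataFrame:
    """BED-like 1-based closed-interval annotation: name, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "chrom", "start", "end"],
                     dtype={"chrom": str})
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def candidate_windows(
    hits: list,
    variants: pd.DataFrame,
    flank_bp: int,
    features: pd.DataFrame,
) -> tuple[list[CandidateWindow], list[str]]:
    """Flanking window per hit plus the deduplicated aggregate feature list.

    Windows are 1-based closed: [max(1, pos - flank), pos + flank]; a feature
    overlaps when any base is shared.  Returns (windows, unique feature names
    in first-seen order).
    """
    vmap = variants.set_index("id")
    windows: list[CandidateWindow] = []
    seen: dict[str, None] = {}
    for hid in hits:
        if hid not in vmap.index:
            warnings.warn(f"hit {hid} has no map position; skipped")
            continue
        rec = vmap.loc[hid]
        pos = int(rec["pos_bp"])
        chrom = str(rec["chrom"])
        start, end = max(1, pos - flank_bp), pos + flank_bp
        sel = features[
            (features["chrom"] == chrom)
            & (features["start"] <= end)
            & (features["end"] >= start)
        ]
        overlaps = [(r["name"], int(r["start"]), int(r["end"])) for _, r in sel.iterrows()]
        for name, *_ in overlaps:
            seen.setdefault(name)
        windows.append(CandidateWindow(hid, chrom, start, end, flank_bp, overlaps))
    return windows, list(seen)


# ---------------------------------------------------------------------------
# haplotype fixation diagnostics
# ---------------------------------------------------------------------------

def _pairwise_r2_matrix(dos: np.ndarray) -> np.ndarray:
    m = dos.shape[1]
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            x, y = dos[:, i], dos[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2:
                continue
            xs, ys = x[ok], y[ok]
            vx, vy = xs.var(), ys.var()
            if vx == 0 or vy == 0:
                continue
            c = np.corrcoef(xs, ys)[0, 1]
            r2[i, j] = r2[j, i] = c * c
    return r2


def haplotype_fixation_check(
    panel: GenotypePanel,
    pair: tuple[str, str],
    chrom: str,
    center_bp: int,
    group_col: str = "breed",
    window_bp: int = 1_000_000,
    r2_floor: float = 0.9,
) -> dict:
    """High-LD SNP subset around a scan hit and per-group genotype fixation.

    Collects the SNPs within ``window_bp`` centered on ``center_bp``, finds the
    largest subset whose pairwise r2 all exceed ``r2_floor`` (max clique on the
    LD graph; leftmost subset on ties), and reports each group's modal
    multi-locus genotype string and its frequency.  Genotype characters:
    the homozygous allele letter, "H" for heterozygotes.
    """
    v = panel.variants
    lo, hi = center_bp - window_bp // 2, center_bp + window_bp // 2
    sel = np.nonzero(
        (v["chrom"].to_numpy() == chrom)
        & (v["pos_bp"].to_numpy() >= lo)
        & (v["pos_bp"].to_numpy() <= hi)
    )[0]
    if sel.size == 0:
        raise ValueError("empty window: no SNPs in range")
    dos = panel.dosages()[:, sel]
    r2 = _pairwise_r2_matrix(dos)

    if sel.size == 1:
        subset = [0]
    else:
        g = nx.Graph()
        g.add_nodes_from(range(sel.size))
        for i in range(sel.size):
            for j in range(i + 1, sel.size):
                if np.isfinite(r2[i, j]) and r2[i, j] >= r2_floor:
                    g.add_edge(i, j)
        cliques = list(nx.find_cliques(g))
        best = max(len(c) for c in cliques)
        subset = sorted(min(sorted(c) for c in cliques if len(c) == best))

    cols = sel[subset]
    ids = list(v["id"].to_numpy()[cols])
    aa = v["allele_a"].to_numpy()[cols]
    ab = v["allele_b"].to_numpy()[cols]

    groups = panel.sample_groups(group_col)
    report = {
        "snp_ids": ids,
        "n_window_snps": int(sel.size),
        "r2_floor": r2_floor,
        "groups": {},
    }
    for label in pair:
        idx = groups[label]
        strings = []
        for i in idx:
            row = panel.genotypes[i, cols]
            if np.any(row == MISSING):
                continue
            chars = [aa[k] if g_ == 0 else ab[k] if g_ == 2 else "H"
                     for k, g_ in enumerate(row)]
            strings.append("".join(chars))
        if strings:
            counts = pd.Series(strings).value_counts()
            major = counts.index[0]
            frac = counts.iloc[0] / len(strings)
        else:
            major, frac = "", np.nan
        report["groups"][label] = {
            "major_genotype": major,
            "fixation_fraction": float(frac),
            "n_complete": len(strings),
        }
    return report


def subsample_group(
    panel: GenotypePanel,
    labels,
    n: int,
    seed: int,
    group_col: str = "breed",
    new_label: str = "SUBSET",
) -> GenotypePanel:
    """Seeded random subsample across one or more labels, relabeled as one group.

    Utility for designs that draw a fixed-size contrast group from several
    breeds; the returned panel contains only the subsample, tagged
    ``new_label`` in ``group_col``.
    """
    idx = panel.group_indices(labels) if group_col == "breed" else np.nonzero(
        panel.samples[group_col].isin([labels] if isinstance(labels, str) else list(labels))
    )[0]
    if n > idx.size:
        raise ValueError("subsample larger than the source groups")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(idx, n, replace=False))
    sub = panel.subset(sample_idx=pick)
    sub.samples = sub.samples.copy()
    sub.samples[group_col] = new_label
    return sub
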