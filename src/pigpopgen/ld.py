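"""Genotype-correlation LD, binned decay curves, the r2 = 0.3 extent, and
LD-based historic effective population size.

r2 is the squared Pearson correlation of allele-B dosages over co-nonmissing
samples (composite LD; no phasing).  Decay uses a fixed distance-bin ladder up
to 1 Mb, and the historic Ne trajectory follows the Sved-lineage relation

    N(t) = (1 / (4 c)) * (1 / E[r2_adj | c] - alpha),    t = 1 / (2 c)

with r2_adj = r2 - 1/(2 n) correcting for sample size, c the recombination
fraction of a distance bin (Haldane map at a constant cM/Mb), and alpha a
mutation/model constant (default 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plink import GenotypePanel

#: Distance-bin ladder (kb) used for decay curves and the Ne trajectory.
BIN_EDGES_KB = (0, 1, 3, 6, 9, 15, 30, 40, 60, 80, 100, 150,
                200, 250, 300, 500, 800, 1000)

LD_PAIR_COLUMNS = ["chrom", "id_a", "id_b", "pos_a", "pos_b", "dist_bp", "r2"]


def pairwise_r2(
    panel: GenotypePanel,
    max_dist_kb: int = 1000,
    max_snp_window: int = 9999,
) -> pd.DataFrame:
    """All intra-chromosome dosage-r2 pairs within the distance and index caps.

    Mirrors the windowing of ``--r2 --ld-window 9999 --ld-window-r2 0
    --ld-window-kb 1000``.  Pairs where either member is monomorphic over the
    co-nonmissing samples are skipped.
    """
    v = panel.variants
    order = np.lexsort((v["pos_bp"].to_numpy(), v["chrom"].to_numpy()))
    d = panel.dosages()[:, order]
    chrom = v["chrom"].to_numpy()[order]
    pos = v["pos_bp"].to_numpy()[order]
    ids = v["id"].to_numpy()[order]
    max_dist_bp = max_dist_kb * 1000

    rows = []
    m = len(ids)
    valid = ~np.isnan(d)
    for j in range(m - 1):
        hi = j + 1
        while (
            hi < m
            and chrom[hi] == chrom[j]
            and pos[hi] - pos[j] <= max_dist_bp
            and hi - j <= max_snp_window
        ):
            hi += 1
        if hi == j + 1:
            continue
        x = d[:, j]
        y = d[:, j + 1:hi]
        both = valid[:, j][:, None] & valid[:, j + 1:hi]
        n = both.sum(axis=0).astype(float)
        xm = np.where(both, x[:, None], 0.0)
        ym = np.where(both, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = xm.sum(axis=0)
            sy = ym.sum(axis=0)
            sxx = (xm * xm).sum(axis=0)
            syy = (ym * ym).sum(axis=0)
            sxy = (xm * ym).sum(axis=0)
            cov = sxy - sx * sy / n
            vx = sxx - sx**2 / n
            vy = syy - sy**2 / n
            r2 = cov**2 / (vx * vy)
        for k in range(j + 1, hi):
            kk = k - (j + 1)
            if n[kk] < 2 or not np.isfinite(r2[kk]):
                continue  # monomorphic in the co-called subset, or no overlap
            rows.append(
                (chrom[j], ids[j], ids[k], int(pos[j]), int(pos[k]),
                 int(pos[k] - pos[j]), float(r2[kk]))
            )
    return pd.DataFrame(rows, columns=LD_PAIR_COLUMNS)


@dataclass
class LDDecayCurve:
    """Mean r2 per distance bin plus the r2 = 0.3 extent."""

    bin_edges_kb: tuple
    midpoints_kb: np.ndarray
    mean_r2: np.ndarray          # NaN for empty bins
    n_pairs: np.ndarray
    extent_kb: float             # np.inf when censored
    censored: bool
    mode: str

    @property
    def extent_label(self) -> str:
        return ">1000" if self.censored else f"{self.extent_kb:.2f}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_kb": self.bin_edges_kb[:-1],
                "bin_high_kb": self.bin_edges_kb[1:],
                "midpoint_kb": self.midpoints_kb,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def ld_decay_curve(
    pairs: pd.DataFrame,
    per_chrom_average: bool = True,
    threshold: float = 0.3,
    mode: str = "interpolated",
) -> LDDecayCurve:
    """Bin pairs on the fixed kb ladder and locate the decay extent.

    ``mode="interpolated"`` (default) reports the first linear-interpolation
    crossing of ``threshold`` between consecutive non-empty bin midpoints;
    if the curve is already below the threshold at the first non-empty
    midpoint the extent is the ladder floor (0 kb).  ``mode="midpoint"``
    reports the midpoint of the first non-empty bin whose mean is below the
    threshold.  If the curve never drops below the threshold the extent is
    censored at the ladder's end (">1000").
    """
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    if mode not in ("interpolated", "midpoint"):
        raise ValueError("mode must be 'interpolated' or 'midpoint'")
    edges = np.asarray(BIN_EDGES_KB, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    dist_kb = pairs["dist_bp"].to_numpy() / 1000.0
    # (low, high] assignment
    bin_idx = np.searchsorted(edges, dist_kb, side="left") - 1
    ok = (bin_idx >= 0) & (bin_idx < len(mids)) & (dist_kb > edges[0])
    pairs = pairs.loc[ok].assign(_bin=bin_idx[ok])

    nbins = len(mids)
    n_pairs = np.zeros(nbins, dtype=int)
    mean_r2 = np.full(nbins, np.nan)
    if per_chrom_average:
        per = pairs.groupby(["chrom", "_bin"])["r2"].mean().reset_index()
        g = per.groupby("_bin")["r2"].mean()
    else:
        g = pairs.groupby("_bin")["r2"].mean()
    counts = pairs.groupby("_bin")["r2"].size()
    for b, val in g.items():
        mean_r2[b] = val
    for b, cnt in counts.items():
        n_pairs[b] = cnt

    filled = ~np.isnan(mean_r2)
    xs, ys = mids[filled], mean_r2[filled]
    extent, censored = np.inf, True
    if xs.size:
        if mode == "midpoint":
            below = ys < threshold
            if below.any():
                extent, censored = float(xs[below.argmax()]), False
        else:
            if ys[0] < threshold:
                extent, censored = 0.0, False
            else:
                for k in range(1, len(xs)):
                    if ys[k] < threshold <= ys[k - 1]:
                        frac = (ys[k - 1] - threshold) / (ys[k - 1] - ys[k])
                        extent = float(xs[k - 1] + frac * (xs[k] - xs[k - 1]))
                        censored = False
                        break
    return LDDecayCurve(
        bin_edges_kb=BIN_EDGES_KB,
        midpoints_kb=mids,
        mean_r2=mean_r2,
        n_pairs=n_pairs,
        extent_kb=extent,
        censored=censored,
        mode=mode,
    )


def haldane_c(dist_bp: np.ndarray, cm_per_mb: float = 1.0) -> np.ndarray:
    """Recombination fraction from physical distance via the Haldane map."""
    morgans = np.asarray(dist_bp, dtype=float) * 1e-6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


NE_COLUMNS = ["generations_ago", "ne", "c", "mean_r2_adj", "n_pairs"]


def ne_from_ld(
    pairs: pd.DataFrame,
    sample_n: int,
    alpha: float = 1.0,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Historic Ne trajectory from distance-binned LD.

    Pairs are grouped on the decay ladder; each bin's recombination fraction c
    comes from the bin-midpoint distance, dating the estimate to
    t = 1/(2c) generations ago.  Bins whose adjusted mean r2 makes the Ne
    formula non-positive are dropped.  Sorted by generations ascending
    (most recent first = largest distances).
    """
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    edges = np.asarray(BIN_EDGES_KB, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    dist_kb = pairs["dist_bp"].to_numpy() / 1000.0
    bin_idx = np.searchsorted(edges, dist_kb, side="left") - 1
    ok = (bin_idx >= 0) & (bin_idx < len(mids)) & (dist_kb > edges[0])
    r2_adj = pairs["r2"].to_numpy() - 1.0 / (2.0 * sample_n)

    rows = []
    for b in range(len(mids)):
        sel = ok & (bin_idx == b)
        if not sel.any():
            continue
        e_r2 = float(r2_adj[sel].mean())
        c = float(haldane_c(mids[b] * 1000.0, cm_per_mb))
        if e_r2 <= 0:
            continue
        ne = (1.0 / e_r2 - alpha) / (4.0 * c)
        if ne <= 0:
            continue  # complete LD or r2 floor: non-positive Ne, point dropped
        rows.append((1.0 / (2.0 * c), ne, c, e_r2, int(sel.sum())))
    df = pd.DataFrame(rows, columns=NE_COLUMNS)
    return df.sort_values("generations_ago").reset_index(drop=True)
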