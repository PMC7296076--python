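"""Conservation-farm subfamily classification: NJ-guided maximal split followed
by criterion-driven merging.

The procedure mirrors breeding practice for in-situ conservation herds:

1. **Initial split** — leaves of the farm's NJ tree are walked in tree order
   and consecutive individuals are joined into one subfamily only when their
   allele-sharing distance falls below a threshold derived from the
   population's distance distribution (default: mean - 2 SD), producing the
   finest defensible partition.
2. **Merging** — pairs of subfamilies that are insufficiently differentiated
   (pairwise Fst below a floor, default 0.05) or closest in mean distance are
   merged iteratively until every pairwise Fst exceeds the floor AND the
   coefficient of variation of between-subfamily mean distances is below a
   ceiling (default 10%), i.e. the farm's genetic resource is evenly spread
   over moderately differentiated subfamilies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .fst import weir_cockerham_components
from .plink import GenotypePanel
from .tree import PhyloTree

logger = logging.getLogger(__name__)

THRESHOLD_RULES = ("mean_minus_sd", "within_sd_band")


@dataclass
class SubfamilyDiagnostics:
    cv_pairwise_distance_percent: float
    min_pairwise_fst: float
    mean_pairwise_distance: float


@dataclass
class SubfamilyPartition:
    """Individual -> subfamily assignment with merge history and diagnostics."""

    assignment: dict            # sample_id -> subfamily index (0-based)
    n_subfamilies: int
    diagnostics: SubfamilyDiagnostics | None = None
    history: list = field(default_factory=list)  # (kept, absorbed, reason)
    success: bool = False

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, k in self.assignment.items():
            out.setdefault(k, []).append(sid)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.assignment), "subfamily": list(self.assignment.values())}
        )


def _leaf_order(tree: PhyloTree) -> list[str]:
    return tree.leaf_names()


def initial_partition(
    tree: PhyloTree,
    dist: DistanceMatrix,
    sd_factor: float = 2.0,
    threshold_rule: str = "mean_minus_sd",
) -> SubfamilyPartition:
    """Finest split: join tree-adjacent individuals only when clearly related.

    ``threshold_rule="mean_minus_sd"`` (default) joins consecutive tree leaves
    whose distance is below mean - sd_factor*SD of all pairwise distances; a
    non-positive threshold makes every individual a singleton (valid, logged).
    ``"within_sd_band"`` instead joins pairs within sd_factor*SD of the mean
    on the low side or closer (distance < mean), the permissive reading.
    """
    if threshold_rule not in THRESHOLD_RULES:
        raise ValueError(f"threshold_rule must be one of {THRESHOLD_RULES}")
    leaves = _leaf_order(tree)
    if set(leaves) != set(dist.ids):
        raise ValueError("tree leaves do not match distance-matrix ids")
    tri = dist.upper_triangle()
    mean, sd = float(np.mean(tri)), float(np.std(tri))
    if threshold_rule == "mean_minus_sd":
        tau = mean - sd_factor * sd
    else:
        tau = mean  # join anything on the near side of the mean within the band
    if tau <= 0:
        logger.info("adjacency threshold %.4f <= 0: all singletons", tau)

    parent = list(range(len(leaves)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(len(leaves) - 1):
        a, b = leaves[k], leaves[k + 1]
        d_ab = dist.lookup(a, b)
        if threshold_rule == "within_sd_band":
            join = abs(d_ab - mean) < sd_factor * sd and d_ab < mean
        else:
            join = d_ab < tau
        if join:
            parent[find(k)] = find(k + 1)

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for k, leaf in enumerate(leaves):
        root = find(k)
        if root not in roots:
            roots[root] = len(roots)
        assignment[leaf] = roots[root]
    return SubfamilyPartition(assignment=assignment, n_subfamilies=len(roots))


def _pair_stats(
    panel: GenotypePanel, dist: DistanceMatrix, members: dict[int, list[str]]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """(between-mean-distance matrix, pairwise-Fst matrix, subfamily keys)."""
    keys = sorted(members)
    pos = {sid: i for i, sid in enumerate(dist.ids)}
    row_of = {sid: i for i, sid in enumerate(panel.samples["sample_id"])}
    k = len(keys)
    dmat = np.full((k, k), np.nan)
    fmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            ia = [pos[s] for s in members[keys[i]]]
            ib = [pos[s] for s in members[keys[j]]]
            dmat[i, j] = dmat[j, i] = dist.values[np.ix_(ia, ib)].mean()
            ga = panel.genotypes[[row_of[s] for s in members[keys[i]]]]
            gb = panel.genotypes[[row_of[s] for s in members[keys[j]]]]
            if ga.shape[0] >= 2 and gb.shape[0] >= 2:
                a, b, c = weir_cockerham_components(ga, gb)
                denom = a + b + c
                ok = ~np.isnan(denom) & (denom != 0)
                if ok.any():
                    fmat[i, j] = fmat[j, i] = np.nansum(a[ok]) / np.nansum(denom[ok])
    return dmat, fmat, keys


def _diagnostics(dmat: np.ndarray, fmat: np.ndarray) -> SubfamilyDiagnostics:
    iu = np.triu_indices(dmat.shape[0], k=1)
    dists = dmat[iu]
    fsts = fmat[iu]
    mean_d = float(np.nanmean(dists)) if dists.size else np.nan
    cv = (
        100.0 * float(np.nanstd(dists)) / mean_d
        if dists.size and mean_d and not np.isnan(mean_d)
        else np.nan
    )
    min_f = float(np.nanmin(fsts)) if fsts.size and not np.all(np.isnan(fsts)) else np.nan
    return SubfamilyDiagnostics(
        cv_pairwise_distance_percent=cv,
        min_pairwise_fst=min_f,
        mean_pairwise_distance=mean_d,
    )


def _criteria_met(dmat, fmat, cv_threshold, fst_floor) -> bool:
    iu = np.triu_indices(dmat.shape[0], k=1)
    fsts = fmat[iu]
    if fsts.size == 0:
        return False
    if np.any(np.isnan(fsts)) or np.nanmin(fsts) <= fst_floor:
        return False  # undefined Fst (singleton subfamily) cannot certify the floor
    diag = _diagnostics(dmat, fmat)
    return diag.cv_pairwise_distance_percent < cv_threshold


def merge_subfamilies(
    partition: SubfamilyPartition,
    panel: GenotypePanel,
    dist: DistanceMatrix,
    cv_threshold_percent: float = 10.0,
    fst_floor: float = 0.05,
) -> SubfamilyPartition:
    """Iteratively merge under-differentiated subfamilies until the farm rules hold.

    Merge priority: among pairs violating the Fst floor (undefined Fst counts
    as a violation), the lowest Fst — NaN ordered first by smallest mean
    between distance; otherwise the pair with the smallest mean between
    distance.  Ties break on the lexicographically smallest index pair.  Stops
    with ``success=True`` when min pairwise Fst > floor and the CV of
    between-subfamily mean distances is under the ceiling, or with
    ``success=False`` at 2 subfamilies if the criteria remain unsatisfiable.
    """
    assignment = dict(partition.assignment)
    history = list(partition.history)
    members = SubfamilyPartition(assignment, partition.n_subfamilies).members()

    while True:
        dmat, fmat, keys = _pair_stats(panel, dist, members)
        if len(keys) < 2:
            diag = _diagnostics(dmat, fmat)
            return SubfamilyPartition(
                assignment, len(keys), diag, history, success=False
            )
        if _criteria_met(dmat, fmat, cv_threshold_percent, fst_floor):
            return SubfamilyPartition(
                assignment, len(keys), _diagnostics(dmat, fmat), history, success=True
            )
        if len(keys) == 2:
            return SubfamilyPartition(
                assignment, 2, _diagnostics(dmat, fmat), history, success=False
            )

        iu = list(zip(*np.triu_indices(len(keys), k=1)))
        violating = [
            (i, j) for i, j in iu
            if np.isnan(fmat[i, j]) or fmat[i, j] <= fst_floor
        ]
        if violating:
            # lowest Fst first; undefined (NaN) first, ordered by distance
            best = min(
                violating,
                key=lambda ij: (
                    not np.isnan(fmat[ij]),
                    fmat[ij] if not np.isnan(fmat[ij]) else dmat[ij],
                    dmat[ij],
                    ij,
                ),
            )
            reason = "fst_floor"
        else:
            best = min(iu, key=lambda ij: (dmat[ij], ij))
            reason = "distance"
        i, j = best
        keep, absorb = keys[i], keys[j]
        for sid in members[absorb]:
            assignment[sid] = keep
        members[keep] = members[keep] + members.pop(absorb)
        history.append((keep, absorb, reason))


def classify_farm(
    panel: GenotypePanel,
    dist: DistanceMatrix,
    tree: PhyloTree,
    sd_factor: float = 2.0,
    cv_threshold_percent: float = 10.0,
    fst_floor: float = 0.05,
    threshold_rule: str = "mean_minus_sd",
) -> SubfamilyPartition:
    """Full pipeline: initial maximal split, then criterion-driven merging.

    The final partition is renumbered 0..k-1 in order of first appearance
    along the tree's leaf order.
    """
    part = initial_partition(tree, dist, sd_factor, threshold_rule)
    merged = merge_subfamilies(part, panel, dist, cv_threshold_percent, fst_floor)
    remap: dict[int, int] = {}
    for leaf in tree.leaf_names():
        k = merged.assignment[leaf]
        if k not in remap:
            remap[k] = len(remap)
    merged.assignment = {sid: remap[k] for sid, k in merged.assignment.items()}
    merged.history = [
        (remap.get(a, a), b, r) for a, b, r in merged.history
    ]
    return merged


def subfamily_report(partition: SubfamilyPartition, boar_flags: dict) -> pd.DataFrame:
    """Per-subfamily size and boar count, plus farm totals in ``.attrs``.

    ``boar_flags`` maps every sample_id to True for boars; the attrs carry
    ``n_subfamilies`` and ``n_subfamilies_with_boars``, the statistics a
    conservation-farm audit reports.
    """
    missing = [s for s in partition.assignment if s not in boar_flags]
    if missing:
        raise ValueError(f"boar_flags missing for {missing[:5]}")
    rows = []
    for k, mem in sorted(partition.members().items()):
        boars = sum(bool(boar_flags[s]) for s in mem)
        rows.append((k, len(mem), boars))
    df = pd.DataFrame(rows, columns=["subfamily", "size", "n_boars"])
    df.attrs["n_subfamilies"] = partition.n_subfamilies
    df.attrs["n_subfamilies_with_boars"] = int((df["n_boars"] > 0).sum())
    return df
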