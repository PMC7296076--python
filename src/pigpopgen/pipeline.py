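"""Stage orchestration: run the full analysis from a flat key=value config.

Stages: qc -> diversity -> dist/tree -> fst -> ld/ne, plus optional f3, scans
and subfamily classification.  Every run writes a ``manifest.json`` recording
input hashes, the effective parameters and each stage's status, so outputs
are auditable and byte-reproducible under a fixed seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity, f3, fst, ld, plink, scan, subfamily, tree
from .distance import allele_sharing_distance, breed_average_distance, pca_coordinates

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "bed", "bim", "fam", "ped", "map", "metadata",
    "out_dir", "seed",
    "run_qc", "min_sample_call", "min_variant_call", "min_maf", "autosomes_only",
    "group_col", "stages",
    "freq_reference", "bias_correct",
    "ld_max_dist_kb", "ld_max_snp_window", "ne_alpha", "ne_cm_per_mb", "ld_group",
    "f3_target", "f3_source_a", "f3_source_b", "f3_block_snps",
    "scan_pair", "scan_top_n", "lsbl_groups", "lsbl_top_quantile",
    "subfamily_farm", "subfamily_sd_factor", "subfamily_cv_percent", "subfamily_fst_floor",
    "bootstrap_reps",
}

_ALL_STAGES = ("qc", "diversity", "dist", "tree", "fst", "ld", "ne",
               "f3", "scan_fst", "scan_lsbl", "subfamily")
_DEFAULT_STAGES = ("qc", "diversity", "dist", "tree", "fst", "ld", "ne")

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class RunConfig:
    """Parsed flat key=value run configuration."""

    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {ln}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _KNOWN_KEYS:
                raise ValueError(f"{path}: line {ln}: unknown config key {key!r}")
            raw[key] = val
        return cls(raw=raw)

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def get_float(self, key, default):
        return float(self.raw.get(key, default))

    def get_int(self, key, default):
        return int(self.raw.get(key, default))

    def get_bool(self, key, default):
        v = self.raw.get(key)
        return default if v is None else _BOOL[v.lower()]

    def stages(self) -> list[str]:
        v = self.raw.get("stages")
        if v is None:
            return list(_DEFAULT_STAGES)
        names = [s.strip() for s in v.split(",") if s.strip()]
        bad = [s for s in names if s not in _ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        return names


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_panel(cfg: RunConfig) -> tuple[plink.GenotypePanel, dict]:
    meta = cfg.get("metadata")
    hashes = {}
    if cfg.get("bed"):
        paths = {k: cfg.get(k) for k in ("bed", "bim", "fam")}
        panel = plink.read_plink_binary(paths["bed"], paths["bim"], paths["fam"], meta)
    elif cfg.get("ped"):
        paths = {k: cfg.get(k) for k in ("ped", "map")}
        panel = plink.read_plink_text(paths["ped"], paths["map"], meta)
    else:
        raise ValueError("config must name either bed/bim/fam or ped/map inputs")
    for k, p in paths.items():
        hashes[k] = _sha256(p)
    if meta:
        hashes["metadata"] = _sha256(meta)
    return panel, hashes


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out_dir = Path(cfg.get("out_dir", "pigpopgen_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pigpopgen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stages = cfg.stages()
    seed = cfg.get_int("seed", 0)
    group_col = cfg.get("group_col", "breed")
    manifest: dict = {"config": dict(cfg.raw), "stages": {}, "inputs": {}}
    root.info("effective config: %s", json.dumps(cfg.raw, sort_keys=True))

    panel, hashes = _load_panel(cfg)
    manifest["inputs"] = hashes

    try:
        for name in _ALL_STAGES:
            if name not in stages:
                manifest["stages"][name] = "skipped"
                continue
            root.info("stage %s start", name)
            if name == "qc":
                panel, report = plink.apply_qc(
                    panel,
                    cfg.get_float("min_sample_call", 0.9),
                    cfg.get_float("min_variant_call", 0.9),
                    cfg.get_float("min_maf", 0.05),
                    cfg.get_bool("autosomes_only", True),
                )
                (out_dir / "qc_report.json").write_text(json.dumps({
                    "n_samples_in": report.n_samples_in,
                    "n_samples_out": report.n_samples_out,
                    "n_variants_in": report.n_variants_in,
                    "n_variants_out": report.n_variants_out,
                    "removed_samples": report.removed_samples,
                    "removed_variants": report.removed_variants,
                    "thresholds": report.thresholds,
                }, indent=1))
            elif name == "diversity":
                table = diversity.breed_diversity(
                    panel, group_col,
                    freq_reference=cfg.get("freq_reference", "pooled_panel"),
                    bias_correct=cfg.get_bool("bias_correct", True),
                )
                table.to_csv(out_dir / "diversity.tsv", sep="\t")
            elif name == "dist":
                dist = allele_sharing_distance(panel)
                dist.write(out_dir / "distance_1mDst.tsv")
                labels = dict(zip(panel.samples["sample_id"], panel.samples[group_col]))
                breed_average_distance(dist, labels).write(out_dir / "distance_breed_avg.tsv")
                coords, frac = pca_coordinates(panel, min(4, panel.n_samples - 1))
                coords.to_csv(out_dir / "pca.tsv", sep="\t")
                np.savetxt(out_dir / "pca_variance_fractions.tsv", frac)
            elif name == "tree":
                reps = cfg.get_int("bootstrap_reps", 0)
                if reps > 0:
                    t = tree.bootstrap_nj(panel, reps, seed)
                    (out_dir / "nj_tree.nwk").write_text(t.newick(include_support=True) + "\n")
                else:
                    t = tree.neighbor_joining(allele_sharing_distance(panel))
                    (out_dir / "nj_tree.nwk").write_text(t.newick() + "\n")
            elif name == "fst":
                mat = fst.pairwise_fst_matrix(panel, group_col)
                mat.write(out_dir / "fst_matrix.tsv")
                bands = {a: {b: fst.classify_fst(mat.lookup(a, b))
                             for b in mat.ids if b != a} for a in mat.ids}
                (out_dir / "fst_bands.json").write_text(json.dumps(bands, indent=1))
            elif name in ("ld", "ne"):
                group = cfg.get("ld_group")
                sub = panel if group is None else panel.subset(panel.group_indices(group))
                pairs = ld.pairwise_r2(
                    sub,
                    cfg.get_int("ld_max_dist_kb", 1000),
                    cfg.get_int("ld_max_snp_window", 9999),
                )
                if name == "ld":
                    pairs.to_csv(out_dir / "ld_pairs.tsv", sep="\t", index=False)
                    curve = ld.ld_decay_curve(pairs)
                    curve.to_frame().to_csv(out_dir / "ld_decay.tsv", sep="\t", index=False)
                    (out_dir / "ld_extent.txt").write_text(curve.extent_label + "\n")
                else:
                    traj = ld.ne_from_ld(
                        pairs, sub.n_samples,
                        cfg.get_float("ne_alpha", 1.0),
                        cfg.get_float("ne_cm_per_mb", 1.0),
                    )
                    traj.to_csv(out_dir / "ne_trajectory.tsv", sep="\t", index=False)
            elif name == "f3":
                res = f3.block_jackknife_z(
                    panel, cfg.get("f3_target"), cfg.get("f3_source_a"),
                    cfg.get("f3_source_b"), group_col,
                    cfg.get_int("f3_block_snps", 200),
                )
                with open(out_dir / "f3.tsv", "w") as fh:
                    fh.write("target\tsource_a\tsource_b\tf3\tse\tz\tsignificant\n")
                    fh.write(f"{res.target}\t{res.source_a}\t{res.source_b}\t"
                             f"{res.f3:.6g}\t{res.se:.6g}\t{res.z:.4f}\t{res.significant}\n")
            elif name == "scan_fst":
                pair = tuple(cfg.get("scan_pair").split(","))
                res = scan.fst_scan(panel, pair, group_col, cfg.get_int("scan_top_n", 10))
                res.to_frame(panel.variants).to_csv(out_dir / "scan_fst.tsv", sep="\t", index=False)
                (out_dir / "scan_fst_hits.txt").write_text("\n".join(res.hits) + "\n")
            elif name == "scan_lsbl":
                g1, g2, g3 = cfg.get("lsbl_groups").split(",")
                res = scan.lsbl_scan(panel, g1, g2, g3, group_col,
                                     cfg.get_float("lsbl_top_quantile", 0.005))
                res.to_frame(panel.variants).to_csv(out_dir / "scan_lsbl.tsv", sep="\t", index=False)
                (out_dir / "scan_lsbl_hits.txt").write_text("\n".join(res.hits) + "\n")
            elif name == "subfamily":
                farm = cfg.get("subfamily_farm")
                sub = panel if farm is None else panel.subset(
                    np.nonzero((panel.samples["farm"] == farm)
                               | (panel.samples[group_col] == farm))[0])
                dist = allele_sharing_distance(sub)
                t = tree.neighbor_joining(dist)
                part = subfamily.classify_farm(
                    sub, dist, t,
                    cfg.get_float("subfamily_sd_factor", 2.0),
                    cfg.get_float("subfamily_cv_percent", 10.0),
                    cfg.get_float("subfamily_fst_floor", 0.05),
                )
                part.to_frame().to_csv(out_dir / "subfamilies.tsv", sep="\t", index=False)
                (out_dir / "subfamily_history.tsv").write_text(
                    "\n".join(f"{a}\t{b}\t{r}" for a, b, r in part.history) + "\n")
            manifest["stages"][name] = "done"
            root.info("stage %s done", name)
    except Exception as exc:
        root.error("stage failed: %s", exc)
        raise
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        root.removeHandler(handler)
        handler.close()
    return out_dir
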