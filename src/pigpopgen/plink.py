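"""PLINK-format genotype I/O, the in-memory panel, QC filtering and panel merging.

The central container is :class:`GenotypePanel`: a samples x variants matrix of
allele-B dosages (0/1/2, ``MISSING`` = -1) with a variant map and per-sample
breed/farm metadata.  Both the PLINK 1 text format (.ped/.map) and the SNP-major
binary format (.bed/.bim/.fam) are supported bit-exactly on the genotype codes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING = np.int8(-1)

#: Pig autosome labels (SSC1..SSC18); everything else is dropped by QC.
AUTOSOMES = frozenset(str(i) for i in range(1, 19))

_VALID_ALLELES = frozenset("ACGT012")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

VARIANT_COLUMNS = ["id", "chrom", "pos_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "breed", "farm"]


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK input (ragged rows, bad magic, size mismatch)."""


@dataclass
class GenotypePanel:
    """Diploid biallelic SNP genotypes plus sample and variant metadata.

    Parameters
    ----------
    samples
        DataFrame with at least ``sample_id``, ``breed``, ``farm`` columns;
        one row per individual, order matching genotype rows.
    variants
        DataFrame with ``id``, ``chrom``, ``pos_bp``, ``allele_a``,
        ``allele_b`` columns, order matching genotype columns.
    genotypes
        ``int8`` array of shape (n_samples, n_variants); entries count copies
        of ``allele_b`` (0, 1 or 2) with ``MISSING`` (-1) for no-calls.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in panel")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant id in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """Genotypes as float64 with missing calls as NaN."""
        d = self.genotypes.astype(np.float64)
        d[self.genotypes == MISSING] = np.nan
        return d

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypePanel":
        """Return a new panel restricted to the given positional indices."""
        def _index(idx, n):
            if idx is None:
                return np.arange(n)
            arr = np.asarray(idx)
            if arr.dtype == bool:
                return np.nonzero(arr)[0]
            return arr.astype(np.intp)

        si = _index(sample_idx, self.n_samples)
        vi = _index(variant_idx, self.n_variants)
        return GenotypePanel(
            self.samples.iloc[si].reset_index(drop=True),
            self.variants.iloc[vi].reset_index(drop=True),
            self.genotypes[np.ix_(si, vi)],
        )

    def sample_groups(self, column: str = "breed") -> dict[str, np.ndarray]:
        """Map each label in ``samples[column]`` to its row indices."""
        out: dict[str, np.ndarray] = {}
        for label, grp in self.samples.groupby(column, sort=False):
            out[str(label)] = grp.index.to_numpy()
        return out

    def group_indices(self, labels) -> np.ndarray:
        """Row indices of samples whose breed is in ``labels`` (str or iterable)."""
        if isinstance(labels, str):
            labels = [labels]
        mask = self.samples["breed"].isin(list(labels)).to_numpy()
        return np.nonzero(mask)[0]

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            list(self.samples["sample_id"]) == list(other.samples["sample_id"])
            and list(self.variants["id"]) == list(other.variants["id"])
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class QCReport:
    """Bookkeeping of a QC pass; input minus removals equals output on both axes."""

    n_samples_in: int
    n_samples_out: int
    n_variants_in: int
    n_variants_out: int
    removed_samples: list = field(default_factory=list)  # (sample_id, reason)
    removed_variants: list = field(default_factory=list)  # (variant_id, reason)
    thresholds: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_samples_in - len(self.removed_samples) == self.n_samples_out
        assert self.n_variants_in - len(self.removed_variants) == self.n_variants_out


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------

def _apply_metadata(samples: pd.DataFrame, metadata_path) -> pd.DataFrame:
    """Overlay a tab-separated sidecar (sample_id, breed, farm) onto sample metadata."""
    if metadata_path is None:
        return samples
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata sidecar must have a sample_id column")
    meta = meta.set_index("sample_id")
    samples = samples.copy()
    for col in ("breed", "farm"):
        if col in meta.columns:
            mapped = samples["sample_id"].map(meta[col])
            samples[col] = mapped.fillna(samples[col])
    return samples


# ---------------------------------------------------------------------------
# text format (.ped/.map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, metadata_path=None) -> GenotypePanel:
    """Read a PLINK .ped/.map pair.

    The .map has no allele columns, so allele_a/allele_b are assigned
    lexicographically from the observed symbols (monomorphic variants get
    allele_a = "0").  Dosages count copies of allele_b; any "0" in an allele
    pair makes the call MISSING.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts
            map_rows.append((vid, chrom, int(pos)))
    m = len(map_rows)

    sample_rows = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            alleles = parts[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise PlinkFormatError(f"{ped_path}: line {ln}: invalid allele symbol {a!r}")
            sample_rows.append((iid, fid, ""))
            allele_pairs.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)])

    n = len(sample_rows)
    # assign allele_a/allele_b per variant (lexicographic among observed, "0" excluded)
    var_records = []
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        observed = sorted(
            {a for pairs in allele_pairs for a in pairs[j] if a != "0"}
        )
        if len(observed) > 2:
            raise PlinkFormatError(f"variant {map_rows[j][0]}: more than two alleles {observed}")
        if len(observed) == 2:
            allele_a, allele_b = observed
        elif len(observed) == 1:
            allele_a, allele_b = "0", observed[0]
        else:
            allele_a, allele_b = "0", "0"
        vid, chrom, pos = map_rows[j]
        var_records.append((vid, chrom, pos, allele_a, allele_b))
        for i in range(n):
            a1, a2 = allele_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            geno[i, j] = (a1 == allele_b) + (a2 == allele_b)

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    variants = pd.DataFrame(var_records, columns=VARIANT_COLUMNS)
    samples = _apply_metadata(samples, metadata_path)
    return GenotypePanel(samples, variants, geno)


def write_plink_text(panel: GenotypePanel, prefix) -> tuple[Path, Path]:
    """Write a .ped/.map pair.

    Note the text format does not record allele order; a read-back reassigns
    alleles lexicographically, so round-trip identity of the codes holds when
    allele_a < allele_b (as produced by :func:`read_plink_text`).
    """
    prefix = Path(prefix)
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise ValueError("refusing to write an empty panel")
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for rec in panel.variants.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos_bp}\n")
    aa = panel.variants["allele_a"].to_numpy()
    ab = panel.variants["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, srec in enumerate(panel.samples.itertuples(index=False)):
            fields = [srec.breed or "0", srec.sample_id, "0", "0", "0", "-9"]
            row = panel.genotypes[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [aa[j], aa[j]]
                elif g == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# binary format (.bed/.bim/.fam), SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 = hom allele_a (dosage 0), 01 = missing,
# 10 = het, 11 = hom allele_b (dosage 2)
_BITS_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CODE_TO_BITS = {0: 0b00, 1: 0b10, 2: 0b11, int(MISSING): 0b01}


def read_plink_binary(bed_path, bim_path, fam_path, metadata_path=None) -> GenotypePanel:
    """Read a SNP-major PLINK .bed/.bim/.fam trio."""
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos_bp", "allele_a", "allele_b"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not SNP-major PLINK .bed)")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise PlinkFormatError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{m} variants x {bytes_per_variant} bytes"
        )
    blocks = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit fields, sample i in bits (2*(i%4), 2*(i%4)+1)
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = _BITS_TO_CODE[two_bit.reshape(m, -1)[:, :n]]
    geno = np.ascontiguousarray(codes.T)

    samples = pd.DataFrame(
        {"sample_id": fam["iid"], "breed": fam["fid"], "farm": ""}
    )
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos_bp": bim["pos_bp"].astype(int),
            "allele_a": bim["allele_a"],
            "allele_b": bim["allele_b"],
        }
    )
    samples = _apply_metadata(samples, metadata_path)
    return GenotypePanel(samples, variants, geno)


def write_plink_binary(panel: GenotypePanel, prefix) -> tuple[Path, Path, Path]:
    """Write a SNP-major .bed/.bim/.fam trio readable by :func:`read_plink_binary`."""
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise ValueError("refusing to write an empty panel")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(fam_path, "w") as fh:
        for rec in panel.samples.itertuples(index=False):
            fh.write(f"{rec.breed or '0'}\t{rec.sample_id}\t0\t0\t0\t-9\n")
    with open(bim_path, "w") as fh:
        for rec in panel.variants.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos_bp}\t{rec.allele_a}\t{rec.allele_b}\n")

    n, m = panel.n_samples, panel.n_variants
    bits = np.empty((m, n), dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        bits[panel.genotypes.T == code] = b
    pad = (-n) % 4
    if pad:
        bits = np.concatenate([bits, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    quads = bits.reshape(m, -1, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (quads << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def minor_allele_frequency(geno: np.ndarray) -> np.ndarray:
    """Per-variant MAF over non-missing calls; NaN where nothing is called."""
    called = geno != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, geno, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    return maf


def apply_qc(
    panel: GenotypePanel,
    min_sample_call: float = 0.9,
    min_variant_call: float = 0.9,
    min_maf: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypePanel, QCReport]:
    """Single-pass QC: sample call rate, then variant call rate, MAF, chromosome.

    Call-rate thresholds are strict (keep strictly greater); the MAF threshold
    keeps variants with MAF >= ``min_maf`` (removal only when MAF is strictly
    below), matching the dominant ``--maf`` tool convention.
    """
    for t in (min_sample_call, min_variant_call, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must be in [0, 1]")
    report = QCReport(
        n_samples_in=panel.n_samples,
        n_samples_out=0,
        n_variants_in=panel.n_variants,
        n_variants_out=0,
        thresholds={
            "min_sample_call": min_sample_call,
            "min_variant_call": min_variant_call,
            "min_maf": min_maf,
            "autosomes_only": autosomes_only,
        },
    )
    geno = panel.genotypes
    called = geno != MISSING

    # 1. sample call rate
    if panel.n_variants > 0:
        sample_rate = called.mean(axis=1)
    else:
        sample_rate = np.ones(panel.n_samples)
    keep_s = sample_rate > min_sample_call
    for sid in panel.samples.loc[~keep_s, "sample_id"]:
        report.removed_samples.append((sid, "call_rate"))
    if not keep_s.any():
        raise ValueError("empty panel: every sample fails the call-rate filter")
    geno = geno[keep_s]
    called = called[keep_s]

    keep_v = np.ones(panel.n_variants, dtype=bool)
    # 2. variant call rate (on surviving samples)
    var_rate = called.mean(axis=0)
    fail = var_rate <= min_variant_call
    for vid in panel.variants.loc[fail, "id"]:
        report.removed_variants.append((vid, "call_rate"))
    keep_v &= ~fail
    # 3. MAF on surviving samples
    maf = minor_allele_frequency(geno)
    fail = keep_v & (np.isnan(maf) | (maf < min_maf))
    for vid in panel.variants.loc[fail, "id"]:
        report.removed_variants.append((vid, "maf"))
    keep_v &= ~fail
    # 4. chromosome class
    if autosomes_only:
        fail = keep_v & ~panel.variants["chrom"].isin(AUTOSOMES).to_numpy()
        for vid in panel.variants.loc[fail, "id"]:
            report.removed_variants.append((vid, "chrom"))
        keep_v &= ~fail

    out = panel.subset(np.nonzero(keep_s)[0], np.nonzero(keep_v)[0])
    report.n_samples_out = out.n_samples
    report.n_variants_out = out.n_variants
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    """Merge two panels on their shared variants, concatenating samples.

    Variant ids present in both panels are kept; allele orientation is
    reconciled by dosage flip and/or strand complement.  Strand-ambiguous
    (A/T, C/G) variants and irreconcilable allele pairs are dropped (counted
    via a warning).
    """
    shared_ids = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if shared_ids:
        raise ValueError(f"duplicate sample_id across panels: {sorted(shared_ids)[:5]}")

    b_index = {vid: j for j, vid in enumerate(b.variants["id"])}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[bool] = []
    n_ambiguous = n_irreconcilable = 0
    for i, rec in enumerate(a.variants.itertuples(index=False)):
        j = b_index.get(rec.id)
        if j is None:
            continue
        brec = b.variants.iloc[j]
        pair_a = (rec.allele_a, rec.allele_b)
        if set(pair_a) in _AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        pair_b = (brec["allele_a"], brec["allele_b"])
        resolved = None
        for candidate, flipped in (
            (pair_b, False),
            ((pair_b[1], pair_b[0]), True),
            ((_COMPLEMENT.get(pair_b[0], "?"), _COMPLEMENT.get(pair_b[1], "?")), False),
            ((_COMPLEMENT.get(pair_b[1], "?"), _COMPLEMENT.get(pair_b[0], "?")), True),
        ):
            if candidate == pair_a:
                resolved = flipped
                break
        if resolved is None:
            n_irreconcilable += 1
            continue
        keep_a.append(i)
        keep_b.append(j)
        flip_b.append(resolved)

    if n_ambiguous or n_irreconcilable:
        warnings.warn(
            f"merge_panels dropped {n_ambiguous} strand-ambiguous and "
            f"{n_irreconcilable} irreconcilable shared variants"
        )

    geno_a = a.genotypes[:, keep_a]
    geno_b = b.genotypes[:, keep_b].copy()
    flip = np.asarray(flip_b, dtype=bool)
    if flip.any():
        cols = geno_b[:, flip]
        flipped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        geno_b[:, flip] = flipped

    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    variants = a.variants.iloc[keep_a].reset_index(drop=True)
    geno = np.vstack([geno_a, geno_b])
    return GenotypePanel(samples, variants, geno)
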