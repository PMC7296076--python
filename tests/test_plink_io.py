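"""PLINK text/binary codec, QC filtering and panel merging."""
import numpy as np
import pytest

from pigpopgen import (
    MISSING,
    apply_qc,
    merge_panels,
    read_plink_binary,
    read_plink_text,
    write_plink_binary,
    write_plink_text,
)
from pigpopgen.plink import PlinkFormatError, minor_allele_frequency

from conftest import make_panel


def _write_toy_text(tmp_path):
    (tmp_path / "toy.map").write_text(
        "1 rs1 0 100\n1 rs2 0 200\n2 rs3 0 300\n"
    )
    (tmp_path / "toy.ped").write_text(
        "FAM1 S1 0 0 1 -9 A A A G 0 0\n"
        "FAM2 S2 0 0 2 -9 G G G G C T\n"
    )
    return tmp_path / "toy.ped", tmp_path / "toy.map"


class TestTextFormat:
    def test_hand_coded_example(self, tmp_path):
        """Allele-B dosages match the hand-derived coding of a 2x3 .ped."""
        panel = read_plink_text(*_write_toy_text(tmp_path))
        assert (panel.n_samples, panel.n_variants) == (2, 3)
        # rs1: A/G -> S1 AA=0, S2 GG=2; rs2: S1 AG=1; rs3: S1 "0 0" missing, S2 CT=1
        assert panel.genotypes.tolist() == [[0, 1, MISSING], [2, 2, 1]]
        assert list(panel.samples["breed"]) == ["FAM1", "FAM2"]
        assert list(panel.variants["allele_b"]) == ["G", "G", "T"]

    def test_zero_zero_is_missing(self, tmp_path):
        panel = read_plink_text(*_write_toy_text(tmp_path))
        assert panel.genotypes[0, 2] == MISSING

    def test_empty_ped_keeps_map(self, tmp_path):
        ped, mp = _write_toy_text(tmp_path)
        ped.write_text("")
        panel = read_plink_text(ped, mp)
        assert panel.n_samples == 0 and panel.n_variants == 3

    def test_ragged_row_names_line(self, tmp_path):
        ped, mp = _write_toy_text(tmp_path)
        ped.write_text(ped.read_text() + "FAM3 S3 0 0 1 -9 A A\n")
        with pytest.raises(PlinkFormatError, match="line 3"):
            read_plink_text(ped, mp)

    def test_invalid_allele_symbol(self, tmp_path):
        ped, mp = _write_toy_text(tmp_path)
        ped.write_text("FAM1 S1 0 0 1 -9 A A A G N N\n")
        with pytest.raises(PlinkFormatError, match="allele"):
            read_plink_text(ped, mp)

    def test_round_trip_polymorphic(self, tmp_path, two_pop_panel):
        """Text round trip is code-exact when both alleles are observed."""
        panel, _ = two_pop_panel
        keep = np.nonzero(minor_allele_frequency(panel.genotypes) > 0)[0][:200]
        sub = panel.subset(variant_idx=keep)
        write_plink_text(sub, tmp_path / "rt")
        back = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert sub.equals(back)


class TestBinaryFormat:
    def test_round_trip_with_missing(self, tmp_path, two_pop_panel):
        panel, _ = two_pop_panel
        geno = panel.genotypes.copy()
        geno[0, :5] = MISSING
        panel = make_panel(geno, breeds=list(panel.samples["breed"]))
        write_plink_binary(panel, tmp_path / "bin")
        back = read_plink_binary(
            tmp_path / "bin.bed", tmp_path / "bin.bim", tmp_path / "bin.fam"
        )
        assert np.array_equal(panel.genotypes, back.genotypes)

    def test_hand_packed_bytes(self, tmp_path):
        """2-bit decoding: 10 = het, 01 = missing, 00/11 = homozygotes."""
        (tmp_path / "h.fam").write_text("F S1 0 0 0 -9\nF S2 0 0 0 -9\n")
        (tmp_path / "h.bim").write_text("1\trs1\t0\t100\tA\tG\n")
        # sample0 bits 0-1 = 0b10 (het), sample1 bits 2-3 = 0b01 (missing)
        (tmp_path / "h.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b0110]))
        panel = read_plink_binary(tmp_path / "h.bed", tmp_path / "h.bim", tmp_path / "h.fam")
        assert panel.genotypes.tolist() == [[1], [MISSING]]

    def test_single_cell_panel(self, tmp_path):
        panel = make_panel([[2]])
        write_plink_binary(panel, tmp_path / "one")
        back = read_plink_binary(
            tmp_path / "one.bed", tmp_path / "one.bim", tmp_path / "one.fam"
        )
        assert back.genotypes.shape == (1, 1) and back.genotypes[0, 0] == 2

    def test_bad_magic_rejected(self, tmp_path):
        write_plink_binary(make_panel([[0], [1]]), tmp_path / "m")
        raw = (tmp_path / "m.bed").read_bytes()
        (tmp_path / "m.bed").write_bytes(b"\x00\x00" + raw[2:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(tmp_path / "m.bed", tmp_path / "m.bim", tmp_path / "m.fam")

    def test_size_mismatch_rejected(self, tmp_path):
        write_plink_binary(make_panel([[0], [1]]), tmp_path / "s")
        (tmp_path / "s.fam").write_text(
            "\n".join(f"F S{i} 0 0 0 -9" for i in range(9)) + "\n"
        )
        with pytest.raises(PlinkFormatError, match="payload"):
            read_plink_binary(tmp_path / "s.bed", tmp_path / "s.bim", tmp_path / "s.fam")

    def test_empty_panel_write_rejected(self, tmp_path):
        panel = make_panel(np.zeros((2, 1), dtype=np.int8)).subset(variant_idx=[])
        with pytest.raises(ValueError, match="empty"):
            write_plink_binary(panel, tmp_path / "e")

    def test_metadata_sidecar_overrides_breed(self, tmp_path):
        write_plink_binary(make_panel([[0], [1]], breeds=["X", "X"]), tmp_path / "md")
        (tmp_path / "meta.tsv").write_text(
            "sample_id\tbreed\tfarm\nS0\tEHL\tCZ\nS1\tEHL\tCS\n"
        )
        panel = read_plink_binary(
            tmp_path / "md.bed", tmp_path / "md.bim", tmp_path / "md.fam",
            metadata_path=tmp_path / "meta.tsv",
        )
        assert list(panel.samples["breed"]) == ["EHL", "EHL"]
        assert list(panel.samples["farm"]) == ["CZ", "CS"]


def _qc_oracle(panel, min_sample_call, min_variant_call, min_maf, autosomes_only):
    """Brute-force reapplication of the four QC rules in order."""
    g = panel.genotypes
    keep_s = [
        i for i in range(panel.n_samples)
        if np.mean(g[i] != MISSING) > min_sample_call
    ]
    g = g[keep_s]
    keep_v = []
    for j in range(panel.n_variants):
        col = g[:, j]
        called = col[col != MISSING]
        if len(called) / len(col) <= min_variant_call:
            continue
        p = called.sum() / (2 * len(called))
        if min(p, 1 - p) < min_maf:
            continue
        if autosomes_only and panel.variants.loc[j, "chrom"] not in {
            str(c) for c in range(1, 19)
        }:
            continue
        keep_v.append(j)
    return keep_s, keep_v


class TestQC:
    def test_maf_threshold_removal(self):
        """A variant at MAF 0.04 is removed with reason 'maf'; 0.05 survives."""
        # 25 samples: 2 hets -> p = 2/50 = 0.04 ; second variant p = 0.05
        g = np.zeros((25, 2), dtype=np.int8)
        g[:2, 0] = 1
        g[0, 1] = 2
        g[1, 1] = 1  # p = 3/50 = 0.06
        panel = make_panel(g)
        out, report = apply_qc(panel)
        assert ("v0", "maf") in report.removed_variants
        assert list(out.variants["id"]) == ["v1"]

    def test_low_call_sample_removed(self):
        g = np.ones((3, 10), dtype=np.int8)
        g[1, 1] = 0  # keep variants polymorphic-ish
        g[0, :5] = MISSING  # 50% missing
        out, report = apply_qc(make_panel(g), min_maf=0.0)
        assert ("S0", "call_rate") in report.removed_samples
        assert out.n_samples == 2

    def test_matches_brute_force_oracle(self):
        """Survivor sets equal a brute-force application of the rules."""
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, (10, 10)).astype(np.int8)
        g[rng.random((10, 10)) < 0.15] = MISSING
        g[0, :4] = MISSING
        chroms = ["1"] * 8 + ["X", "19"]
        panel = make_panel(g, chroms=chroms)
        out, report = apply_qc(panel, 0.6, 0.7, 0.1, True)
        keep_s, keep_v = _qc_oracle(panel, 0.6, 0.7, 0.1, True)
        assert list(out.samples["sample_id"]) == [f"S{i}" for i in keep_s]
        assert list(out.variants["id"]) == [f"v{j}" for j in keep_v]
        report.validate()

    def test_idempotent(self, two_pop_panel):
        panel, _ = two_pop_panel
        once, _ = apply_qc(panel)
        twice, rep = apply_qc(once)
        assert once.equals(twice)
        assert not rep.removed_samples and not rep.removed_variants

    def test_all_samples_removed_raises(self):
        g = np.full((2, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="empty panel"):
            apply_qc(make_panel(g))


class TestMerge:
    def test_identical_maps_concatenate(self):
        a = make_panel([[0, 1], [1, 2]])
        b = make_panel([[2, 0]])
        b.samples["sample_id"] = ["T0"]
        merged = merge_panels(a, b)
        assert merged.n_samples == 3 and merged.n_variants == 2
        assert merged.genotypes.tolist() == [[0, 1], [1, 2], [2, 0]]

    def test_private_variant_absent(self):
        a = make_panel([[0, 1]])
        b = make_panel([[1]])
        b.samples["sample_id"] = ["T0"]
        b.variants.loc[0, "id"] = "v1"  # only v1 shared
        merged = merge_panels(a, b)
        assert list(merged.variants["id"]) == ["v1"]

    def test_strand_flip_and_ambiguous_drop(self):
        """T/C opposite-strand coding is complement-flipped; A/T is dropped."""
        a = make_panel([[0, 1]], alleles=[("A", "G"), ("A", "T")])
        b = make_panel([[2, 0]], alleles=[("T", "C"), ("A", "T")])
        b.samples["sample_id"] = ["T0"]
        with pytest.warns(UserWarning, match="ambiguous"):
            merged = merge_panels(a, b)
        assert list(merged.variants["id"]) == ["v0"]
        # b's T/C == complement A/G, same orientation: dosage kept
        assert merged.genotypes.tolist() == [[0], [2]]

    def test_swapped_alleles_flip_dosage(self):
        a = make_panel([[0]], alleles=[("A", "G")])
        b = make_panel([[0]], alleles=[("G", "A")])
        b.samples["sample_id"] = ["T0"]
        merged = merge_panels(a, b)
        assert merged.genotypes.tolist() == [[0], [2]]

    def test_duplicate_sample_rejected(self):
        a = make_panel([[0]])
        with pytest.raises(ValueError, match="duplicate"):
            merge_panels(a, make_panel([[1]]))
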