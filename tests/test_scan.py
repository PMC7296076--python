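"""Selection scans: Fst ranking, LSBL, thresholds, windows, fixation check."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigpopgen import (
    candidate_windows,
    empirical_threshold,
    fst_scan,
    fst_weir_cockerham,
    haplotype_fixation_check,
    lsbl_scan,
    lsbl_values,
)
from pigpopgen.scan import subsample_group

from conftest import make_panel


def _two_group_panel(seed=100, n=10, m=60):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 3, (2 * n, m)).astype(np.int8)
    return make_panel(g, breeds=["X"] * n + ["Y"] * n)


class TestFstScan:
    def test_fixed_difference_ranks_first(self):
        panel = _two_group_panel()
        g = panel.genotypes.copy()
        g[:10, 7] = 0
        g[10:, 7] = 2
        panel = make_panel(g, breeds=["X"] * 10 + ["Y"] * 10)
        res = fst_scan(panel, ("X", "Y"), top_n=3)
        assert res.hits[0] == "v7"
        assert res.per_locus[7] == pytest.approx(1.0)

    def test_top_n_clamped_to_snp_count(self):
        panel = _two_group_panel(m=5)
        res = fst_scan(panel, ("X", "Y"), top_n=50)
        assert len(res.hits) <= 5

    def test_hits_stable_under_snp_reorder(self):
        panel = _two_group_panel()
        rng = np.random.default_rng(101)
        perm = rng.permutation(panel.n_variants)
        res1 = fst_scan(panel, ("X", "Y"), top_n=5)
        res2 = fst_scan(panel.subset(variant_idx=perm), ("X", "Y"), top_n=5)
        assert res1.hits == res2.hits


class TestLsbl:
    def test_formula_cases(self):
        """LSBL(g1) = (F12 + F13 - F23)/2 on engineered frequency layouts."""
        # identical polymorphic sources: F12 = F13 = d, F23 clamps to 0 -> LSBL = d
        src = np.array([[0], [0], [1], [1]], np.int8).repeat(3, axis=1)
        g = np.vstack([np.full((4, 3), 2, np.int8), src, src])
        panel = make_panel(g, breeds=["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        vals = lsbl_values(panel, "A", "B", "C")
        d = fst_weir_cockerham(panel, ("A", "B")).per_locus
        np.testing.assert_allclose(vals, np.maximum(d, 0.0))
        # all groups identical -> all pairwise Fst ~ 0 -> LSBL ~ 0
        rng = np.random.default_rng(102)
        block = rng.integers(0, 3, (6, 100)).astype(np.int8)
        panel0 = make_panel(np.vstack([block] * 3), breeds=["A"] * 6 + ["B"] * 6 + ["C"] * 6)
        assert np.nanmax(np.abs(lsbl_values(panel0, "A", "B", "C"))) < 1e-9

    def test_swap_sources_invariance(self):
        panel = make_panel(
            np.random.default_rng(103).integers(0, 3, (12, 40)).astype(np.int8),
            breeds=["A"] * 4 + ["B"] * 4 + ["C"] * 4,
        )
        np.testing.assert_allclose(
            lsbl_values(panel, "A", "B", "C"),
            lsbl_values(panel, "A", "C", "B"),
            equal_nan=True,
        )

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sum_identity_preclamp(self, seed):
        """LSBL(g1) + LSBL(g2) = Fst(g1,g2) per locus before clamping."""
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, (12, 30)).astype(np.int8)
        panel = make_panel(g, breeds=["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        l1 = lsbl_values(panel, "A", "B", "C", clamp_negative=False)
        l2 = lsbl_values(panel, "B", "A", "C", clamp_negative=False)
        f12 = fst_weir_cockerham(panel, ("A", "B")).per_locus
        np.testing.assert_allclose(l1 + l2, f12, atol=1e-10, equal_nan=True)

    def test_scan_threshold_and_hits(self):
        panel = _two_group_panel(m=200)
        g = np.vstack([panel.genotypes, panel.genotypes[:10]])
        panel3 = make_panel(g, breeds=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        res = lsbl_scan(panel3, "A", "B", "C", top_quantile=0.05)
        assert len(res.hits) >= int(0.05 * 200)
        assert all(
            res.per_locus[res.variant_ids.index(h)] >= res.threshold_value for h in res.hits
        )


class TestEmpiricalThreshold:
    def test_floor_arithmetic_large_vector(self):
        values = np.arange(18_703, dtype=float)
        threshold, n_hits = empirical_threshold(values, 0.005)
        assert n_hits == 93  # floor(0.005 * 18703)
        assert threshold == values[-93]

    def test_total_tie_includes_all(self):
        _, n_hits = empirical_threshold(np.ones(40), 0.1)
        assert n_hits == 40

    def test_quantile_one_returns_all(self):
        _, n_hits = empirical_threshold(np.arange(17.0), 1.0)
        assert n_hits == 17


class TestCandidateWindows:
    VARIANTS = pd.DataFrame(
        {
            "id": ["s1", "s2"],
            "chrom": ["1", "2"],
            "pos_bp": [10_000, 50_000],
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    FEATURES = pd.DataFrame(
        {
            "name": ["inA", "edge", "before", "otherchrom", "inB"],
            "chrom": ["1", "1", "1", "2", "2"],
            "start": [9_500, 8_000, 1, 49_000, 50_500],
            "end": [10_200, 8_999, 8_999, 49_100, 50_600],
        }
    )

    def test_hand_enumerated_overlaps(self):
        windows, names = candidate_windows(
            ["s1", "s2"], self.VARIANTS, 1000, self.FEATURES
        )
        assert [w.center_variant for w in windows] == ["s1", "s2"]
        assert [f[0] for f in windows[0].overlapping_features] == ["inA"]
        assert sorted(f[0] for f in windows[1].overlapping_features) == ["inB", "otherchrom"]
        assert names == ["inA", "otherchrom", "inB"]

    def test_boundary_exclusive_at_start_minus_one(self):
        """A feature ending exactly at start_bp - 1 does not overlap."""
        windows, _ = candidate_windows(["s1"], self.VARIANTS, 1000, self.FEATURES)
        assert windows[0].start_bp == 9_000
        assert "edge" not in [f[0] for f in windows[0].overlapping_features]

    def test_window_clipped_at_one(self):
        windows, _ = candidate_windows(["s1"], self.VARIANTS, 50_000, self.FEATURES.iloc[:0])
        assert windows[0].start_bp == 1 and windows[0].end_bp == 60_000

    def test_unknown_hit_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no map position"):
            windows, _ = candidate_windows(["nope"], self.VARIANTS, 100, self.FEATURES)
        assert windows == []


class TestHaplotypeFixation:
    def _opposite_fixed_panel(self):
        m = 9
        g = np.vstack([np.zeros((6, m), np.int8), np.full((6, m), 2, np.int8)])
        return make_panel(
            g, breeds=["MMS"] * 6 + ["SMS"] * 6, pos=[100_000 * (j + 1) for j in range(m)]
        )

    def test_opposite_fixation_complementary_strings(self):
        panel = self._opposite_fixed_panel()
        rep = haplotype_fixation_check(panel, ("MMS", "SMS"), "1", 450_000)
        assert len(rep["snp_ids"]) == 9
        assert rep["groups"]["MMS"]["fixation_fraction"] == 1.0
        assert rep["groups"]["SMS"]["fixation_fraction"] == 1.0
        assert rep["groups"]["MMS"]["major_genotype"] == "A" * 9
        assert rep["groups"]["SMS"]["major_genotype"] == "G" * 9

    def test_panmictic_no_group_contrast(self):
        rng = np.random.default_rng(104)
        g = rng.integers(0, 3, (40, 6)).astype(np.int8)
        panel = make_panel(
            g, breeds=["X"] * 20 + ["Y"] * 20, pos=[10_000 * (j + 1) for j in range(6)]
        )
        rep = haplotype_fixation_check(panel, ("X", "Y"), "1", 30_000, r2_floor=0.95)
        fr = [rep["groups"][k]["fixation_fraction"] for k in ("X", "Y")]
        assert all(f < 0.9 for f in fr)

    def test_single_snp_window_degenerates(self):
        panel = self._opposite_fixed_panel()
        rep = haplotype_fixation_check(
            panel, ("MMS", "SMS"), "1", 100_000, window_bp=50_000
        )
        assert rep["snp_ids"] == ["v0"]

    def test_empty_window_rejected(self):
        panel = self._opposite_fixed_panel()
        with pytest.raises(ValueError, match="empty window"):
            haplotype_fixation_check(panel, ("MMS", "SMS"), "7", 100_000)


def test_seeded_subsample_utility():
    panel = _two_group_panel(n=20)
    sub = subsample_group(panel, ["X", "Y"], 12, seed=5, new_label="G1")
    assert sub.n_samples == 12
    assert set(sub.samples["breed"]) == {"G1"}
    again = subsample_group(panel, ["X", "Y"], 12, seed=5, new_label="G1")
    assert sub.equals(again)
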