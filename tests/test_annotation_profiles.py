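"""Annotation overlays: overlap, distance, GC windows, sub-regions, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncohap import annotation_profiles as ap
from ncohap.dataio import GeneModel, IntervalTrack


def _avrank(v):
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    r = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        r[i:j] = (i + j + 1) / 2.0
        i = j
    out = np.empty(len(v))
    out[order] = r
    return out


def reference_mannwhitney(x, y):
    """Independent rank-sum implementation (normal approx, tie + continuity
    corrections), for cross-checking the packaged test."""
    n1, n2 = len(x), len(y)
    comb = np.concatenate([x, y])
    ranks = _avrank(comb)
    U1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(comb, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1))))
    z = U1 - mu
    z = (z - 0.5 * np.sign(z)) / sigma
    return U1, min(1.0, 2 * stats.norm.sf(abs(z)))


def reference_spearman(x, y):
    rx, ry = _avrank(np.asarray(x, float)), _avrank(np.asarray(y, float))
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return rho, 2 * stats.t.sf(abs(t), n - 2)


TRACK = IntervalTrack("t", [("chr1", 100, 101), ("chr1", 1000, 2000)])


class TestOverlap:
    def test_one_based_convention(self):
        got = ap.overlap_any(["chr1", "chr1"], [101, 102], TRACK)
        assert got.tolist() == [True, False]

    def test_empty_track_all_false(self):
        empty = IntervalTrack("e", [])
        assert not ap.overlap_any(["chr1"], [101], empty).any()


class TestSignedDistance:
    def test_outside_distance(self):
        df = ap.signed_distance(["chr1"], [501], TRACK)
        # nearest interval is (100, 101): last covered base is 1-based 101
        assert df["distance"].iloc[0] == 400
        assert not df["inside"].iloc[0]

    def test_inside_zero_with_flag(self):
        df = ap.signed_distance(["chr1"], [1501], TRACK)
        assert df["distance"].iloc[0] == 0
        assert df["inside"].iloc[0]
        assert df["boundary_distance"].iloc[0] == 499

    def test_chromosome_without_intervals_undefined(self):
        df = ap.signed_distance(["chr2"], [100], TRACK)
        assert np.isnan(df["distance"].iloc[0])


class TestGcContent:
    def test_fraction(self):
        seq = "GC" * 40 + "AT" * 60  # 200 bp, 80 G/C
        ref = {"chr1": seq}
        assert ap.gc_content_window(ref, "chr1", 101) == pytest.approx(0.40)

    def test_all_at(self):
        ref = {"chr1": "AT" * 200}
        assert ap.gc_content_window(ref, "chr1", 200) == 0.0

    def test_truncated_window(self):
        # pos 51 → window [0, 150); make those 150 bases carry 75 G/C
        seq = "GA" * 75 + "T" * 100
        ref = {"chr1": seq}
        assert ap.gc_content_window(ref, "chr1", 51) == pytest.approx(0.50)

    def test_all_n_undefined(self):
        ref = {"chr1": "N" * 400}
        assert ap.gc_content_window(ref, "chr1", 200) is None


def gene_fixture():
    #  span 10000-20000 (+): exons (10000,12000),(15000,20000);
    #  CDS (11000,16000) → UTR5 (10000,11000), UTR3 (16000,20000)
    return GeneModel(
        gene_id="g1", chrom="chr1", strand="+",
        transcript_intervals=[(10_000, 20_000)],
        exon_intervals=[(10_000, 12_000), (15_000, 20_000)],
        cds_intervals=[(11_000, 12_000), (15_000, 16_000)],
        utr5_intervals=[(10_000, 11_000)], utr3_intervals=[(16_000, 20_000)])


class TestSubregions:
    def test_priority_labels(self):
        g = gene_fixture()
        pos = [11_500,  # CDS exon
               12_002,  # 1 bp into intron (0-based 12001) → splice
               13_000,  # deep intron
               10_500,  # UTR5
               17_000,  # UTR3
               9_000,   # 1 kb upstream (+)
               21_000,  # 1 kb downstream
               80_000]  # 60 kb downstream
        labels = ap.genic_subregion_assign(["chr1"] * len(pos), pos, [g])
        assert labels.tolist() == [
            "exonic", "splice_site", "intronic", "UTR5", "UTR3",
            "intergenic_0to5kb_up", "intergenic_0to5kb_down",
            "intergenic_gt50kb_down"]

    def test_minus_strand_flips_sides(self):
        g = gene_fixture()
        g.strand = "-"
        labels = ap.genic_subregion_assign(["chr1", "chr1"], [9_000, 21_000],
                                           [g])
        assert labels.tolist() == ["intergenic_0to5kb_down",
                                   "intergenic_0to5kb_up"]

    def test_no_genes_all_intergenic(self):
        labels = ap.genic_subregion_assign(["chr1"], [500], [])
        assert ap.coarse_subregion(labels).tolist() == ["intergenic"]

    def test_coarse_merges_splice_into_intronic(self):
        assert ap.coarse_subregion(["splice_site"]).tolist() == ["intronic"]


class TestBinnedProfile:
    def test_single_bin_mean(self):
        prof = ap.binned_mean_profile([0, 1, 1, 0.5], [0.1, 0.2, 0.3, 0.4],
                                      [0, 1])
        assert prof.table["mean"].iloc[0] == pytest.approx(0.625)

    def test_conservation_of_global_mean(self, rng):
        v = rng.normal(size=500)
        by = rng.uniform(0, 1, 500)
        prof = ap.binned_mean_profile(v, by, np.linspace(0, 1, 11))
        assert prof.global_mean == pytest.approx(v.mean(), abs=1e-12)
        assert prof.table["count"].sum() == 500

    def test_empty_bin_reported(self):
        prof = ap.binned_mean_profile([1.0], [0.05], [0, 0.1, 0.2])
        assert prof.table["count"].tolist() == [1, 0]
        assert np.isnan(prof.table["mean"].iloc[1])

    def test_uncovered_range_fatal(self):
        with pytest.raises(ValueError, match="cover"):
            ap.binned_mean_profile([1.0], [1.5], [0, 1])


class TestMarkDelta:
    def test_identical_strata_ns(self, rng):
        rates = rng.uniform(0, 1, 200)
        on = np.arange(200) % 2 == 0
        df = ap.subregion_mark_delta(rates, on, ["x"] * 200)
        row = df.iloc[0]
        assert row["p_value"] > 0.05

    def test_shifted_strata_detected(self, rng):
        on = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        rates = np.concatenate([rng.uniform(0.2, 1.0, 500) + 0.2,
                                rng.uniform(0.2, 1.0, 500)])
        df = ap.subregion_mark_delta(rates, on, ["x"] * 1000)
        row = df.iloc[0]
        assert row["delta"] == pytest.approx(0.2, abs=0.05)
        assert row["p_value"] < 1e-6

    def test_full_coverage_untestable(self):
        df = ap.subregion_mark_delta([1.0, 0.5], [True, True], ["x", "x"])
        assert not df.iloc[0]["testable"]
        assert np.isnan(df.iloc[0]["p_value"])

    def test_exclusion_mask_applied(self, rng):
        rates = rng.uniform(0, 1, 100)
        on = np.arange(100) % 2 == 0
        df = ap.subregion_mark_delta(rates, on, ["x"] * 100,
                                     exclude_mask=np.ones(100, bool))
        assert df.empty

    def test_utest_matches_reference(self, rng):
        """Packaged U test equals the independent rank-sum implementation on
        100 random tied strata (p within 1e-9)."""
        for _ in range(100):
            n1, n2 = rng.integers(51, 150, 2)
            x = rng.integers(0, 15, n1).astype(float)
            y = rng.integers(0, 17, n2).astype(float)
            df = ap.subregion_mark_delta(
                np.concatenate([x, y]),
                np.concatenate([np.ones(n1, bool), np.zeros(n2, bool)]),
                ["s"] * (n1 + n2))
            U_ref, p_ref = reference_mannwhitney(x, y)
            assert df.iloc[0]["U"] == pytest.approx(U_ref, abs=1e-9)
            assert df.iloc[0]["p_value"] == pytest.approx(p_ref, abs=1e-9)


class TestFoldChange:
    def test_independent_track_flat(self, rng):
        rates = rng.uniform(0, 1, 5000)
        overlap = rng.random(5000) < 0.3
        table, m, r2 = ap.overlap_foldchange_slope(rates, overlap, n_bins=5)
        assert np.allclose(table["fold_change"].dropna(), 1.0, atol=0.25)
        assert abs(m) < 0.5

    def test_linear_rise_recovered(self):
        # overlap frequency rises 0.1 → 0.3 over 5 bins (global 0.2):
        # fold change 0.5 → 1.5, slope recoverable from bin means
        rates, overlap = [], []
        freqs = [0.1, 0.15, 0.2, 0.25, 0.3]
        centers = [0.1, 0.3, 0.5, 0.7, 0.9]
        for c, f in zip(centers, freqs):
            n = 1000
            rates.extend([c] * n)
            overlap.extend([True] * int(f * n) + [False] * (n - int(f * n)))
        table, m, r2 = ap.overlap_foldchange_slope(rates, overlap, n_bins=5)
        assert table["fold_change"].iloc[0] == pytest.approx(0.5, abs=0.01)
        assert table["fold_change"].iloc[-1] == pytest.approx(1.5, abs=0.01)
        # analytic slope: Δfold/Δrate = (1.5 − 0.5) / (0.9 − 0.1) = 1.25
        assert m == pytest.approx(1.25, abs=0.05)
        assert r2 > 0.99

    def test_too_few_bins_fatal(self, rng):
        with pytest.raises(ValueError):
            ap.overlap_foldchange_slope([0.5] * 10, [True] * 10, n_bins=1)

    def test_zero_overlap_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ap.overlap_foldchange_slope([0.1, 0.9], [False, False], n_bins=3)


class TestStateSummary:
    def test_monotone_coupling_gives_rho_one(self):
        rng = np.random.default_rng(2)
        states = np.array([f"s{i}" for i in rng.integers(0, 10, 2000)],
                          dtype=object)
        rates = np.array([int(s[1:]) / 10 for s in states])
        mark = np.array([rng.random() < int(s[1:]) / 12 for s in states])
        table, corr = ap.state_region_summary(
            rates, {"e1": states}, {"m": mark})
        rho, p = corr["m"]
        assert rho > 0.9 and p < 0.01
        assert len(table) == 10

    def test_constant_mark_undefined(self):
        states = np.array(["a", "b"] * 50, dtype=object)
        rates = np.linspace(0, 1, 100)
        table, corr = ap.state_region_summary(
            rates, {"e1": states}, {"m": np.ones(100, bool)})
        assert np.isnan(corr["m"][0])

    def test_spearman_matches_reference(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 100))
            x = rng.integers(0, 25, n).astype(float)
            y = x * 0.4 + rng.normal(0, 4, n)
            rho, p = stats.spearmanr(x, y)
            rho_ref, p_ref = reference_spearman(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_assign_states_partitions(self):
        tracks = {
            "A": IntervalTrack("A", [("chr1", 0, 100)], "chrom_state"),
            "B": IntervalTrack("B", [("chr1", 100, 200)], "chrom_state"),
        }
        labels = ap.assign_states(["chr1", "chr1", "chr1"], [50, 150, 500],
                                  tracks)
        assert labels.tolist() == ["A", "B", ""]


class TestPermutationInvariance:
    def test_profiles_order_invariant(self, rng):
        rates = rng.uniform(0, 1, 300)
        on = rng.random(300) < 0.4
        labels = np.array(["a", "b", "c"] * 100, dtype=object)
        perm = rng.permutation(300)
        a = ap.subregion_mark_delta(rates, on, labels).sort_values(
            "subregion").reset_index(drop=True)
        b = ap.subregion_mark_delta(rates[perm], on[perm], labels[perm]
                                    ).sort_values("subregion").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
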