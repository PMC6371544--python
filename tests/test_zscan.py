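"""Window construction, rolling means, per-chromosome Z-scores, signature calls."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.freqstats import SiteStatTrack
from sweepscan.zscan import merge_across_windows, SelectionSignature

from conftest import make_snp_map


def two_chrom_map(n1, n2, spacing=50_000):
    frames = []
    for c, n in ((1, n1), (2, n2)):
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"c{c}s{i}" for i in range(n)],
                    "chrom": c,
                    "pos": np.arange(1, n + 1) * spacing,
                    "allele1": "A",
                    "allele2": "G",
                }
            )
        )
    return ss.SnpMap(pd.concat(frames, ignore_index=True))


def afd_track(snp_map, values):
    return SiteStatTrack("AFD", ("I", "III"), np.asarray(values, float), snp_map)


class TestBuildWindows:
    def test_count_mode_edge_truncation(self):
        snp_map = make_snp_map([10, 20, 30, 40, 50])
        w = ss.build_windows(snp_map, "count", 3)
        assert w.lower.tolist() == [0, 0, 1, 2, 3]
        assert w.upper.tolist() == [1, 2, 3, 4, 4]

    def test_distance_mode_half_window_each_side(self):
        snp_map = make_snp_map([1, 400_001, 800_001, 1_600_001])
        w = ss.build_windows(snp_map, "distance", 1_000_000)
        # SNP at 0.4 Mb covers 0.0-0.8 Mb (0.5 Mb each side)
        assert (w.lower[1], w.upper[1]) == (0, 2)
        # SNP at 1.6 Mb reaches back only to 1.1 Mb: itself alone
        assert (w.lower[3], w.upper[3]) == (3, 3)

    def test_windows_stay_within_chromosome(self):
        snp_map = two_chrom_map(5, 5)
        for mode, size in (("count", 5), ("distance", 10_000_000)):
            w = ss.build_windows(snp_map, mode, size)
            chrom = snp_map.chrom
            assert (chrom[w.lower] == chrom[np.arange(10)]).all()
            assert (chrom[w.upper] == chrom[np.arange(10)]).all()

    def test_even_count_size_rejected(self):
        with pytest.raises(ValueError):
            ss.build_windows(make_snp_map([1, 2, 3]), "count", 4)


class TestLongrangeMean:
    def test_three_snp_window_arithmetic(self):
        snp_map = make_snp_map([10, 20, 30])
        x = ss.longrange_mean(afd_track(snp_map, [0.1, 0.2, 0.3]),
                              ss.build_windows(snp_map, "count", 3))
        np.testing.assert_allclose(x, [0.15, 0.2, 0.25])

    def test_constant_statistic_unchanged(self):
        snp_map = make_snp_map(range(10, 110, 10))
        x = ss.longrange_mean(afd_track(snp_map, [0.4] * 10),
                              ss.build_windows(snp_map, "count", 5))
        np.testing.assert_allclose(x, 0.4)

    def test_missing_statistics_shrink_the_denominator(self):
        snp_map = make_snp_map([10, 20, 30])
        x = ss.longrange_mean(afd_track(snp_map, [0.1, np.nan, 0.3]),
                              ss.build_windows(snp_map, "count", 3))
        np.testing.assert_allclose(x, [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("mode,size", [("count", 7), ("distance", 300_000)])
    def test_rolling_equals_naive_windows(self, mode, size):
        rng = np.random.default_rng(5)
        snp_map = two_chrom_map(300, 200)
        vals = rng.uniform(0, 1, 500)
        vals[rng.choice(500, 30, replace=False)] = np.nan
        w = ss.build_windows(snp_map, mode, size)
        x = ss.longrange_mean(afd_track(snp_map, vals), w)
        for j in range(500):
            win = vals[w.lower[j] : w.upper[j] + 1]
            expected = np.nanmean(win) if ~np.isnan(win).all() else np.nan
            if np.isnan(expected):
                assert np.isnan(x[j])
            else:
                assert x[j] == pytest.approx(expected, abs=1e-12)


class TestStandardize:
    def test_closed_form_three_values(self):
        snp_map = make_snp_map([10, 20, 30])
        track = afd_track(snp_map, [1.0, 2.0, 3.0])
        w = ss.build_windows(snp_map, "count", 1)
        zt = ss.zscore_scan(track, w)
        np.testing.assert_allclose(zt.z, [-1.0, 0.0, 1.0])

    def test_per_chromosome_centering(self):
        rng = np.random.default_rng(2)
        snp_map = two_chrom_map(100, 80)
        # different scales per chromosome
        vals = np.concatenate([rng.uniform(0, 0.2, 100), rng.uniform(0.5, 1.0, 80)])
        zt = ss.zscore_scan(afd_track(snp_map, vals), ss.build_windows(snp_map, "count", 5))
        for sl in snp_map.chrom_slices().values():
            z = zt.z[sl]
            assert abs(z.mean()) < 1e-12
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_chromosomes_standardized_independently(self):
        rng = np.random.default_rng(3)
        snp_map = two_chrom_map(60, 60)
        vals = rng.uniform(0, 1, 120)
        w = ss.build_windows(snp_map, "count", 3)
        zt = ss.zscore_scan(afd_track(snp_map, vals), w)
        # oracle: standardize each chromosome's X by hand
        x = ss.longrange_mean(afd_track(snp_map, vals), w)
        for sl in snp_map.chrom_slices().values():
            xs = x[sl]
            np.testing.assert_allclose(
                zt.z[sl], (xs - xs.mean()) / xs.std(ddof=1), atol=1e-12
            )

    def test_affine_invariance_of_z(self):
        rng = np.random.default_rng(4)
        snp_map = make_snp_map(range(10, 1010, 10))
        vals = rng.uniform(0, 1, 100)
        w = ss.build_windows(snp_map, "count", 5)
        z1 = ss.zscore_scan(afd_track(snp_map, vals), w).z
        z2 = ss.zscore_scan(afd_track(snp_map, 3.0 * vals + 0.2), w).z
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_constant_chromosome_flagged(self):
        snp_map = make_snp_map([10, 20, 30])
        zt = ss.zscore_scan(afd_track(snp_map, [0.2, 0.2, 0.2]),
                            ss.build_windows(snp_map, "count", 1))
        assert np.isnan(zt.z).all()
        assert zt.chrom_stats[1][1] == 0.0


class TestCallSignatures:
    def zt(self, z_values, kind="AFD"):
        snp_map = make_snp_map([(i + 1) * 1000 for i in range(len(z_values))])
        w = ss.build_windows(snp_map, "count", 1)
        x = np.asarray(z_values, float)
        return ss.ZScoreTrack(kind, ("I", "III"), w, x, x.copy(), {1: (0, 1)}, snp_map)

    def test_peak_and_extend_rule(self):
        sigs = ss.call_signatures(self.zt([0, 2.5, 3.5, 2.2, 1.0]))
        assert len(sigs) == 1
        s = sigs[0]
        assert (s.start_bp, s.end_bp, s.peak_bp) == (2000, 4000, 3000)
        assert s.n_snps == 3

    def test_no_peak_no_signature(self):
        assert ss.call_signatures(self.zt([2.9, 2.9, 2.9])) == []

    def test_afd_is_one_sided(self):
        assert ss.call_signatures(self.zt([-3.5, -3.5, 0.0])) == []

    def test_hd_two_sided_with_sign_consistent_runs(self):
        sigs = ss.call_signatures(self.zt([-2.5, -3.5, 2.5, 3.5, 2.1], kind="HD"))
        assert len(sigs) == 2
        assert sigs[0].sign == -1 and sigs[0].n_snps == 2
        assert sigs[1].sign == 1 and sigs[1].n_snps == 3

    def test_tied_peak_takes_leftmost(self):
        sigs = ss.call_signatures(self.zt([3.5, 3.5, 2.5]))
        assert sigs[0].peak_bp == 1000

    def test_called_signatures_satisfy_their_invariants(self, sweep_sim, sweep_combined):
        _, _, freqs = sweep_combined
        track = ss.afd(freqs, "I", "III")
        for w in (500_000, 1_000_000):
            zt = ss.zscore_scan(track, ss.build_windows(sweep_sim.snp_map, "distance", w))
            for sig in ss.call_signatures(zt):
                assert abs(sig.peak_z) >= 3.0
                sl = sweep_sim.snp_map.chrom_slices()[sig.chrom]
                pos = sweep_sim.snp_map.pos[sl]
                inside = (pos >= sig.start_bp) & (pos <= sig.end_bp)
                assert (np.abs(zt.z[sl][inside]) >= 2.0).all()

    def test_call_below_extend_rejected(self):
        with pytest.raises(ValueError):
            ss.call_signatures(self.zt([0.0, 0.0]), call_thresh=1.0, extend_thresh=2.0)


def sig(chrom, start, end, peak_z=3.5, window="1Mb"):
    return SelectionSignature(chrom, start, end, (start + end) // 2, peak_z,
                              "Z_AFD", 1, ("I", "III"), window, 5)


class TestMergeAcrossWindows:
    def test_disjoint_inputs_concatenate(self):
        merged = merge_across_windows([[sig(1, 100, 200)], [sig(1, 500, 600)]])
        assert [(m.start_bp, m.end_bp) for m in merged] == [(100, 200), (500, 600)]

    def test_nested_intervals_become_one_region(self):
        merged = merge_across_windows([[sig(1, 100, 1000)], [sig(1, 300, 400, peak_z=5.0)]])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start_bp, m.end_bp) == (100, 1000)
        assert m.best_peak_z == 5.0
        assert m.n_merged == 2

    def test_merged_count_never_exceeds_input_count(self, sweep_sim, sweep_combined):
        _, _, freqs = sweep_combined
        track = ss.afd(freqs, "I", "III")
        lists = [
            ss.call_signatures(
                ss.zscore_scan(track, ss.build_windows(sweep_sim.snp_map, "distance", w))
            )
            for w in (500_000, 1_000_000, 2_000_000, 3_000_000)
        ]
        merged = merge_across_windows(lists)
        assert len(merged) <= sum(len(l) for l in lists)
        assert all(m.window_labels for m in merged)

    def test_same_chromosome_required_for_merging(self):
        merged = merge_across_windows([[sig(1, 100, 200)], [sig(2, 100, 200)]])
        assert len(merged) == 2
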