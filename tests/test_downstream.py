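"""IBS distances, classical MDS, effect correlations, signature annotation."""

import numpy as np
import pytest

import sweepscan as ss
from sweepscan.downstream import annotate_signatures, signatures_with_hits
from sweepscan.zscan import SelectionSignature

from conftest import make_snp_map


def matrix_from(rows, samples=None):
    rows = np.asarray(rows, dtype=np.int8)
    snp_map = make_snp_map(np.arange(1, rows.shape[1] + 1) * 1000)
    if samples is None:
        samples = [f"s{i}" for i in range(rows.shape[0])]
    return ss.GenotypeMatrix(samples, rows, snp_map)


class TestIbsDistances:
    def test_identical_samples_have_zero_distance(self):
        d = ss.ibs_distances(matrix_from([[0, 1, 2], [0, 1, 2]]))
        assert d.values[0, 1] == 0.0
        assert (np.diag(d.values) == 0).all()

    def test_opposite_homozygotes_have_distance_one(self):
        d = ss.ibs_distances(matrix_from([[0, 0, 0], [2, 2, 2]]))
        assert d.values[0, 1] == 1.0

    def test_missing_pairs_use_co_observed_snps_only(self):
        d = ss.ibs_distances(matrix_from([[0, 1, -1], [0, -1, 2]]))
        assert d.values[0, 1] == 0.0  # only SNP 0 is co-observed, and it matches

    def test_all_missing_sample_errors(self):
        with pytest.raises(ValueError, match="s1"):
            ss.ibs_distances(matrix_from([[0, 1], [-1, -1]]))

    def test_matches_per_pair_loop_oracle(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        rows[rng.random(rows.shape) < 0.1] = -1
        rows[:, 0] = 1  # guarantee co-observation everywhere
        m = matrix_from(rows)
        d = ss.ibs_distances(m)
        for i in range(12):
            for j in range(i + 1, 12):
                both = (rows[i] >= 0) & (rows[j] >= 0)
                ibs = np.mean((2 - np.abs(rows[i][both] - rows[j][both])) / 2)
                assert d.values[i, j] == pytest.approx(1 - ibs, abs=1e-12)
        np.testing.assert_allclose(d.values, d.values.T)


class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        from sweepscan.downstream import DistanceMatrix

        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float
        ))
        res = ss.classical_mds(d, k=2)
        x = res.coordinates[:, 0]
        assert np.abs(np.diff(x)).max() == pytest.approx(1.0, abs=1e-8)
        if res.coordinates.shape[1] > 1:
            assert np.abs(res.coordinates[:, 1]).max() < 1e-8

    def test_planted_plane_distances_round_trip(self):
        from scipy.spatial.distance import squareform, pdist
        from sweepscan.downstream import DistanceMatrix

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 2))
        d = DistanceMatrix(list(range(15)), squareform(pdist(pts)))
        res = ss.classical_mds(d, k=2)
        np.testing.assert_allclose(
            squareform(pdist(res.coordinates)), d.values, atol=1e-8
        )

    def test_agrees_with_pcoa_reference(self):
        # independent cross-check against scikit-bio's principal coordinates
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix as SkbioDM
        from sweepscan.downstream import DistanceMatrix

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import squareform, pdist

        dv = squareform(pdist(pts))
        res = ss.classical_mds(DistanceMatrix(list("abcdefghij"), dv), k=3)
        ref = pcoa(SkbioDM(dv, ids=list("abcdefghij")), number_of_dimensions=3)
        ref_coords = ref.samples.to_numpy()
        for axis in range(3):
            r = np.corrcoef(res.coordinates[:, axis], ref_coords[:, axis])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_serial_cohorts_order_along_dimension_one(self, sweep_combined):
        matrix, _, _ = sweep_combined
        res = ss.classical_mds(ss.ibs_distances(matrix), k=2)
        dim1 = res.coordinates[:, 0]
        centroids = [dim1[:80].mean(), dim1[80:160].mean(), dim1[160:].mean()]
        diffs = np.diff(centroids)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_deterministic_sign_convention(self):
        from scipy.spatial.distance import squareform, pdist
        from sweepscan.downstream import DistanceMatrix

        rng = np.random.default_rng(5)
        dv = squareform(pdist(rng.normal(size=(8, 2))))
        d = DistanceMatrix(list(range(8)), dv)
        a = ss.classical_mds(d, k=2)
        b = ss.classical_mds(d, k=2)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        for axis in range(2):
            col = a.coordinates[:, axis]
            assert col[np.argmax(np.abs(col))] > 0


class TestEffectCorrelation:
    def test_perfect_antagonism(self):
        snp_map = make_snp_map(range(1, 101))
        eff = ss.simulate_effect_table(snp_map, None, 0.3, seed=1)
        eff["fertility"] = -eff["milk_yield"]
        rep = ss.effect_correlation(eff, snp_map, "milk_yield", "fertility")
        assert rep.r == pytest.approx(-1.0)

    def test_sampling_interval_at_large_n(self):
        snp_map = make_snp_map(range(1, 60_001))
        eff = ss.simulate_effect_table(snp_map, None, -0.27, seed=9)
        rep = ss.effect_correlation(eff, snp_map, "milk_yield", "fertility")
        assert rep.r == pytest.approx(-0.27, abs=0.01)
        assert rep.n_snps == 60_000
        assert rep.p_value < 1e-4

    def test_matches_two_pass_oracle(self):
        snp_map = make_snp_map(range(1, 501))
        eff = ss.simulate_effect_table(snp_map, None, -0.4, seed=2)
        rep = ss.effect_correlation(eff, snp_map, "milk_yield", "fertility")
        a = eff["milk_yield"].to_numpy()
        b = eff["fertility"].to_numpy()
        am, bm = a - a.mean(), b - b.mean()
        r_oracle = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert rep.r == pytest.approx(r_oracle, abs=1e-12)

    def test_exclusion_intervals_remove_snps(self):
        snp_map = make_snp_map(range(1, 101))
        eff = ss.simulate_effect_table(snp_map, None, 0.0, seed=3)
        rep = ss.effect_correlation(
            eff, snp_map, "milk_yield", "fertility", exclusions=[(1, 0, 50, "x")]
        )
        assert rep.n_snps == 51  # positions 1..49 excluded (half-open interval)

    def test_signature_subset_contrast_recovered(self):
        snp_map = make_snp_map(range(1, 30_001))
        intervals = [(1, 0, 6000, "sig")]
        eff = ss.simulate_effect_table(snp_map, intervals, -0.21, seed=4, inside_corr=-0.30)
        inside = ss.snp_mask_from_intervals(snp_map, intervals)
        r_in = ss.effect_correlation(eff, snp_map, "milk_yield", "fertility",
                                     subset=inside, label="signatures").r
        r_out = ss.effect_correlation(eff, snp_map, "milk_yield", "fertility",
                                      subset=~inside, label="background").r
        assert r_in < r_out

    def test_constant_vector_flagged(self):
        snp_map = make_snp_map(range(1, 11))
        eff = ss.simulate_effect_table(snp_map, None, 0.0, seed=5)
        eff["fertility"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ss.effect_correlation(eff, snp_map, "milk_yield", "fertility")


def sig(chrom, start, end):
    return SelectionSignature(chrom, start, end, (start + end) // 2, 3.5,
                              "Z_AFD", 1, ("I", "III"), "1Mb", 9)


class TestAnnotateSignatures:
    def test_contained_gene(self):
        ann, summary = annotate_signatures(
            [sig("23", 25_170_000, 27_990_000)],
            [("23", 26_000_000, 26_100_000, "BOLA-DRB2")],
        )
        hit = ann[0].hits[0]
        assert (hit.relation, hit.distance_bp) == ("contained", 0)
        assert summary["label"].iloc[0] == "contained"

    def test_gene_one_megabase_upstream_is_proximal(self):
        # a gene ~1.0 Mb upstream of the signature, within the 1.5 Mb proximity
        ann, _ = annotate_signatures(
            [sig("X", 116_000_000, 117_000_000)],
            [("X", 114_900_000, 114_999_000, "ADGRG2")],
            proximity_bp=1_500_000,
        )
        hit = ann[0].hits[0]
        assert hit.relation == "proximal"
        assert hit.distance_bp == pytest.approx(1_000_999, abs=1)

    def test_gene_beyond_proximity_ignored(self):
        ann, _ = annotate_signatures(
            [sig("1", 10_000_000, 11_000_000)],
            [("1", 13_000_000, 13_100_000, "FAR")],
            proximity_bp=1_500_000,
        )
        assert ann[0].hits == []

    def test_no_genes_empty_report(self):
        ann, summary = annotate_signatures([sig("1", 100, 200)], [])
        assert ann[0].hits == []
        assert summary["label"].iloc[0] == "none"
        assert signatures_with_hits(ann) == 0

    def test_annotation_invariant_to_gene_order(self):
        genes = [("1", 500, 600, "a"), ("1", 100, 150, "b"), ("1", 950, 1000, "c")]
        a, _ = annotate_signatures([sig("1", 400, 800)], genes, proximity_bp=300)
        b, _ = annotate_signatures([sig("1", 400, 800)], genes[::-1], proximity_bp=300)
        assert [h.gene for h in a[0].hits] == [h.gene for h in b[0].hits]
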