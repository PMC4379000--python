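import numpy as np
import pytest

import drivemap as dm
from drivemap.qtl import ScanResult


def _single_marker_map():
    return dm.GeneticMap([dm.Chromosome("2", 10.0)], [dm.Marker("m1", "2", 5.0)])


def _two_marker_map():
    return dm.GeneticMap(
        [dm.Chromosome("1", 10.0), dm.Chromosome("2", 10.0)],
        [dm.Marker("a", "1", 5.0), dm.Marker("b", "2", 5.0)],
    )


class TestTransforms:
    def test_sterile_male_transforms(self):
        phen = [dm.MalePhenotype(0, 0, 0)]
        assert dm.transform_trait(phen, "log10T1").values[0] == 0.0
        assert dm.transform_trait(phen, "binary").values[0] == 0.0

    def test_log_transform(self):
        phen = [dm.MalePhenotype(99, 50, 49)]
        assert dm.transform_trait(phen, "log10T1").values[0] == pytest.approx(2.0)

    def test_sex_ratio_eligibility_mask(self):
        phen = [dm.MalePhenotype(29, 20, 9), dm.MalePhenotype(30, 20, 10)]
        tv = dm.transform_trait(phen, "sexratio")
        assert list(tv.mask) == [False, True]
        assert tv.usable[0] == pytest.approx(2 / 3)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="transform"):
            dm.transform_trait([], "sqrtT")


class TestLodScan:
    def test_closed_form_single_marker(self):
        """Four males, doses [1,1,0,0], trait [1,2,3,4]: LOD = 2 log10 5."""
        D = np.array([[1], [1], [0], [0]])
        tv = dm.TraitVector(np.array([1.0, 2, 3, 4]), "T", np.ones(4, bool))
        scan = dm.lod_scan(D, tv, _single_marker_map())
        assert scan.lod[scan.peak()] == pytest.approx(2 * np.log10(5), abs=1e-9)

    def test_lod_invariant_to_affine_trait_transform(self):
        rng = np.random.default_rng(0)
        D = rng.integers(0, 2, size=(80, 2))
        y = D[:, 0] + rng.normal(0, 1, 80)
        a = dm.lod_scan(D, dm.TraitVector(y, "T", np.ones(80, bool)), _two_marker_map())
        b = dm.lod_scan(
            D, dm.TraitVector(3.0 * y - 7.0, "T", np.ones(80, bool)), _two_marker_map()
        )
        np.testing.assert_allclose(a.lod, b.lod, atol=1e-9)

    def test_constant_trait_rejected(self):
        D = np.array([[1], [0], [1], [0]])
        tv = dm.TraitVector(np.ones(4), "T", np.ones(4, bool))
        with pytest.raises(ValueError, match="constant"):
            dm.lod_scan(D, tv, _single_marker_map())

    def test_binary_trait_uses_logistic_lod(self):
        rng = np.random.default_rng(1)
        D = rng.integers(0, 2, size=(200, 2))
        p = 0.2 + 0.6 * D[:, 0]
        y = (rng.random(200) < p).astype(float)
        tv = dm.TraitVector(y, "binary", np.ones(200, bool))
        scan = dm.lod_scan(D, tv, _two_marker_map())
        assert scan.chrom[scan.peak()] == "1"
        assert scan.lod[scan.peak()] > 3

    def test_binary_lod_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        D = rng.integers(0, 2, size=(150, 2))
        y = (rng.random(150) < 0.3 + 0.4 * D[:, 1]).astype(float)
        tv = dm.TraitVector(y, "binary", np.ones(150, bool))
        scan = dm.lod_scan(D, tv, _two_marker_map())
        x = sm.add_constant(D[:, 1].astype(float))
        ll1 = sm.Logit(y, x).fit(disp=0).llf
        ll0 = sm.Logit(y, np.ones((150, 1))).fit(disp=0).llf
        assert scan.lod[1] == pytest.approx((ll1 - ll0) / np.log(10), abs=1e-4)

    def test_blocked_chromosome_collapses_to_one_position(self, exp2_map):
        genos = dm.simulate_mapping_population(dm.study_design("Exp2", 120), exp2_map, rng=3)
        phen_y = dm.dosage_matrix(genos)[:, 0] + np.random.default_rng(4).normal(0, 1, 120)
        tv = dm.TraitVector(phen_y, "T", np.ones(120, bool))
        scan = dm.lod_scan(genos, tv, exp2_map, cross_label="Exp2")
        on_arm = (scan.chrom == "X-3") & (scan.pos > 100.0) & (scan.pos < 200.0)
        assert on_arm.sum() == 1

    def test_peak_ties_resolve_to_smallest_position(self):
        scan = ScanResult(
            np.array(["2"] * 3, dtype=object),
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 2.0, 1.0]),
            np.zeros(3),
            "T",
            {"2": 10.0},
        )
        assert scan.pos[scan.peak()] == 1.0


class TestPermutationThreshold:
    def test_cutoff_is_upper_quantile_and_reproducible(self):
        rng = np.random.default_rng(5)
        D = rng.integers(0, 2, size=(100, 2))
        tv = dm.TraitVector(rng.normal(0, 1, 100), "T", np.ones(100, bool))
        t1 = dm.permutation_threshold(D, tv, _two_marker_map(), n_perm=100, rng=7)
        t2 = dm.permutation_threshold(D, tv, _two_marker_map(), n_perm=100, rng=7)
        assert t1.cutoff == t2.cutoff
        assert t1.cutoff == pytest.approx(np.quantile(t1.max_lods, 0.95), abs=1e-12)
        assert len(t1.max_lods) == 100

    def test_alpha_one_gives_sample_minimum(self):
        rng = np.random.default_rng(6)
        D = rng.integers(0, 2, size=(60, 2))
        tv = dm.TraitVector(rng.normal(0, 1, 60), "T", np.ones(60, bool))
        thr = dm.permutation_threshold(D, tv, _two_marker_map(), n_perm=50, alpha=1.0, rng=8)
        assert thr.cutoff == pytest.approx(thr.max_lods.min())

    def test_constant_trait_error_propagates(self):
        D = np.array([[1], [0], [1], [0]])
        tv = dm.TraitVector(np.ones(4), "T", np.ones(4, bool))
        with pytest.raises(ValueError, match="constant"):
            dm.permutation_threshold(D, tv, _single_marker_map(), n_perm=10, rng=9)


class TestSupportInterval:
    def test_unimodal_curve_contains_peak(self):
        pos = np.arange(0.0, 11.0)
        lod = 5.0 - 0.5 * np.abs(pos - 5.0)
        scan = ScanResult(np.array(["2"] * 11, dtype=object), pos, lod, np.zeros(11), "T", {"2": 10.0})
        iv = dm.support_interval(scan)
        assert iv.start_cM <= iv.peak_cM <= iv.end_cM
        assert iv.peak_cM == 5.0
        assert iv.start_cM == 2.0 and iv.end_cM == 8.0  # LOD >= peak - 1.5 at slope 0.5

    def test_flat_profile_spans_whole_chromosome(self):
        scan = ScanResult(
            np.array(["2"] * 5, dtype=object),
            np.arange(2.0, 7.0),
            np.full(5, 3.0),
            np.zeros(5),
            "T",
            {"2": 20.0},
        )
        iv = dm.support_interval(scan)
        assert iv.U == 1.0

    def test_interval_width_shrinks_with_sample_size(self, exp2_map):
        widths = []
        for n in (80, 640):
            genos = dm.simulate_mapping_population(dm.study_design("Exp2", n), exp2_map, rng=10)
            D = dm.dosage_matrix(genos)
            idx = exp2_map.marker_index("X3_05")
            y = 1.2 * D[:, idx] + np.random.default_rng(n).normal(0, 1, n)
            scan = dm.lod_scan(genos, dm.TraitVector(y, "T", np.ones(n, bool)), exp2_map, cross_label="Exp2")
            widths.append(dm.support_interval(scan, scan.peak("X-3")).U)
        assert widths[1] < widths[0]


class TestMultiQtl:
    def test_pure_additive_trait_fully_explained(self):
        rng = np.random.default_rng(11)
        D = rng.integers(0, 2, size=(120, 2))
        y = D[:, 0] + D[:, 1]
        tv = dm.TraitVector(y.astype(float), "T", np.ones(120, bool))
        vc = dm.fit_multi_qtl(D, tv, [("1", 5.0), ("2", 5.0)], _two_marker_map())
        assert vc.h2 == pytest.approx(1.0, abs=1e-9)
        assert vc.H2 == pytest.approx(1.0, abs=1e-9)

    def test_xor_trait_is_pure_epistasis(self):
        rng = np.random.default_rng(12)
        D = rng.integers(0, 2, size=(200, 2))
        y = (D[:, 0] ^ D[:, 1]).astype(float)
        tv = dm.TraitVector(y, "T", np.ones(200, bool))
        vc = dm.fit_multi_qtl(D, tv, [("1", 5.0), ("2", 5.0)], _two_marker_map(), epistasis=True)
        assert vc.H2 == pytest.approx(1.0, abs=1e-9)
        assert vc.h2 < 0.05

    def test_variance_components_bounded(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            D = rng.integers(0, 2, size=(60, 2))
            y = rng.normal(0, 1, 60) + rng.uniform(0, 1) * D[:, 0]
            tv = dm.TraitVector(y, "T", np.ones(60, bool))
            vc = dm.fit_multi_qtl(D, tv, [("1", 5.0), ("2", 5.0)], _two_marker_map(), epistasis=True)
            assert 0.0 <= vc.h2 <= vc.H2 <= 1.0

    def test_empty_locus_list_rejected(self, exp2_map):
        tv = dm.TraitVector(np.ones(3), "T", np.ones(3, bool))
        with pytest.raises(ValueError, match="no loci"):
            dm.fit_multi_qtl(np.zeros((3, exp2_map.n_markers)), tv, [], exp2_map)


def test_single_locus_scan_localizes_true_position(exp2_map):
    """A 1-SD additive locus at n=200 peaks near its true location."""
    hits = 0
    for rep in range(12):
        genos = dm.simulate_mapping_population(dm.study_design("Exp2", 200), exp2_map, rng=100 + rep)
        D = dm.dosage_matrix(genos)
        idx = exp2_map.marker_index("2_10")
        true_pos = exp2_map.markers[idx].position
        y = 2.0 * D[:, idx] + np.random.default_rng(200 + rep).normal(0, 1, 200)
        scan = dm.lod_scan(genos, dm.TraitVector(y, "T", np.ones(200, bool)), exp2_map, cross_label="Exp2")
        pk = scan.peak()
        if scan.chrom[pk] == "2" and abs(scan.pos[pk] - true_pos) <= 15.0:
            hits += 1
    assert hits >= 10


def test_cofactor_scan_runs_and_keeps_peak(exp2_map):
    genos = dm.simulate_mapping_population(dm.study_design("Exp2", 150), exp2_map, rng=14)
    D = dm.dosage_matrix(genos)
    idx = exp2_map.marker_index("2_10")
    y = 1.5 * D[:, idx] + np.random.default_rng(15).normal(0, 1, 150)
    tv = dm.TraitVector(y, "T", np.ones(150, bool))
    scan = dm.lod_scan(genos, tv, exp2_map, cross_label="Exp2", n_cofactors=3)
    pk = scan.peak()
    assert scan.chrom[pk] == "2"
    assert abs(scan.pos[pk] - exp2_map.markers[idx].position) <= 20.0
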