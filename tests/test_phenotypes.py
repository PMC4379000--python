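import numpy as np
import pytest

import drivemap as dm
from drivemap.phenotypes import daily_weights, model_from_yaml, model_to_yaml


def _introgression(gmap, loci, model, homozygous=()):
    from drivemap.pipeline import simulate_introgression_group

    grp = simulate_introgression_group("g", loci, model, gmap, 1, np.random.default_rng(0), set(homozygous))
    # rebuild the genotype deterministically for expectation checks
    by_name = {l.name: l for l in model.loci}
    segs = []
    for nm in loci:
        loc = by_name[nm]
        pm = gmap.positions(loc.chromosome)
        c = float(pm[np.argmin(np.abs(pm - loc.position))])
        segs.append(
            dm.IntrogressionSegment(loc.chromosome, c - 2, c + 2, loc.line, nm in homozygous)
        )
    return dm.make_introgression_genotype(dm.IntrogressionSpec(segs), gmap)


def test_no_distorters_gives_mendelian_ratio_exactly(exp2_map, effect_model):
    ctrl = dm.make_introgression_genotype(dm.IntrogressionSpec([]), exp2_map)
    assert dm.expected_sex_ratio(ctrl, effect_model, exp2_map) == 0.5


def test_f1_like_genotype_expresses_strong_drive(exp2_map, effect_model, f1_like):
    k = dm.expected_sex_ratio(f1_like, effect_model, exp2_map)
    assert abs(k - 0.92) < 0.01


def test_three_distorter_genotype_near_published_ratio(exp2_map, effect_model):
    g = _introgression(exp2_map, ["D2", "D3", "D4"], effect_model)
    k = dm.expected_sex_ratio(g, effect_model, exp2_map)
    assert abs(k - 0.86) < 0.01


def test_sex_ratio_bounded_below_one(exp2_map, f1_like):
    model = dm.default_effect_model()
    huge = dm.EffectModel(
        [dm.Locus("D", "X-3", 20.0, drive=1e6)], [], k_max_excess=model.k_max_excess
    )
    k = dm.expected_sex_ratio(f1_like, huge, exp2_map)
    assert 0.5 <= k < 1.0


def test_suppressor_dose_monotonicity(exp2_map, effect_model):
    k0 = dm.expected_sex_ratio(_introgression(exp2_map, ["D2", "D3", "D4"], effect_model), effect_model, exp2_map)
    k1 = dm.expected_sex_ratio(_introgression(exp2_map, ["D2", "D3", "D4", "S3"], effect_model), effect_model, exp2_map)
    k2 = dm.expected_sex_ratio(
        _introgression(exp2_map, ["D2", "D3", "D4", "S3"], effect_model, homozygous=("S3",)),
        effect_model,
        exp2_map,
    )
    # one-copy/two-copy ordering of semidominant suppression
    assert k0 > k1 > k2 >= 0.5


def test_insensitive_y_responder_silences_drive(exp2_map, effect_model, f1_like):
    import dataclasses

    insensitive = dataclasses.replace(effect_model, y_sensitive=False)
    assert dm.expected_sex_ratio(f1_like, insensitive, exp2_map) == 0.5


class TestFertility:
    def test_background_genotype_fully_fertile(self, exp2_map, effect_model):
        ctrl = dm.make_introgression_genotype(dm.IntrogressionSpec([]), exp2_map)
        p_st, mu, theta = dm.fertility_distribution(ctrl, effect_model, exp2_map)
        assert p_st < 0.05
        assert abs(mu - 115) < 1
        assert theta > 0

    def test_d1_alone_nearly_sterilizing(self, exp2_map, effect_model):
        g = _introgression(exp2_map, ["D1"], effect_model)
        p_st, mu, _ = dm.fertility_distribution(g, effect_model, exp2_map)
        assert p_st > 0.95

    def test_s3_rescues_fertility(self, exp2_map, effect_model):
        for base in (["D1"], ["D2", "D3", "D4"]):
            p0, mu0, _ = dm.fertility_distribution(
                _introgression(exp2_map, base, effect_model), effect_model, exp2_map
            )
            p1, mu1, _ = dm.fertility_distribution(
                _introgression(exp2_map, base + ["S3"], effect_model), effect_model, exp2_map
            )
            assert p1 <= p0 and mu1 >= mu0


def test_null_model_recovers_baseline_means(exp2_map):
    null = dm.EffectModel([], [], mu0=100.0, theta=8.0, sterility_logodds0=-20.0)
    ctrl = dm.make_introgression_genotype(dm.IntrogressionSpec([]), exp2_map)
    phen = dm.simulate_phenotypes([ctrl] * 1000, null, exp2_map, rng=5)
    T = np.array([p.T for p in phen])
    k = np.array([p.k for p in phen if p.T > 0])
    assert abs(T.mean() - 100) < 4 * 100 / np.sqrt(8 * 1000) * 2
    assert abs(k.mean() - 0.5) < 0.01


def test_phenotypes_reproducible_under_seed(exp2_population, exp2_map, effect_model):
    genotypes, _ = exp2_population
    a = dm.simulate_phenotypes(genotypes[:50], effect_model, exp2_map, rng=7)
    b = dm.simulate_phenotypes(genotypes[:50], effect_model, exp2_map, rng=7)
    assert all(pa == pb for pa, pb in zip(a, b))


def test_phenotype_count_invariant():
    with pytest.raises(ValueError, match="females"):
        dm.MalePhenotype(10, 4, 5)
    assert dm.MalePhenotype(0, 0, 0).k is None


class TestVialSeries:
    def test_vial_counts_sum_to_T(self):
        phen = dm.MalePhenotype(137, 90, 47)
        series = dm.simulate_vial_series(phen, rng=1)
        assert series.true_total() == 137
        assert sum(v.females for v in series.vials) == 90

    def test_sterile_male_gives_empty_series(self):
        series = dm.simulate_vial_series(dm.MalePhenotype(0, 0, 0), rng=2)
        assert series.true_total() == 0

    def test_schedule_marks_one_day_vials_counted(self):
        series = dm.simulate_vial_series(dm.MalePhenotype(200, 120, 80), rng=3)
        for v in series.vials:
            if v.n_days == 1 and v.start_day in (1, 2, 3, 8, 13, 18):
                assert v.counted
            if v.n_days == 4:
                assert not v.counted

    def test_capacity_censoring_caps_every_vial(self):
        proto = dm.ProtocolConfig(vial_capacity=20)
        series = dm.simulate_vial_series(dm.MalePhenotype(900, 500, 400), proto, rng=4)
        assert max(v.total for v in series.vials) <= 20

    def test_linear_decay_weights_decline_to_zero(self):
        w = daily_weights(10, "linear")
        assert np.all(np.diff(w) < 0)
        assert abs(w.sum() - 1) < 1e-12
        with pytest.raises(ValueError, match="decay"):
            daily_weights(10, "cubic")


def test_effect_model_yaml_round_trip(effect_model):
    back = model_from_yaml(model_to_yaml(effect_model))
    assert back == effect_model


def test_effect_model_invariants():
    with pytest.raises(ValueError):
        dm.EffectModel([], [], k_max_excess=0.6)
    with pytest.raises(ValueError):
        dm.EffectModel([], [], mu0=-1)
    with pytest.raises(ValueError):
        dm.Locus("x", "2", 1.0, drive=-0.1)
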