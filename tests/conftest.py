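import numpy as np
import pytest

import drivemap as dm


@pytest.fixture(scope="session")
def exp2_map():
    return dm.build_study_map("Exp2")


@pytest.fixture(scope="session")
def effect_model():
    return dm.default_effect_model()


@pytest.fixture(scope="session")
def exp2_population(exp2_map, effect_model):
    """A seeded mid-size Exp2 backcross population with phenotypes."""
    design = dm.study_design("Exp2", 250)
    genotypes = dm.simulate_mapping_population(design, exp2_map, rng=101)
    phenotypes = dm.simulate_phenotypes(genotypes, effect_model, exp2_map, rng=102)
    return genotypes, phenotypes


def make_genotype(gmap, maternal_line_at=None, default_maternal="nas314", paternal="nas314"):
    """Build a male whose maternal allele is `maternal_line_at[marker_index]`."""
    n = gmap.n_markers
    maternal = np.full(n, default_maternal, dtype=object)
    if maternal_line_at:
        for idx, line in maternal_line_at.items():
            maternal[idx] = line
    pat = np.full(n, paternal, dtype=object)
    xmask = np.array([m.chromosome == "X-3" for m in gmap.markers])
    return dm.MaleGenotype(maternal, pat, xmask)


@pytest.fixture()
def f1_like(exp2_map):
    n = exp2_map.n_markers
    xmask = np.array([m.chromosome == "X-3" for m in exp2_map.markers])
    return dm.MaleGenotype(
        np.full(n, "alb267", dtype=object), np.full(n, "nas314", dtype=object), xmask
    )
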