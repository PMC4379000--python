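"""Calibration experiments for the scan machinery.

Two simulation studies back the mapping pipeline: a null study measuring the
genome-wide type-I error of the permutation threshold, and a parameter-
recovery study checking that the multi-locus fit recovers a known additive
variance fraction and that all simulated architecture regions are detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crosses import CrossDesign, dosage_matrix, simulate_mapping_population
from .genome import Chromosome, GeneticMap, InversionRegion, Marker
from .pipeline import stage_seed
from .qtl import TraitVector, fit_multi_qtl, lod_scan, permutation_threshold

__all__ = ["null_rejection_rate", "Recovery", "h2_recovery_experiment", "small_backcross_map"]


def small_backcross_map(n_markers: int = 40) -> GeneticMap:
    """A reduced backcross map (X-3 with blocked arm, chr2, chr4).

    Marker counts scale the full design down while keeping the chromosome
    proportions; used for simulation studies where marker density is not the
    question.
    """
    n_x = max(n_markers // 5, 2)
    n_3 = max(n_markers // 5, 2)
    n_2 = n_markers - n_x - n_3 - max(n_markers // 8, 1)
    n_4 = n_markers - n_x - n_3 - n_2
    def grid(start, span, n):
        return start + (np.arange(n) + 0.5) * span / n
    markers = (
        [Marker(f"x{i}", "X-3", p) for i, p in enumerate(grid(0, 100, n_x))]
        + [Marker(f"t{i}", "X-3", p) for i, p in enumerate(grid(100, 100, n_3))]
        + [Marker(f"a{i}", "2", p) for i, p in enumerate(grid(0, 120, n_2))]
        + [Marker(f"f{i}", "4", p) for i, p in enumerate(grid(0, 20, n_4))]
    )
    return GeneticMap(
        [Chromosome("X-3", 200.0, True), Chromosome("2", 120.0), Chromosome("4", 20.0)],
        markers,
        [InversionRegion("X-3", 100.0, 200.0, frozenset({"Exp2", "Exp3"}))],
    )


def null_rejection_rate(
    n_sims: int = 200,
    n_males: int = 200,
    n_markers: int = 40,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null simulations whose genome-wide max LOD exceeds the
    permutation cutoff: the empirical type-I error of the threshold.

    Traits are standard normal, independent of all genotypes, over freshly
    simulated backcross populations.
    """
    gmap = small_backcross_map(n_markers)
    design = CrossDesign("Exp2", ("alb267", "nas314"), "nas314", n_males)
    rejections = 0
    for s in range(n_sims):
        rng = np.random.default_rng(stage_seed(seed, f"null-{s}"))
        genos = simulate_mapping_population(design, gmap, rng)
        y = rng.normal(0.0, 1.0, n_males)
        trait = TraitVector(y, "T", np.ones(n_males, bool))
        scan = lod_scan(genos, trait, gmap, cross_label="Exp2")
        thr = permutation_threshold(
            genos, trait, gmap, n_perm, alpha, rng, cross_label="Exp2"
        )
        rejections += scan.max_lod() > thr.cutoff
    return rejections / n_sims


@dataclass
class Recovery:
    h2_estimates: np.ndarray
    detection_rate: dict[str, float]

    @property
    def mean_h2(self) -> float:
        return float(self.h2_estimates.mean())


def h2_recovery_experiment(
    n_reps: int = 50,
    n_males: int = 442,
    true_h2: float = 0.64,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    window_cM: float = 15.0,
) -> Recovery:
    """Recover a known additive variance fraction from simulated scans.

    Each replicate simulates a backcross population whose sex-ratio-like
    trait is the additive sum of four loci (two on the recombining X arm, two
    on chromosome 2) plus Gaussian noise scaled so the realized additive
    variance fraction equals ``true_h2``. The multi-locus fit at the true
    positions estimates h2; a locus counts as detected when the scan's max
    LOD within ``window_cM`` of it clears the genome-wide permutation cutoff.
    """
    from .genome import build_study_map

    gmap = build_study_map("Exp2")
    loci_names = ["X3_03", "X3_10", "2_08", "2_20"]
    loci = [
        (gmap.markers[gmap.marker_index(nm)].chromosome, gmap.markers[gmap.marker_index(nm)].position)
        for nm in loci_names
    ]
    idx = [gmap.marker_index(nm) for nm in loci_names]
    design = CrossDesign("Exp2", ("alb267", "nas314"), "nas314", n_males)
    h2s = np.empty(n_reps)
    detected = {nm: 0 for nm in loci_names}
    for rep in range(n_reps):
        rng = np.random.default_rng(stage_seed(seed, f"recovery-{rep}"))
        genos = simulate_mapping_population(design, gmap, rng)
        D = dosage_matrix(genos).astype(float)
        g = D[:, idx].sum(axis=1)
        vg = g.var()
        noise = rng.normal(0.0, np.sqrt(vg * (1.0 - true_h2) / true_h2), n_males)
        trait = TraitVector(g + noise, "T", np.ones(n_males, bool))
        h2s[rep] = fit_multi_qtl(genos, trait, loci, gmap, cross_label="Exp2").h2
        scan = lod_scan(genos, trait, gmap, cross_label="Exp2")
        cutoff = permutation_threshold(
            genos, trait, gmap, n_perm, alpha, rng, cross_label="Exp2"
        ).cutoff
        for nm, (chrom, pos) in zip(loci_names, loci):
            near = (scan.chrom == chrom) & (np.abs(scan.pos - pos) <= window_cM)
            if scan.lod[near].max() > cutoff:
                detected[nm] += 1
    return Recovery(h2s, {nm: detected[nm] / n_reps for nm in loci_names})
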