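"""Mapping-population and introgression genotypes.

Males in the three mapping designs are produced by crossing heterozygous F1
females to males of a recurrent paternal line, so each male carries one
maternal recombinant gamete plus the paternal line's alleles. The fused X-3
is hemizygous in males (the maternal gamete is the only copy). Alleles are
symbolic line labels (``alb267``, ``shl2-hap1``, ``nas314``), which is all
interval mapping and genotype contrasts need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GeneticMap, sample_gametes

__all__ = [
    "CrossDesign",
    "MaleGenotype",
    "IntrogressionSegment",
    "IntrogressionSpec",
    "study_design",
    "simulate_mapping_population",
    "make_introgression_genotype",
    "dosage_matrix",
]


@dataclass(frozen=True)
class CrossDesign:
    """One mapping cross: F1 (maternal_haplotypes) females x paternal_line males."""

    label: str
    maternal_haplotypes: tuple[str, str]
    paternal_line: str
    n_males: int

    def __post_init__(self) -> None:
        if self.n_males <= 0:
            raise ValueError("n_males must be positive")
        if self.maternal_haplotypes[0] == self.maternal_haplotypes[1]:
            raise ValueError("maternal haplotypes must be distinct lines")


#: the three mapping designs: (maternal F1 haplotypes, tester sires, population size)
_STUDY_DESIGNS = {
    "Exp1": (("alb267", "shl2-hap1"), "nas314", 459),
    "Exp2": (("alb267", "nas314"), "nas314", 442),
    "Exp3": (("shl2-hap1", "nas314"), "nas314", 470),
}


def study_design(label: str, n_males: int | None = None) -> CrossDesign:
    """The published cross design for a label, optionally resized."""
    if label not in _STUDY_DESIGNS:
        raise ValueError(f"unknown design label {label!r}")
    haps, sire, n = _STUDY_DESIGNS[label]
    return CrossDesign(label, haps, sire, n if n_males is None else n_males)


@dataclass
class MaleGenotype:
    """One male: maternal gamete vector + paternal vector over map markers.

    ``x_linked`` masks the sex-linked X-3 markers, where males are hemizygous
    and only the maternal allele exists.
    """

    maternal: np.ndarray
    paternal: np.ndarray
    x_linked: np.ndarray

    @property
    def x3_alleles(self) -> np.ndarray:
        return self.maternal[self.x_linked]

    def autosomal_pairs(self) -> np.ndarray:
        """(n_autosomal_markers, 2) array of (maternal, paternal) alleles."""
        return np.stack(
            [self.maternal[~self.x_linked], self.paternal[~self.x_linked]], axis=1
        )

    def dose(self, focal_line: str) -> np.ndarray:
        """Copies of the focal line's allele per marker (X-3 counts 0/1)."""
        d = (self.maternal == focal_line).astype(int)
        d = d + np.where(self.x_linked, 0, (self.paternal == focal_line).astype(int))
        return d


def _x_mask(gmap: GeneticMap) -> np.ndarray:
    sex = {c.name for c in gmap.chromosomes if c.is_sex_linked}
    return np.array([m.chromosome in sex for m in gmap.markers])


def simulate_mapping_population(
    design: CrossDesign,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
) -> list[MaleGenotype]:
    """Draw ``design.n_males`` backcross males.

    Maternal contributions are recombinant F1 gametes sampled under the map
    (inversion suppression applies for the design's cross label); the paternal
    contribution is the paternal line everywhere.
    """
    rng = np.random.default_rng(rng)
    n_mark = gmap.n_markers
    hap_a = np.full(n_mark, design.maternal_haplotypes[0], dtype=object)
    hap_b = np.full(n_mark, design.maternal_haplotypes[1], dtype=object)
    gametes = sample_gametes(
        (hap_a, hap_b), gmap, design.n_males, cross_label=design.label, rng=rng
    )
    paternal = np.full(n_mark, design.paternal_line, dtype=object)
    xmask = _x_mask(gmap)
    return [MaleGenotype(gametes[i], paternal.copy(), xmask) for i in range(design.n_males)]


@dataclass(frozen=True)
class IntrogressionSegment:
    chromosome: str
    start_cM: float
    end_cM: float
    donor: str
    homozygous: bool = False

    def __post_init__(self) -> None:
        if self.start_cM > self.end_cM:
            raise ValueError("segment start_cM > end_cM")


@dataclass
class IntrogressionSpec:
    """Donor segments retained in an otherwise uniform background line."""

    retained_segments: list[IntrogressionSegment] = field(default_factory=list)
    background: str = "nas314"


def make_introgression_genotype(spec: IntrogressionSpec, gmap: GeneticMap) -> MaleGenotype:
    """Deterministic genotype of a marker-assisted introgression male.

    Donor alleles appear exactly inside the retained segments (half-open cM
    intervals); everywhere else both alleles are the background line. Donor
    segments are hemizygous on the X-3 and heterozygous on autosomes unless
    the segment is flagged homozygous.
    """
    by_chrom: dict[str, list[IntrogressionSegment]] = {}
    for seg in spec.retained_segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start_cM)
        for a, b in zip(segs, segs[1:]):
            if b.start_cM < a.end_cM:
                raise ValueError("overlapping introgression segments on one chromosome")
    maternal = np.full(gmap.n_markers, spec.background, dtype=object)
    paternal = np.full(gmap.n_markers, spec.background, dtype=object)
    for i, m in enumerate(gmap.markers):
        for seg in by_chrom.get(m.chromosome, []):
            if seg.start_cM <= m.position < seg.end_cM:
                maternal[i] = seg.donor
                if seg.homozygous:
                    paternal[i] = seg.donor
    return MaleGenotype(maternal, paternal, _x_mask(gmap))


def dosage_matrix(
    genotypes: list[MaleGenotype], focal_line: str = "alb267"
) -> np.ndarray:
    """(n_males, n_markers) focal-allele dose matrix for mapping."""
    return np.stack([g.dose(focal_line) for g in genotypes])
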