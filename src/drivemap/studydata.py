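"""Published summary values used as analysis inputs.

These are printed study results (QTL interval widths, introgression sex
ratios, mapping-design sizes) that downstream calculations take as inputs —
they are data, not free parameters of this package.
"""

from __future__ import annotations

#: 95% support-interval widths of the six QTL, as fractions of their
#: chromosome's map length: the four X-3 distorter regions (D1-D4) and the
#: two second-chromosome suppressor regions (S3, S4).
QTL_INTERVAL_WIDTHS: dict[str, list[float]] = {
    "X-3": [0.037, 0.038, 0.111, 0.054],  # D1, D2, D3, D4
    "2": [0.040, 0.255],                  # S3, S4
}

#: Sex ratios of the three-distorter genotype at 0, 1 and 2 copies of the
#: S3 suppressor — the series behind S3's semidominance classification.
S3_DOMINANCE_SEX_RATIOS: tuple[float, float, float] = (0.864, 0.695, 0.601)

#: Mapping designs: (population size, genotyped marker count).
DESIGN_SIZES: dict[str, tuple[int, int]] = {
    "Exp1": (459, 62),
    "Exp2": (442, 67),
    "Exp3": (470, 39),
}

#: Exp2 additive variance fraction (h2) for sex ratio from the multi-locus
#: fit, used as the ground truth of the parameter-recovery simulation.
EXP2_SEXRATIO_H2: float = 0.64

#: Control introgression genotype: mean offspring count of the all-background
#: line, and the F1-male sex ratio with the full distorter complement.
CONTROL_MEAN_OFFSPRING: float = 114.9
F1_SEX_RATIO: float = 0.92
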