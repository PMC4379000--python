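"""Genetic maps with recombination-suppressed regions, and gamete sampling.

The study system is a Drosophila nasuta/albomicans hybrid cross. D. albomicans
carries a Robertsonian X-3 fusion, so the X and the ancestral third chromosome
segregate as one sex-linked element; heterozygosity for fixed inversions on the
chromosome-3 arm suppresses recovery of recombinants across that arm in crosses
to D. nasuta. Maps are in centimorgans, 0-based from the chromosome start;
intervals are half-open ``[start, end)``. Recombination uses the Haldane map
function (no interference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Marker",
    "InversionRegion",
    "Chromosome",
    "GeneticMap",
    "build_study_map",
    "haldane_r",
    "sample_gamete",
    "sample_gametes",
    "map_to_json",
    "map_from_json",
]

STUDY_DESIGNS = ("Exp1", "Exp2", "Exp3")


@dataclass(frozen=True)
class Marker:
    """A mapped marker: name, chromosome, map position in cM (non-negative)."""

    name: str
    chromosome: str
    position: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"marker {self.name}: negative cM position")


@dataclass(frozen=True)
class InversionRegion:
    """A map interval where inversion heterozygosity blocks recombination.

    ``active_in`` lists the cross labels in which the region is heterozygous
    for the inversion and therefore refractory to recombination.
    """

    chromosome: str
    start_cM: float
    end_cM: float
    active_in: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start_cM > self.end_cM:
            raise ValueError("inversion start_cM > end_cM")

    def is_active(self, cross_label: str | None) -> bool:
        return cross_label is not None and cross_label in self.active_in

    def contains(self, position: float) -> bool:
        return self.start_cM <= position < self.end_cM


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cM: float
    is_sex_linked: bool = False


@dataclass
class GeneticMap:
    """Ordered chromosomes, markers and inversion regions.

    Markers are kept sorted by (chromosome order, position); marker names are
    unique genome-wide. The sex-linked element (X-3) is hemizygous in males.
    """

    chromosomes: list[Chromosome]
    markers: list[Marker] = field(default_factory=list)
    inversions: list[InversionRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = {c.name: i for i, c in enumerate(self.chromosomes)}
        if len(order) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for m in self.markers:
            if m.chromosome not in order:
                raise ValueError(f"marker {m.name} on unknown chromosome {m.chromosome}")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique genome-wide")
        self.markers = sorted(self.markers, key=lambda m: (order[m.chromosome], m.position))
        for c in self.chromosomes:
            pos = [m.position for m in self.markers if m.chromosome == c.name]
            if pos and max(pos) > c.length_cM:
                raise ValueError(f"marker beyond the {c.name} map span")
        for inv in self.inversions:
            if inv.chromosome not in order:
                raise ValueError("inversion on unknown chromosome")

    # -- lookups -------------------------------------------------------------

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def marker_index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise KeyError(name)

    def chromosome_slice(self, name: str) -> slice:
        """Contiguous slice of the sorted marker list lying on ``name``."""
        idx = [i for i, m in enumerate(self.markers) if m.chromosome == name]
        if not idx:
            return slice(0, 0)
        return slice(idx[0], idx[-1] + 1)

    def positions(self, name: str) -> np.ndarray:
        return np.array([m.position for m in self.markers if m.chromosome == name])

    def active_inversions(self, chromosome: str, cross_label: str | None) -> list[InversionRegion]:
        return [
            inv
            for inv in self.inversions
            if inv.chromosome == chromosome and inv.is_active(cross_label)
        ]


# -- study maps ---------------------------------------------------------------

# Fig-4-style linkage groups: the fused X-3 (X arm then chromosome-3 arm),
# the large second chromosome, and the small fourth. Lengths in cM.
_X_ARM = 100.0
_C3_ARM = 100.0
_CHROM_LAYOUT = [
    Chromosome("X-3", _X_ARM + _C3_ARM, is_sex_linked=True),
    Chromosome("2", 120.0),
    Chromosome("4", 20.0),
]

# marker counts per design: (X arm, chr-3 arm, chr2, chr4)
_DESIGN_MARKERS = {
    "Exp1": (15, 15, 26, 6),  # 62 informative alb267/shl2-hap1 markers
    "Exp2": (14, 18, 29, 6),  # 67 alb267/nas314 markers
    "Exp3": (14, 3, 18, 4),   # 39 informative shl2-hap1/nas314 markers
}


def _grid(start: float, span: float, n: int) -> np.ndarray:
    """Even marker grid: n positions centred on equal cells of [start, start+span)."""
    return start + (np.arange(n) + 0.5) * span / n


def build_study_map(
    design_label: str,
    *,
    positions: dict[str, np.ndarray] | None = None,
) -> GeneticMap:
    """Genetic map for one of the three mapping designs.

    Exp1 segregates two D. albomicans complements (alb267 vs shl2-hap1) and
    recombines freely everywhere. Exp2 and Exp3 segregate a D. albomicans
    complement against D. nasuta (nas314); their F1 females are inversion
    heterozygotes over the chromosome-3 arm of the X-3, so that arm is
    modelled as a single recombination-suppressed block.

    Default per-marker positions are an even grid per arm; pass ``positions``
    (chromosome name -> cM array) to override.
    """
    if design_label not in _DESIGN_MARKERS:
        raise ValueError(f"unknown design label {design_label!r}; expected one of {STUDY_DESIGNS}")
    n_x, n_3, n_2, n_4 = _DESIGN_MARKERS[design_label]
    if positions is None:
        positions = {
            "X-3": np.concatenate([_grid(0.0, _X_ARM, n_x), _grid(_X_ARM, _C3_ARM, n_3)]),
            "2": _grid(0.0, 120.0, n_2),
            "4": _grid(0.0, 20.0, n_4),
        }
    markers: list[Marker] = []
    for chrom in ("X-3", "2", "4"):
        tag = chrom.replace("-", "")
        for i, pos in enumerate(positions[chrom], start=1):
            markers.append(Marker(f"{tag}_{i:02d}", chrom, float(pos)))
    inversions = [
        InversionRegion("X-3", _X_ARM, _X_ARM + _C3_ARM, frozenset({"Exp2", "Exp3"}))
    ]
    return GeneticMap(list(_CHROM_LAYOUT), markers, inversions)


# -- meiosis ------------------------------------------------------------------


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _interval_recomb(
    gmap: GeneticMap,
    chromosome: str,
    pos: np.ndarray,
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cross_label: str | None,
    inversion_leak: float,
) -> np.ndarray:
    """Per-interval recombination fractions, with active inversions blocked.

    An interval's map length inside a heterozygous active inversion does not
    contribute recombinants (beyond ``inversion_leak``); only markers actually
    heterozygous inside the region trigger suppression.
    """
    d = np.diff(pos)
    eff = d.copy()
    for inv in gmap.active_inversions(chromosome, cross_label):
        inside = (pos >= inv.start_cM) & (pos < inv.end_cM)
        if not np.any(hap_a[inside] != hap_b[inside]):
            continue  # homozygous across the region: nothing to suppress
        lo = np.maximum(pos[:-1], inv.start_cM)
        hi = np.minimum(pos[1:], inv.end_cM)
        overlap = np.clip(hi - lo, 0.0, None)
        eff = eff - overlap * (1.0 - inversion_leak)
    return np.asarray(haldane_r(np.clip(eff, 0.0, None)))


def sample_gametes(
    haplotype_pair: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    n: int,
    *,
    cross_label: str | None = None,
    rng: np.random.Generator | int | None = None,
    inversion_leak: float = 0.0,
) -> np.ndarray:
    """Sample ``n`` recombinant gametes from a heterozygous female.

    Haplotypes are allele vectors over the map's sorted marker list. Crossover
    placement follows the Haldane map function per marker interval; within any
    inversion region active for ``cross_label`` and heterozygous, the gamete
    is non-recombinant (up to ``inversion_leak``). Each chromosome starts from
    either haplotype with probability 1/2, so every marker transmits each
    allele with marginal probability 1/2.
    """
    hap_a = np.asarray(haplotype_pair[0])
    hap_b = np.asarray(haplotype_pair[1])
    if hap_a.shape != hap_b.shape or hap_a.shape[0] != gmap.n_markers:
        raise ValueError("haplotypes must both cover all map markers")
    rng = np.random.default_rng(rng)
    choose_b = np.empty((n, gmap.n_markers), dtype=bool)
    for chrom in gmap.chromosomes:
        sl = gmap.chromosome_slice(chrom.name)
        m = sl.stop - sl.start
        if m == 0:
            continue
        pos = gmap.positions(chrom.name)
        r = _interval_recomb(
            gmap, chrom.name, pos, hap_a[sl], hap_b[sl], cross_label, inversion_leak
        )
        start = rng.random(n) < 0.5
        if m > 1:
            switches = rng.random((n, m - 1)) < r
            state = np.cumsum(switches, axis=1) % 2
            choose_b[:, sl] = np.concatenate(
                [start[:, None], state.astype(bool) ^ start[:, None]], axis=1
            )
        else:
            choose_b[:, sl] = start[:, None]
    return np.where(choose_b, hap_b[None, :], hap_a[None, :])


def sample_gamete(
    haplotype_pair: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    *,
    cross_label: str | None = None,
    rng: np.random.Generator | int | None = None,
    inversion_leak: float = 0.0,
) -> np.ndarray:
    """Single-gamete convenience wrapper around :func:`sample_gametes`."""
    return sample_gametes(
        haplotype_pair, gmap, 1, cross_label=cross_label, rng=rng, inversion_leak=inversion_leak
    )[0]


# -- serialization ------------------------------------------------------------


def map_to_json(gmap: GeneticMap) -> str:
    obj = {
        "chromosomes": [
            {"name": c.name, "length_cM": c.length_cM, "is_sex_linked": c.is_sex_linked}
            for c in gmap.chromosomes
        ],
        "markers": [
            {"name": m.name, "chromosome": m.chromosome, "position": m.position}
            for m in gmap.markers
        ],
        "inversions": [
            {
                "chromosome": v.chromosome,
                "start_cM": v.start_cM,
                "end_cM": v.end_cM,
                "active_in": sorted(v.active_in),
            }
            for v in gmap.inversions
        ],
    }
    return json.dumps(obj, indent=1)


def map_from_json(text: str) -> GeneticMap:
    obj = json.loads(text)
    return GeneticMap(
        [Chromosome(c["name"], c["length_cM"], c["is_sex_linked"]) for c in obj["chromosomes"]],
        [Marker(m["name"], m["chromosome"], m["position"]) for m in obj["markers"]],
        [
            InversionRegion(
                v["chromosome"], v["start_cM"], v["end_cM"], frozenset(v["active_in"])
            )
            for v in obj["inversions"]
        ],
    )
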