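"""Genotype -> (sex ratio, fertility) effect model and phenotype sampling.

The genetic architecture is the distorter/suppressor/sterility system of the
D. albomicans / D. nasuta hybrid zone: X-3-linked distorters bias transmission
against Y-bearing sperm (sex ratio k > 0.5 among offspring), autosomal
semidominant suppressors silence them, and the same loci carry hybrid male
sterility effects — distorters reduce male fertility, suppressors rescue it.

Sex ratio: k = 0.5 + dmax * sigma(sum_j d_j x_j - sum_l s_l dose_l), with
x_j in {0,1} hemizygous distorter presence, dose_l in {0, w_l, 1} for 0/1/2
suppressor copies, and sigma(z) = max(z,0)/(1+max(z,0)) a saturating link
onto [0,1). k is therefore exactly 0.5 with no active drive and strictly
below 0.5 + dmax always.

Fertility: a hurdle model. Sterility probability is logistic in the summed
per-locus sterility log-odds; conditional on fertile, the offspring count is
negative binomial with a mean multiplicative in per-locus log-fecundity
effects (clipped at a physiological ceiling).

Default calibration targets the study's printed genotype means qualitatively
(F1 males k ~ 0.92; the three-distorter genotype k ~ 0.86; control fecundity
~ 115; the strongest distorter alone nearly sterilizing); those summaries are
data, not parameters, so only orderings and approximate levels are built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .crosses import MaleGenotype
from .genome import GeneticMap
from .protocol import ProtocolConfig, VialSeries, vial_series_from_daily

__all__ = [
    "Locus",
    "EffectModel",
    "MalePhenotype",
    "default_effect_model",
    "expected_sex_ratio",
    "fertility_distribution",
    "simulate_phenotypes",
    "simulate_vial_series",
    "model_to_yaml",
    "model_from_yaml",
]


@dataclass(frozen=True)
class Locus:
    """One architecture locus.

    ``drive`` (distorters) and ``suppression`` (suppressors) act on the sex
    ratio; ``sterility`` is the locus' log-odds contribution to the sterility
    hurdle (positive = sterilizing) and ``log_fecundity`` its contribution to
    the conditional-fertile mean (positive = more offspring). ``dominance``
    weights a single autosomal copy relative to two; X-3 loci are hemizygous
    and ignore it.
    """

    name: str
    chromosome: str
    position: float
    line: str = "alb267"
    drive: float = 0.0
    suppression: float = 0.0
    dominance: float = 0.64
    sterility: float = 0.0
    log_fecundity: float = 0.0

    def __post_init__(self) -> None:
        if self.drive < 0 or self.suppression < 0:
            raise ValueError("drive and suppression effects must be >= 0")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance weight must lie in [0,1]")


@dataclass
class EffectModel:
    distorters: list[Locus] = field(default_factory=list)
    suppressors: list[Locus] = field(default_factory=list)
    k_max_excess: float = 0.48     # dmax: ceiling of the drive excess over 0.5
    mu0: float = 115.0             # control conditional-fertile mean offspring
    theta: float = 5.5             # negative-binomial dispersion
    sterility_logodds0: float = -4.0
    mu_ceiling: float = 220.0      # physiological fecundity ceiling
    y_sensitive: bool = True       # drive needs a sensitive Y-linked responder

    def __post_init__(self) -> None:
        if not 0.0 < self.k_max_excess < 0.5:
            raise ValueError("k_max_excess must lie in (0, 0.5)")
        if self.mu0 <= 0 or self.theta <= 0:
            raise ValueError("mu0 and theta must be positive")

    @property
    def loci(self) -> list[Locus]:
        return self.distorters + self.suppressors


def default_effect_model() -> EffectModel:
    """The shipped calibration of the alb267-vs-nas314 architecture.

    Four X-3 distorters (D1, D2 on the X arm; D3, D4 on the chromosome-3 arm)
    and two second-chromosome suppressors (S3, S4). Drive and suppression
    strengths are set so that the fully driven, singly suppressed F1 genotype
    sits near k = 0.92, the D2 D3 D4 genotype near k = 0.86, and suppression
    follows the semidominant one-copy/two-copy ordering; sterility and
    fecundity effects make D1 nearly sterilizing on its own, the three-
    distorter genotype subfertile, and suppressors strongly rescuing.
    """
    distorters = [
        Locus("D1", "X-3", 20.0, drive=7.185, sterility=12.0, log_fecundity=-1.5),
        Locus("D2", "X-3", 70.0, drive=0.200, sterility=1.0, log_fecundity=-1.2),
        Locus("D3", "X-3", 130.0, drive=2.500, sterility=1.0, log_fecundity=-1.2),
        Locus("D4", "X-3", 170.0, drive=0.438, sterility=1.0, log_fecundity=-1.3),
    ]
    suppressors = [
        Locus("S3", "2", 30.0, suppression=2.87, sterility=-16.0, log_fecundity=5.65),
        Locus("S4", "2", 80.0, suppression=2.322, sterility=-8.0, log_fecundity=3.02),
    ]
    return EffectModel(distorters, suppressors)


def _locus_copies(genotype: MaleGenotype, gmap: GeneticMap, locus: Locus) -> int:
    """Copies of the locus' active allele carried by a male (nearest marker)."""
    sl = gmap.chromosome_slice(locus.chromosome)
    if sl.stop == sl.start:
        raise ValueError(f"locus {locus.name}: chromosome {locus.chromosome} has no markers")
    pos = gmap.positions(locus.chromosome)
    i = sl.start + int(np.argmin(np.abs(pos - locus.position)))
    copies = int(genotype.maternal[i] == locus.line)
    if not genotype.x_linked[i]:
        copies += int(genotype.paternal[i] == locus.line)
    return copies


def _drive_latent(genotype: MaleGenotype, model: EffectModel, gmap: GeneticMap) -> float:
    z = 0.0
    for d in model.distorters:
        z += d.drive * (1 if _locus_copies(genotype, gmap, d) >= 1 else 0)
    for s in model.suppressors:
        c = _locus_copies(genotype, gmap, s)
        dose = 0.0 if c == 0 else (s.dominance if c == 1 else 1.0)
        z -= s.suppression * dose
    return z


def expected_sex_ratio(genotype: MaleGenotype, model: EffectModel, gmap: GeneticMap) -> float:
    """Expected proportion of females among a male's offspring, in [0.5, 1).

    Monotone non-decreasing in every distorter effect and non-increasing in
    every suppressor dose; exactly 0.5 when no distorter allele is present or
    the Y-linked responder is insensitive.
    """
    if not model.y_sensitive:
        return 0.5
    z = max(_drive_latent(genotype, model, gmap), 0.0)
    return 0.5 + model.k_max_excess * z / (1.0 + z)


def fertility_distribution(
    genotype: MaleGenotype, model: EffectModel, gmap: GeneticMap
) -> tuple[float, float, float]:
    """Hurdle parameters (p_sterile, mu, theta) for a male's offspring count.

    Sterility log-odds and log-fecundity sum per-locus contributions, with
    autosomal heterozygotes weighted by the locus' dominance; the conditional
    mean is clipped to the vial-system ceiling.
    """
    logit = model.sterility_logodds0
    logmu = 0.0
    for loc in model.loci:
        c = _locus_copies(genotype, gmap, loc)
        w = 0.0 if c == 0 else (loc.dominance if c == 1 else 1.0)
        if genotype.x_linked[gmap.chromosome_slice(loc.chromosome).start]:
            w = float(c >= 1)  # hemizygous: present or absent
        logit += loc.sterility * w
        logmu += loc.log_fecundity * w
    p_sterile = 1.0 / (1.0 + np.exp(-logit))
    mu = min(model.mu0 * np.exp(logmu), model.mu_ceiling)
    return float(p_sterile), float(mu), model.theta


@dataclass
class MalePhenotype:
    """Offspring counts of one tested male."""

    T: int
    females: int
    males: int

    def __post_init__(self) -> None:
        if self.T != self.females + self.males:
            raise ValueError("T must equal females + males")

    @property
    def k(self) -> float | None:
        return self.females / self.T if self.T > 0 else None


def simulate_phenotypes(
    genotypes: list[MaleGenotype],
    model: EffectModel,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
) -> list[MalePhenotype]:
    """Sample offspring counts: hurdle negative-binomial T, binomial sexing."""
    rng = np.random.default_rng(rng)
    out: list[MalePhenotype] = []
    for g in genotypes:
        p_st, mu, theta = fertility_distribution(g, model, gmap)
        if rng.random() < p_st:
            t = 0
        else:
            t = int(rng.negative_binomial(theta, theta / (theta + mu)))
        k = expected_sex_ratio(g, model, gmap)
        f = int(rng.binomial(t, k)) if t > 0 else 0
        out.append(MalePhenotype(t, f, t - f))
    return out


def daily_weights(lifespan: int, decay: str = "linear", rate: float = 0.9) -> np.ndarray:
    """Relative expected daily output over a male's reproductive lifespan.

    ``linear`` declines to zero at day ``lifespan``+1 (the default: under it
    the 4-day-block interpolation of the mating protocol is exact);
    ``geometric`` multiplies by ``rate`` each day.
    """
    days = np.arange(1, lifespan + 1, dtype=float)
    if decay == "linear":
        w = lifespan + 1 - days
    elif decay == "geometric":
        w = rate ** (days - 1)
    else:
        raise ValueError(f"unknown decay model {decay!r}")
    return w / w.sum()


def simulate_vial_series(
    phenotype: MalePhenotype,
    protocol: ProtocolConfig | None = None,
    decay: str = "linear",
    lifespan: int = 18,
    rate: float = 0.9,
    rng: np.random.Generator | int | None = None,
) -> VialSeries:
    """Allocate a male's lifetime output over the 4+1 vial schedule.

    Day totals are multinomial over the decay curve's daily weights; females
    are allocated across days without replacement so vial sums reproduce the
    male's (T, females, males) exactly. Optional capacity censoring truncates
    any vial at the protocol's ``vial_capacity``.
    """
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(rng)
    w = daily_weights(lifespan, decay, rate)
    day_tot = rng.multinomial(phenotype.T, w)
    day_f = rng.multivariate_hypergeometric(day_tot, phenotype.females)
    daily = [(int(f), int(t - f)) for f, t in zip(day_f, day_tot)]
    series = vial_series_from_daily(daily, protocol)
    if protocol.vial_capacity is not None:
        cap = protocol.vial_capacity
        capped = []
        for v in series.vials:
            if v.total > cap:
                f = int(rng.hypergeometric(v.females, v.males, cap))
                capped.append(type(v)(v.start_day, v.n_days, f, cap - f, v.counted))
            else:
                capped.append(v)
        series = VialSeries(capped)
    return series


# -- config round-trip --------------------------------------------------------


def model_to_yaml(model: EffectModel) -> str:
    obj = asdict(model)
    return yaml.safe_dump(obj, sort_keys=False)


def model_from_yaml(text: str) -> EffectModel:
    obj = yaml.safe_load(text)
    obj["distorters"] = [Locus(**d) for d in obj["distorters"]]
    obj["suppressors"] = [Locus(**s) for s in obj["suppressors"]]
    return EffectModel(**obj)
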