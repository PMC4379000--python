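"""The exhaustive-mating fertility estimator.

A tested male is given fresh virgin females on a 4+1-day transfer regime:
1-day vials on days 1, 2, 3, 8, 13, ... are sexed and counted, while the
intervening 4-day vials (days 4-7, 9-12, ...) are left uncounted and their
output is interpolated as twice the sum of the two flanking 1-day vials.
Summing counted vials and block estimates gives T, the male's lifetime
functional sperm count. The interpolation is exact when daily output
declines linearly (the 4-day block and its two flanks then bracket the same
mean day), which is what makes the cheap schedule a faithful estimator.

Sex ratio k is computed over counted offspring only, and only for males
with enough counted progeny (default at least 30); group-level sex ratios
of sub-fertile genotypes are summarised by bootstrap over males with counts
pooled within each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vial",
    "VialSeries",
    "ProtocolConfig",
    "InterpolationResult",
    "SexRatioResult",
    "interpolate_total",
    "observed_sex_ratio",
    "bootstrap_sex_ratio",
    "vial_series_from_daily",
]


@dataclass(frozen=True)
class Vial:
    start_day: int
    n_days: int
    females: int
    males: int
    counted: bool

    @property
    def total(self) -> int:
        return self.females + self.males


@dataclass
class VialSeries:
    """Ordered vials of one male's mating test.

    Uncounted vials may carry the true (simulated) counts for validation, but
    no estimator reads them; analysis uses counted vials plus interpolation.
    """

    vials: list[Vial] = field(default_factory=list)

    def __post_init__(self) -> None:
        day = None
        for v in self.vials:
            if v.n_days not in (1, 4):
                raise ValueError("vials span 1 or 4 days")
            if v.females < 0 or v.males < 0:
                raise ValueError("negative offspring count")
            if day is not None and v.start_day != day:
                raise ValueError("vial day spans must be contiguous")
            day = v.start_day + v.n_days

    def true_total(self) -> int:
        """Ground-truth total over all vials (simulation only)."""
        return sum(v.total for v in self.vials)


@dataclass
class ProtocolConfig:
    """Exhaustive-protocol settings.

    ``single_days`` are the leading 1-day vials; thereafter 1-day vials recur
    every ``period`` days (1,2,3,8,13,... by default). ``sex_ratio_min_T`` is
    the minimum counted progeny for a per-male sex ratio.
    """

    single_days: tuple[int, ...] = (1, 2, 3)
    period: int = 5
    sex_ratio_min_T: int = 30
    bootstrap_replicates: int = 1000
    vial_capacity: int | None = None

    def __post_init__(self) -> None:
        if self.sex_ratio_min_T < 1:
            raise ValueError("sex_ratio_min_T must be >= 1")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    def is_counted_day(self, day: int) -> bool:
        if day in self.single_days:
            return True
        last = self.single_days[-1]
        return day > last and (day - last) % self.period == 0


@dataclass
class InterpolationResult:
    total: float
    total_rounded: int
    counted_total: int
    block_estimates: list[float]
    edge_rule_used: bool


def interpolate_total(series: VialSeries) -> InterpolationResult:
    """Estimate a male's total offspring from a partially counted series.

    Each uncounted 4-day block is estimated as 2 x (preceding 1-day count +
    following 1-day count); counted vials contribute their actual counts. A
    trailing uncounted block with no following counted vial (the male died)
    is estimated as 4 x the preceding 1-day count and flagged.
    """
    total = 0.0
    counted_total = 0
    blocks: list[float] = []
    edge = False
    vials = series.vials
    for i, v in enumerate(vials):
        if v.counted:
            total += v.total
            counted_total += v.total
            continue
        prev_v = vials[i - 1] if i > 0 else None
        next_v = vials[i + 1] if i + 1 < len(vials) else None
        if prev_v is None or not prev_v.counted:
            raise ValueError(
                f"uncounted block at day {v.start_day} has no preceding counted vial"
            )
        if next_v is not None and next_v.counted:
            est = 2.0 * (prev_v.total + next_v.total)
        else:
            if next_v is not None:
                raise ValueError(
                    f"uncounted block at day {v.start_day} followed by another uncounted vial"
                )
            est = 4.0 * prev_v.total
            edge = True
        blocks.append(est)
        total += est
    return InterpolationResult(total, round(total), counted_total, blocks, edge)


@dataclass
class SexRatioResult:
    k: float | None
    eligible: bool
    females: int
    males: int


def observed_sex_ratio(series, config: ProtocolConfig | None = None) -> SexRatioResult:
    """Proportion of females among counted offspring; ineligible below the
    counted-progeny threshold (interpolated offspring have unknown sex)."""
    config = config or ProtocolConfig()
    if isinstance(series, VialSeries):
        f = sum(v.females for v in series.vials if v.counted)
        m = sum(v.males for v in series.vials if v.counted)
    else:  # any record with .females / .males (e.g. MalePhenotype)
        f, m = int(series.females), int(series.males)
    total = f + m
    if total < config.sex_ratio_min_T:
        return SexRatioResult(None, False, f, m)
    return SexRatioResult(f / total, True, f, m)


def bootstrap_sex_ratio(
    records,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Bootstrap mean and s.e.m. of a group's pooled sex ratio.

    Males are resampled with replacement B times; each replicate's k pools
    female and total counts over the resampled males, so sub-fertile males
    with undefined individual k still contribute. Sterile males (T = 0) are
    excluded from the pooling.
    """
    recs = [r for r in records if (r.females + r.males) > 0]
    if not recs:
        raise ValueError("no records with offspring to bootstrap")
    rng = np.random.default_rng(rng)
    f = np.array([r.females for r in recs], dtype=float)
    t = np.array([r.females + r.males for r in recs], dtype=float)
    idx = rng.integers(0, len(recs), size=(B, len(recs)))
    ks = f[idx].sum(axis=1) / t[idx].sum(axis=1)
    return float(ks.mean()), float(ks.std(ddof=1)) if B > 1 else 0.0


def vial_series_from_daily(
    daily: list[tuple[int, int]],
    config: ProtocolConfig | None = None,
    count_all: bool = False,
) -> VialSeries:
    """Pool per-day (females, males) output into the 4+1 vial schedule.

    Days are 1-based and contiguous from day 1. A block is a 1-day counted
    vial on scheduled days and a 4-day uncounted vial otherwise; a trailing
    partial block shorter than 4 days is emitted as counted 1-day vials
    (end-of-life offspring were counted directly).
    """
    config = config or ProtocolConfig()
    vials: list[Vial] = []
    day = 1
    n = len(daily)
    while day <= n:
        f, m = daily[day - 1]
        if config.is_counted_day(day):
            vials.append(Vial(day, 1, f, m, True))
            day += 1
        elif day + 3 <= n:
            ff = sum(d[0] for d in daily[day - 1 : day + 3])
            mm = sum(d[1] for d in daily[day - 1 : day + 3])
            vials.append(Vial(day, 4, ff, mm, count_all))
            day += 4
        else:  # partial trailing block: count day by day
            vials.append(Vial(day, 1, f, m, True))
            day += 1
    return VialSeries(vials)
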