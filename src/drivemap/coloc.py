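"""Interval colocalization null probability.

If m QTL support intervals on one chromosome are disjoint and a second set of
m genes is placed independently and uniformly on the chromosome's map, the
probability that each interval receives exactly one gene is m! * prod(U_i),
where U_i is the i-th interval's width as a fraction of the map length (each
of the m! interval-to-gene assignments contributes prod U_i). A small value
argues that paired phenotypes mapping to the same intervals are pleiotropic
effects of shared genes rather than coincidentally linked distinct genes.
Placements on different chromosomes are independent, so chromosome-level
probabilities multiply.

A Monte-Carlo estimator of the same probability is provided as a brute-force
check on the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntervalWidths",
    "matching_probability",
    "combined_probability",
    "matching_probability_mc",
]


@dataclass
class IntervalWidths:
    """Disjoint QTL interval widths on one chromosome, as map-length fractions."""

    chromosome: str
    widths: list[float]

    def __post_init__(self) -> None:
        if not self.widths:
            raise ValueError("at least one interval width is required")
        w = np.asarray(self.widths, dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("each width must lie in (0, 1]")
        if w.sum() > 1.0 + 1e-12:
            raise ValueError("widths sum beyond 1: intervals cannot be disjoint")


def _as_widths(U) -> IntervalWidths:
    return U if isinstance(U, IntervalWidths) else IntervalWidths("", list(U))


def matching_probability(U) -> float:
    """m! * prod(U_i): one uniform gene per interval, all intervals hit."""
    iv = _as_widths(U)
    m = len(iv.widths)
    return math.factorial(m) * math.prod(iv.widths)


def combined_probability(groups) -> float:
    """Product of per-chromosome matching probabilities (independent placements)."""
    if not groups:
        raise ValueError("no interval groups given")
    p = 1.0
    for g in groups:
        p *= matching_probability(g)
    return p


def matching_probability_mc(
    U,
    n_sims: int = 10**6,
    rng: np.random.Generator | int | None = None,
    chunk: int = 1_000_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the matching probability, with binomial s.e.

    Intervals are laid disjoint from the chromosome start (the estimate is
    placement-invariant in expectation given disjointness); m points are
    drawn uniform on [0, 1] and a draw succeeds iff each interval contains
    exactly one point.
    """
    iv = _as_widths(U)
    w = np.asarray(iv.widths, dtype=float)
    m = len(w)
    edges = np.concatenate([[0.0], np.cumsum(w)])
    rng = np.random.default_rng(rng)
    hits = 0
    done = 0
    while done < n_sims:
        k = min(chunk, n_sims - done)
        pts = rng.random((k, m))
        idx = np.searchsorted(edges, pts, side="right") - 1  # m => outside all
        idx.sort(axis=1)
        hits += int(np.sum(np.all(idx == np.arange(m)[None, :], axis=1)))
        done += k
    p = hits / n_sims
    se = math.sqrt(p * (1.0 - p) / n_sims)
    return p, se
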