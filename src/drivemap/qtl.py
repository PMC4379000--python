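"""Genome scans for fertility and sex-ratio loci in backcross males.

The scan is Haley-Knott-style expected-genotype regression: at every grid
position the focal-line allele probability is computed from the flanking
marker doses under the Haldane map function, and the trait is regressed on
that expectation. For continuous traits LOD = (n/2) log10(RSS0/RSS1); for the
binary fertile/sterile trait LOD = (l1 - l0)/ln 10 from logistic fits. An
optional forward-selected marker-cofactor set (with a cM exclusion window
around the test position) approximates composite interval mapping; the joint
multi-locus fit approximates multiple interval mapping and yields the total
(H2) and additive (h2) variance components.

Genome-wide significance uses the permutation max-LOD distribution: trait
values are shuffled against genotype rows and the (1 - alpha) quantile of the
per-permutation maximum LOD is the cutoff.

Recombination-suppressed regions (inversion heterozygosity) make all their
markers perfectly collinear, so the scan collapses each such region to a
single representative position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .crosses import MaleGenotype, dosage_matrix
from .genome import GeneticMap, haldane_r

__all__ = [
    "TraitVector",
    "ScanResult",
    "Threshold",
    "QTLInterval",
    "VarianceComponents",
    "transform_trait",
    "lod_scan",
    "permutation_threshold",
    "support_interval",
    "fit_multi_qtl",
]

LOD_CAP = 50.0
TRAIT_KINDS = ("T", "log10T1", "binary", "sexratio")


@dataclass
class TraitVector:
    values: np.ndarray
    transform: str
    mask: np.ndarray  # eligibility: rows entering the scan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("mask length must equal population size")

    @property
    def usable(self) -> np.ndarray:
        return self.values[self.mask]


def transform_trait(phenotypes, kind: str, sex_ratio_min_T: int = 30) -> TraitVector:
    """Published trait treatments: raw T, log10(T+1), fertile/sterile binary,
    and sex ratio restricted to males with at least ``sex_ratio_min_T``
    offspring (small broods give unreliable ratios)."""
    T = np.array([p.T for p in phenotypes], dtype=float)
    f = np.array([p.females for p in phenotypes], dtype=float)
    mask = np.ones(len(T), dtype=bool)
    if kind == "T":
        vals = T
    elif kind == "log10T1":
        vals = np.log10(T + 1.0)
    elif kind == "binary":
        vals = (T > 0).astype(float)
    elif kind == "sexratio":
        mask = T >= sex_ratio_min_T
        vals = np.divide(f, T, out=np.full_like(T, np.nan), where=T > 0)
    else:
        raise ValueError(f"unknown trait transform {kind!r}; expected one of {TRAIT_KINDS}")
    return TraitVector(vals, kind, mask)


# -- scan grid and expected genotypes ----------------------------------------


@dataclass
class _ScanContext:
    """Precomputed per-position expected focal-allele doses for one dataset."""

    chrom: np.ndarray          # chromosome label per grid position
    pos: np.ndarray            # cM per grid position
    E: np.ndarray              # (n_males, n_positions) expected dose
    chrom_lengths: dict[str, float]


def _expected_dose_chrom(D: np.ndarray, pm: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Expected dose at grid points from flanking-marker doses (BC1 coding)."""
    n = D.shape[0]
    E = np.empty((n, len(grid)))
    for gidx, p in enumerate(grid):
        if p <= pm[0]:
            r = haldane_r(pm[0] - p)
            E[:, gidx] = D[:, 0] * (1 - r) + (1 - D[:, 0]) * r
        elif p >= pm[-1]:
            r = haldane_r(p - pm[-1])
            E[:, gidx] = D[:, -1] * (1 - r) + (1 - D[:, -1]) * r
        else:
            i = int(np.searchsorted(pm, p, side="right")) - 1
            j = i + 1
            r12 = haldane_r(pm[j] - pm[i])
            if r12 < 1e-12:
                E[:, gidx] = D[:, i]
                continue
            r1 = haldane_r(p - pm[i])
            r2 = haldane_r(pm[j] - p)
            gi, gj = D[:, i], D[:, j]
            p11 = (1 - r1) * (1 - r2) / (1 - r12)
            p10 = (1 - r1) * r2 / r12
            p01 = r1 * (1 - r2) / r12
            p00 = r1 * r2 / (1 - r12)
            E[:, gidx] = np.select(
                [
                    (gi == 1) & (gj == 1),
                    (gi == 1) & (gj == 0),
                    (gi == 0) & (gj == 1),
                ],
                [p11, p10, p01],
                default=p00,
            )
    return E


def _build_context(
    genotypes,
    gmap: GeneticMap,
    step_cM: float,
    cross_label: str | None,
    focal_line: str,
) -> _ScanContext:
    if isinstance(genotypes, np.ndarray):
        D_all = genotypes.astype(float)
    else:
        D_all = dosage_matrix(genotypes, focal_line).astype(float)
    if D_all.shape[1] != gmap.n_markers:
        raise ValueError("dosage matrix does not match the map's marker count")
    chroms, poss, blocks = [], [], []
    for chrom in gmap.chromosomes:
        sl = gmap.chromosome_slice(chrom.name)
        if sl.stop == sl.start:
            continue
        pm = gmap.positions(chrom.name)
        D = D_all[:, sl]
        grid = np.unique(
            np.concatenate([pm, np.arange(pm[0], pm[-1] + 1e-9, step_cM)])
        )
        # collapse recombination-suppressed regions to one representative
        for inv in gmap.active_inversions(chrom.name, cross_label):
            inside = (grid >= inv.start_cM) & (grid < inv.end_cM)
            if inside.any():
                mid = 0.5 * (inv.start_cM + inv.end_cM)
                grid = np.concatenate([grid[~inside], [mid]])
        grid = np.sort(grid)
        E = _expected_dose_chrom(D, pm, grid)
        chroms.append(np.full(len(grid), chrom.name, dtype=object))
        poss.append(grid)
        blocks.append(E)
    return _ScanContext(
        np.concatenate(chroms),
        np.concatenate(poss),
        np.concatenate(blocks, axis=1),
        {c.name: c.length_cM for c in gmap.chromosomes},
    )


# -- LOD computation ----------------------------------------------------------


def _lods_continuous(E: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LOD and effect for each trait row of Y against each column of E.

    Uses RSS1 = RSS0 (1 - r^2) for simple regression, so
    LOD = -(n/2) log10(1 - r^2). Y is (n_traits, n); E is (n, P).
    Returns (n_traits, P) LODs and effects.
    """
    n = E.shape[0]
    Ec = E - E.mean(axis=0)
    ev = (Ec**2).sum(axis=0)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    yv = (Yc**2).sum(axis=1)
    if np.any(yv <= 0):
        raise ValueError("trait is constant; LOD scan undefined")
    cov = Yc @ Ec  # (n_traits, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ev > 0, cov**2 / (ev * yv[:, None]), 0.0)
        beta = np.where(ev > 0, cov / ev, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    lod = -(n / 2.0) * np.log10(np.clip(1.0 - r2, 10 ** (-2 * LOD_CAP / n), 1.0))
    return np.minimum(lod, LOD_CAP), beta


def _logistic_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)


def _lods_binary(E: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Logistic-regression LODs, Newton iterations vectorised over positions."""
    n, P = E.shape
    pbar = y.mean()
    if pbar <= 0 or pbar >= 1:
        raise ValueError("binary trait is constant; LOD scan undefined")
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    a = np.full(P, np.log(pbar / (1 - pbar)))
    b = np.zeros(P)
    for _ in range(30):
        eta = a[None, :] + E * b[None, :]
        mu = expit(eta)
        w = mu * (1 - mu)
        resid = y[:, None] - mu
        g_a = resid.sum(axis=0)
        g_b = (resid * E).sum(axis=0)
        h_aa = w.sum(axis=0)
        h_ab = (w * E).sum(axis=0)
        h_bb = (w * E**2).sum(axis=0)
        det = h_aa * h_bb - h_ab**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        step = np.clip(np.stack([da, db]), -5, 5)
        a += step[0]
        b += step[1]
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = a[None, :] + E * b[None, :]
    ll1 = _logistic_ll(y[:, None].T, eta.T)
    lod = np.maximum(ll1 - ll0, 0.0) / np.log(10.0)
    return np.minimum(lod, LOD_CAP), b


@dataclass
class ScanResult:
    chrom: np.ndarray
    pos: np.ndarray
    lod: np.ndarray
    effect: np.ndarray  # focal-line allele effect relative to the background line
    transform: str
    chrom_lengths: dict[str, float] = field(default_factory=dict)

    def max_lod(self) -> float:
        return float(self.lod.max())

    def peak(self, chromosome: str | None = None) -> int:
        """Index of the maximum-LOD position (smallest cM on ties)."""
        sel = np.ones(len(self.pos), dtype=bool)
        if chromosome is not None:
            sel = self.chrom == chromosome
        idx = np.flatnonzero(sel)
        lods = self.lod[idx]
        best = lods.max()
        ties = idx[lods >= best - 1e-12]
        return int(ties[np.argmin(self.pos[ties])])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chromosome": self.chrom,
                "cM": self.pos,
                "LOD": self.lod,
                "effect": self.effect,
                "transform": self.transform,
            }
        )


def _select_cofactors(E_mark: np.ndarray, y: np.ndarray, n_cofactors: int) -> list[int]:
    """Forward selection of marker cofactors by incremental RSS reduction."""
    chosen: list[int] = []
    resid = y - y.mean()
    for _ in range(n_cofactors):
        best, best_rss = None, (resid**2).sum()
        for j in range(E_mark.shape[1]):
            if j in chosen:
                continue
            x = E_mark[:, j]
            xc = x - x.mean()
            v = (xc**2).sum()
            if v <= 0:
                continue
            rss = (resid**2).sum() - (xc @ resid) ** 2 / v
            if rss < best_rss - 1e-12:
                best, best_rss = j, rss
        if best is None:
            break
        chosen.append(best)
        x = E_mark[:, [c for c in chosen]]
        X = np.column_stack([np.ones(len(y)), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    return chosen


def lod_scan(
    genotypes,
    trait: TraitVector,
    gmap: GeneticMap,
    step_cM: float = 1.0,
    *,
    cross_label: str | None = None,
    focal_line: str = "alb267",
    n_cofactors: int = 0,
    cofactor_window_cM: float = 10.0,
) -> ScanResult:
    """Genome scan of one trait.

    ``genotypes`` is a list of males or a precomputed (n, n_markers) dosage
    matrix. Rows masked out by the trait's eligibility are dropped. With
    ``n_cofactors`` > 0, forward-selected marker cofactors are partialled out
    of trait and test position (cofactors within ``cofactor_window_cM`` of the
    test position are excluded), approximating composite interval mapping.
    """
    ctx = _build_context(genotypes, gmap, step_cM, cross_label, focal_line)
    m = trait.mask
    y = trait.values[m]
    E = ctx.E[m]
    if len(y) < 3:
        raise ValueError("too few eligible males for a scan")
    if trait.transform == "binary":
        lod, eff = _lods_binary(E, y)
    elif n_cofactors > 0:
        lod, eff = _scan_with_cofactors(
            ctx, E, y, n_cofactors, cofactor_window_cM
        )
    else:
        lod, eff = _lods_continuous(E, y[None, :])
        lod, eff = lod[0], eff[0]
    return ScanResult(ctx.chrom, ctx.pos, lod, eff, trait.transform, ctx.chrom_lengths)


def _scan_with_cofactors(ctx, E, y, n_cofactors, window):
    cof = _select_cofactors(E, y, n_cofactors)
    n = len(y)
    lod = np.zeros(E.shape[1])
    eff = np.zeros(E.shape[1])
    for p in range(E.shape[1]):
        keep = [
            c
            for c in cof
            if ctx.chrom[c] != ctx.chrom[p] or abs(ctx.pos[c] - ctx.pos[p]) > window
        ]
        Z = np.column_stack([np.ones(n)] + [E[:, c] for c in keep])
        Q, _ = np.linalg.qr(Z)
        ry = y - Q @ (Q.T @ y)
        rx = E[:, p] - Q @ (Q.T @ E[:, p])
        rss0 = ry @ ry
        v = rx @ rx
        if v <= 1e-12 or rss0 <= 0:
            continue
        beta = (rx @ ry) / v
        rss1 = rss0 - beta * (rx @ ry)
        lod[p] = min((n / 2.0) * np.log10(max(rss0, 1e-300) / max(rss1, 1e-300)), LOD_CAP)
        eff[p] = beta
    return lod, eff


@dataclass
class Threshold:
    alpha: float
    n_perm: int
    max_lods: np.ndarray

    @property
    def cutoff(self) -> float:
        """(1 - alpha) empirical quantile (type-7) of the max-LOD sample."""
        return float(np.quantile(self.max_lods, 1.0 - self.alpha, method="linear"))


def permutation_threshold(
    genotypes,
    trait: TraitVector,
    gmap: GeneticMap,
    n_perm: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    *,
    step_cM: float = 1.0,
    cross_label: str | None = None,
    focal_line: str = "alb267",
) -> Threshold:
    """Genome-wide LOD cutoff from the permutation max-LOD distribution.

    Trait values are permuted against genotype rows (within the eligible
    subset); each permutation's genome-wide maximum LOD is recorded and the
    cutoff is the empirical (1 - alpha) quantile.
    """
    ctx = _build_context(genotypes, gmap, step_cM, cross_label, focal_line)
    m = trait.mask
    y = trait.values[m]
    E = ctx.E[m]
    rng = np.random.default_rng(rng)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    if trait.transform == "binary":
        maxlod = np.empty(n_perm)
        for i in range(n_perm):
            lod, _ = _lods_binary(E, perms[i])
            maxlod[i] = lod.max()
    else:
        lods, _ = _lods_continuous(E, perms)
        maxlod = lods.max(axis=1)
    return Threshold(alpha, n_perm, maxlod)


@dataclass
class QTLInterval:
    chromosome: str
    peak_cM: float
    start_cM: float
    end_cM: float
    U: float  # interval width as a fraction of the chromosome's map length
    h2: float | None = None

    def __post_init__(self) -> None:
        if not (self.start_cM <= self.peak_cM <= self.end_cM):
            raise ValueError("peak must lie inside the support interval")
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")


def support_interval(scan: ScanResult, peak_index: int | None = None, drop: float = 1.5) -> QTLInterval:
    """LOD-drop support interval (~95% CI) around a peak.

    The smallest contiguous cM interval around the peak over which LOD stays
    within ``drop`` of the peak value; U is its width as a fraction of the
    chromosome's map length (a flat profile spans the whole chromosome, U=1).
    """
    if peak_index is None:
        peak_index = scan.peak()
    chrom = scan.chrom[peak_index]
    sel = scan.chrom == chrom
    pos = scan.pos[sel]
    lod = scan.lod[sel]
    pk = int(np.flatnonzero(np.flatnonzero(sel) == peak_index)[0])
    thr = lod[pk] - drop
    lo = pk
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = pk
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    length = scan.chrom_lengths.get(chrom, pos[-1] - pos[0] or 1.0)
    start, end = float(pos[lo]), float(pos[hi])
    if lo == 0 and hi == len(lod) - 1 and thr <= lod.min():
        start, end = 0.0, float(length)  # flat profile: whole chromosome
    width = max(end - start, 1e-9)
    return QTLInterval(str(chrom), float(pos[pk]), start, end, min(width / length, 1.0))


@dataclass
class VarianceComponents:
    H2: float
    h2: float
    per_locus: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= self.H2 + 1e-9 and self.H2 <= 1.0 + 1e-9):
            raise ValueError("require 0 <= h2 <= H2 <= 1")
        self.h2 = float(min(self.h2, self.H2))
        self.H2 = float(min(self.H2, 1.0))


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(max(0.0, 1.0 - (resid @ resid) / tss)) if tss > 0 else 0.0


def fit_multi_qtl(
    genotypes,
    trait: TraitVector,
    loci: list[tuple[str, float]],
    gmap: GeneticMap,
    *,
    epistasis: bool = False,
    cross_label: str | None = None,
    focal_line: str = "alb267",
) -> VarianceComponents:
    """Joint multi-locus fit; H2 from the full model, h2 from additive terms.

    ``loci`` are (chromosome, cM) positions. H2 is the R^2 of the joint
    linear model with additive expected-dose terms (plus all pairwise
    products when ``epistasis``); h2 is the R^2 of the additive-only refit.
    Per-locus shares are incremental additive R^2 in map order.
    """
    if not loci:
        raise ValueError("no loci given")
    ctx = _build_context(genotypes, gmap, 1e9, cross_label, focal_line)
    m = trait.mask
    y = trait.values[m]
    cols = []
    names = []
    for chrom, p in loci:
        sel = ctx.chrom == chrom
        if not sel.any():
            raise ValueError(f"no markers on chromosome {chrom!r}")
        # expected dose exactly at the requested position
        pm = gmap.positions(chrom)
        sl = gmap.chromosome_slice(chrom)
        if isinstance(genotypes, np.ndarray):
            D = genotypes[:, sl].astype(float)
        else:
            D = dosage_matrix(genotypes, focal_line)[:, sl].astype(float)
        cols.append(_expected_dose_chrom(D, pm, np.array([p]))[m, 0])
        names.append(f"{chrom}@{p:g}")
    X = np.column_stack(cols)
    h2 = _r2(X, y)
    if epistasis and len(loci) > 1:
        inter = [
            X[:, i] * X[:, j] for i in range(X.shape[1]) for j in range(i + 1, X.shape[1])
        ]
        H2 = _r2(np.column_stack([X] + inter), y)
    else:
        H2 = h2
    H2 = max(H2, h2)
    shares: dict[str, float] = {}
    prev = 0.0
    for j in range(X.shape[1]):
        r = _r2(X[:, : j + 1], y)
        shares[names[j]] = max(r - prev, 0.0)
        prev = r
    return VarianceComponents(min(H2, 1.0), min(h2, 1.0), shares)
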