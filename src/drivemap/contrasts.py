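"""Two-genotype contrasts for introgression studies.

Fertility (offspring count T) differences between two introgression genotype
groups are tested with the two-sample Wilcoxon rank-sum test; sex-ratio
differences with a binomial logistic regression on per-male (female, male)
counts — a single group indicator, so larger broods carry more weight — via
a likelihood-ratio test. The dominance index classifies a suppressor from
the sex ratios at 0, 1 and 2 suppressor copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeGroup",
    "fertility_contrast",
    "sexratio_contrast",
    "dominance_index",
]


@dataclass
class GenotypeGroup:
    """A labelled set of phenotyped males of one introgression genotype."""

    label: str
    records: list = field(default_factory=list)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        f = np.array([r.females for r in self.records], dtype=float)
        m = np.array([r.males for r in self.records], dtype=float)
        return f, m

    def totals(self) -> np.ndarray:
        f, m = self.counts()
        return f + m


def _records(group) -> GenotypeGroup:
    if isinstance(group, GenotypeGroup):
        return group
    return GenotypeGroup("", list(group))


def fertility_contrast(groupA, groupB) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on offspring counts.

    Exact enumeration when both groups have n <= 10 and no ties span the
    groups; normal approximation with tie correction otherwise. Returns
    (U statistic, p-value).
    """
    a = _records(groupA)
    b = _records(groupB)
    if not a.records or not b.records:
        raise ValueError("empty genotype group")
    ta = np.array([r.T if hasattr(r, "T") else float(r) for r in a.records], dtype=float)
    tb = np.array([r.T if hasattr(r, "T") else float(r) for r in b.records], dtype=float)
    both = np.concatenate([ta, tb])
    has_ties = len(np.unique(both)) < len(both)
    method = "exact" if (len(ta) <= 10 and len(tb) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(ta, tb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _binom_ll(f: np.ndarray, m: np.ndarray, p: float) -> float:
    # kernel only; binomial coefficients cancel in the LR
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.sum(f) * np.log(p) + np.sum(m) * np.log(1.0 - p))


def sexratio_contrast(groupA, groupB) -> tuple[float, float, bool]:
    """Likelihood-ratio test of a group effect on per-male sex counts.

    The binomial logistic model with a single group indicator has closed-form
    MLEs (each group's pooled female proportion), so the LR statistic is
    computed directly and referred to chi-square with 1 df. Groups whose
    pooled counts are all one sex get a 0.5-count continuity adjustment and
    the result is flagged (third return value).
    """
    a = _records(groupA)
    b = _records(groupB)
    if not a.records or not b.records:
        raise ValueError("empty genotype group")
    fa, ma = a.counts()
    fb, mb = b.counts()
    if (fa + ma).sum() == 0 or (fb + mb).sum() == 0:
        raise ValueError("group with no offspring")
    adjusted = False
    for f, m in ((fa, ma), (fb, mb)):
        if f.sum() == 0 or m.sum() == 0:
            adjusted = True
    if adjusted:
        fa, ma = fa + 0.5 / len(fa), ma + 0.5 / len(ma)
        fb, mb = fb + 0.5 / len(fb), mb + 0.5 / len(mb)
    pa = fa.sum() / (fa.sum() + ma.sum())
    pb = fb.sum() / (fb.sum() + mb.sum())
    p0 = (fa.sum() + fb.sum()) / (fa.sum() + ma.sum() + fb.sum() + mb.sum())
    ll1 = _binom_ll(fa, ma, pa) + _binom_ll(fb, mb, pb)
    ll0 = _binom_ll(fa, ma, p0) + _binom_ll(fb, mb, p0)
    lr = max(2.0 * (ll1 - ll0), 0.0)
    return float(lr), float(stats.chi2.sf(lr, df=1)), adjusted


def dominance_index(k0: float, k1: float, k2: float) -> float:
    """Dominance of a suppressor from sex ratios at 0/1/2 copies.

    d = (k1 - k2) / (k0 - k2). d in (0, 1) means semidominant suppression;
    d -> 0 means one copy suppresses fully (dominant suppression); d -> 1
    means one copy does nothing (recessive suppression). Requires k0 > k2
    (the suppressor actually suppresses). Invariant to affine rescaling of
    the three sex ratios.
    """
    if k0 <= k2:
        raise ValueError("dominance undefined unless k0 > k2")
    return (k1 - k2) / (k0 - k2)
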