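"""Quartile odds ratios, mitotic mean-methylation scores, group tests.

The quartile odds ratio asks whether membership in one quartile of a
score — with quartile boundaries defined on a *reference* (control)
population — is associated with case status. The default Wald 95% CI is
``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``; a median-unbiased
mid-p estimator (the convention of epidemiology toolkits) is available
as an option. Zero cells trigger a flagged Haldane continuity correction
(0.5 added to every cell), never a silent one.

Mitotic-proxy scores are unweighted mean methylation over a curated CpG
set (e.g. polycomb-target promoter CpGs, solo-WCGW CpGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .datamodel import BetaMatrix, CpGSet

__all__ = ["TwoByTwoTable", "OddsRatioResult", "quartile_odds_ratio",
           "odds_ratio", "mean_methylation_score", "group_compare",
           "GroupCompareResult"]

QUARTILE_NAMES = ("lowest", "second", "third", "highest")


@dataclass
class TwoByTwoTable:
    """Counts: a = exposed cases, b = exposed controls, c/d = unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty 2x2 table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


@dataclass
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    table: TwoByTwoTable
    method: str = "wald"
    continuity_corrected: bool = False


def _wald_ci(a, b, c, d, level=0.95):
    z = sps.norm.ppf(0.5 + level / 2)
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def _midp_estimate(table: TwoByTwoTable) -> float:
    """Median-unbiased OR: psi where the mid-p of the conditional
    (non-central hypergeometric) distribution equals 0.5."""
    a, b, c, d = table.cells
    x = a
    M = a + b + c + d
    n1 = a + b          # exposed margin
    N1 = a + c          # case margin

    def midp(psi):
        dist = sps.nchypergeom_fisher(M, n1, N1, psi)
        return dist.sf(x) + 0.5 * dist.pmf(x) - 0.5

    lo, hi = 1e-8, 1e8
    try:
        return float(brentq(midp, lo, hi, maxiter=200))
    except ValueError:
        # root outside bracket: OR effectively 0 or infinite
        return float("inf") if midp(hi) > 0 else 0.0


def odds_ratio(table: TwoByTwoTable, method: str = "wald",
               level: float = 0.95) -> OddsRatioResult:
    """OR and CI for a 2x2 table; Haldane-corrected (flagged) on zero cells."""
    if method not in ("wald", "midp"):
        raise ValueError(f"unknown method {method!r}")
    a, b, c, d = table.cells
    corrected = False
    if min(a, b, c, d) == 0:
        corrected = True
        a, b, c, d = (v + 0.5 for v in table.cells)
    if method == "midp":
        est = _midp_estimate(table)
        ci_low, ci_high = _wald_ci(a, b, c, d, level)
    else:
        est = (a * d) / (b * c)
        ci_low, ci_high = _wald_ci(a, b, c, d, level)
    return OddsRatioResult(float(est), ci_low, ci_high, table, method, corrected)


def quartile_odds_ratio(values, is_case, reference_mask,
                        quartile: str = "lowest", method: str = "wald",
                        ) -> OddsRatioResult:
    """Odds ratio of case status for membership in a reference-defined quartile.

    Quartile boundaries are the 25/50/75th percentiles (linear-interpolation,
    type-7 convention) of the reference samples' values; a value exactly on
    a boundary falls in the lower quartile. Exposure = membership in the
    designated quartile (default: lowest).
    """
    values = np.asarray(values, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    mask = np.asarray(reference_mask, dtype=bool)
    if not (values.shape == is_case.shape == mask.shape):
        raise ValueError("values, is_case and reference_mask must share length")
    if np.isnan(values).any():
        raise ValueError("values must be complete")
    if quartile not in QUARTILE_NAMES:
        raise ValueError(f"quartile must be one of {QUARTILE_NAMES}")
    if mask.sum() < 4:
        raise ValueError("reference must contain at least 4 samples")
    q1, q2, q3 = np.percentile(values[mask], [25, 50, 75])
    # boundary ties go to the lower quartile
    bin_idx = np.searchsorted([q1, q2, q3], values, side="left")
    exposed = bin_idx == QUARTILE_NAMES.index(quartile)
    table = TwoByTwoTable(
        a=int(np.sum(exposed & is_case)),
        b=int(np.sum(exposed & ~is_case)),
        c=int(np.sum(~exposed & is_case)),
        d=int(np.sum(~exposed & ~is_case)),
    )
    return odds_ratio(table, method=method)


def mean_methylation_score(beta: BetaMatrix, cpg_set: CpGSet,
                           ) -> tuple[pd.Series, int]:
    """Per-sample unweighted mean beta over the set/matrix intersection.

    Returns the scores (indexed by sample) and the intersection size.
    """
    shared = [c for c in beta.cpg_ids if c in cpg_set.members]
    if not shared:
        raise ValueError(f"no CpGs of set {cpg_set.name!r} present in the matrix")
    sub = beta.select_cpgs(shared)
    scores = pd.Series(np.nanmean(sub.values, axis=0),
                       index=list(beta.sample_ids), name=cpg_set.name)
    return scores, len(shared)


@dataclass
class GroupCompareResult:
    test: str
    comparisons: list  # (group_a, group_b, statistic, p)
    degenerate: bool = False

    @property
    def p(self) -> float:
        """Single p-value for two-group designs."""
        if len(self.comparisons) != 1:
            raise ValueError("multiple comparisons; inspect .comparisons")
        return self.comparisons[0][3]


def group_compare(values, groups, design: str = "unpaired",
                  pair_ids=None) -> GroupCompareResult:
    """Rank tests for 2 groups, one-way ANOVA + Tukey HSD for more.

    Two groups: Wilcoxon rank-sum (unpaired) or signed-rank (paired,
    requiring ``pair_ids`` to match observations across the two groups).
    More than two: one-way ANOVA with Tukey honest-significant-difference
    per-pair p-values. Paired data in which every within-pair difference
    is zero is degenerate and reported as such (p = NaN).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if design not in ("unpaired", "paired"):
        raise ValueError(f"design must be 'unpaired' or 'paired', got {design!r}")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    by_label = {g: values[groups == g] for g in labels}

    if len(labels) == 2:
        ga, gb = labels
        if design == "paired":
            if pair_ids is None:
                raise ValueError("paired design requires pair_ids")
            pair_ids = np.asarray(pair_ids)
            ids_a = pair_ids[groups == ga]
            ids_b = pair_ids[groups == gb]
            if sorted(ids_a) != sorted(ids_b) or len(set(ids_a)) != len(ids_a):
                raise ValueError("paired design requires one matched id per group")
            order_b = {pid: v for pid, v in zip(ids_b, by_label[gb])}
            diffs = by_label[ga] - np.array([order_b[pid] for pid in ids_a])
            if np.all(diffs == 0):
                return GroupCompareResult("wilcoxon_signed_rank",
                                          [(ga, gb, float("nan"), float("nan"))],
                                          degenerate=True)
            stat, p = sps.wilcoxon(diffs)
            return GroupCompareResult("wilcoxon_signed_rank",
                                      [(ga, gb, float(stat), float(p))])
        stat, p = sps.mannwhitneyu(by_label[ga], by_label[gb],
                                   alternative="two-sided")
        return GroupCompareResult("wilcoxon_rank_sum",
                                  [(ga, gb, float(stat), float(p))])

    if design == "paired":
        raise ValueError("paired design supports exactly two groups")
    f_stat, _ = sps.f_oneway(*(by_label[g] for g in labels))
    hsd = sps.tukey_hsd(*(by_label[g] for g in labels))
    comparisons = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            comparisons.append((labels[i], labels[j],
                                float(hsd.statistic[i, j]),
                                float(hsd.pvalue[i, j])))
    return GroupCompareResult("anova_tukey_hsd", comparisons)
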