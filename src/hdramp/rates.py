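"""Sample-level HDR statistics and group comparisons.

Percentages are over reads passing QC (``n_analyzed``); total HDR is by
construction the sum of perfect and erroneous repair, all three defined
by presence of the planned substitution closest to the cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CATEGORIES, ReadLabel
from .design import RepairTemplate

__all__ = [
    "SampleRates",
    "GroupComparison",
    "aggregate",
    "position_curve",
    "compare_groups",
    "screen_founders",
]

log = logging.getLogger(__name__)


@dataclass
class SampleRates:
    n_analyzed: int
    counts: dict[str, int]
    total_hdr_pct: float
    perfect_pct: float
    erroneous_pct: float
    per_position_perfect_pct: dict[int, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"n_analyzed": self.n_analyzed}
        row.update({f"n_{c}": self.counts.get(c, 0) for c in CATEGORIES})
        row.update(
            {
                "total_hdr_pct": self.total_hdr_pct,
                "perfect_pct": self.perfect_pct,
                "erroneous_pct": self.erroneous_pct,
            }
        )
        for r, v in sorted(self.per_position_perfect_pct.items()):
            row[f"pos_{r:+d}_pct"] = v
        return row


def aggregate(labels: list[ReadLabel], template: RepairTemplate | None = None) -> SampleRates:
    """Collapse per-read labels into sample rates.

    ``perfect_pct + erroneous_pct == total_hdr_pct`` exactly on counts.
    An empty input yields zero counts and percentages (with a warning).
    """
    counts = {c: 0 for c in CATEGORIES}
    for lab in labels:
        counts[lab.category] += 1
    n = len(labels)
    if n == 0:
        log.warning("aggregate called with no labels; percentages reported as zero")
        return SampleRates(0, counts, 0.0, 0.0, 0.0)
    perfect = counts["HDR_perfect"]
    erroneous = counts["HDR_erroneous"]
    rates = SampleRates(
        n_analyzed=n,
        counts=counts,
        total_hdr_pct=100.0 * (perfect + erroneous) / n,
        perfect_pct=100.0 * perfect / n,
        erroneous_pct=100.0 * erroneous / n,
    )
    if template is not None:
        rates.per_position_perfect_pct = position_curve(labels, template)
    return rates


def position_curve(labels: list[ReadLabel], template: RepairTemplate) -> dict[int, float]:
    """Percentage of reads that are non-erroneous and carry each planned
    substitution — the per-position scarless incorporation curve."""
    n = len(labels)
    curve: dict[int, float] = {}
    erroneous = {"HDR_erroneous", "integration_without_hdr", "ambiguous"}
    for r in template.rel_positions:
        if n == 0:
            curve[r] = 0.0
            continue
        k = sum(
            1 for lab in labels if lab.category not in erroneous and lab.presence.get(r, False)
        )
        curve[r] = 100.0 * k / n
    return curve


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)  # adjusted p
    detail: dict = field(default_factory=dict)


def _values(samples: dict[str, list[SampleRates]], metric: str) -> dict[str, np.ndarray]:
    return {g: np.array([getattr(s, metric) for s in ss], float) for g, ss in samples.items()}


def _anova_blocked(vals: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA with replicate (experiment) as a blocking factor;
    replicate i of every group is assumed to come from the same block."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ns = {len(v) for v in vals.values()}
    if len(ns) != 1 or ns.pop() < 2:
        raise ValueError("degenerate design: blocked ANOVA needs equal replicate counts >= 2")
    rows = [
        {"group": g, "block": f"b{i}", "value": x}
        for g, v in vals.items()
        for i, x in enumerate(v)
    ]
    df = pd.DataFrame(rows)
    fit = smf.ols("value ~ C(group) + C(block)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return GroupComparison(
        test="anova_blocked",
        statistic=float(table.loc["C(group)", "F"]),
        p_value=float(table.loc["C(group)", "PR(>F)"]),
        detail={"df_group": float(table.loc["C(group)", "df"])},
    )


def _dunn_bonferroni(vals: dict[str, np.ndarray]) -> GroupComparison:
    """Kruskal–Wallis followed by Dunn's pairwise z tests with Bonferroni
    correction (tie-corrected, standard rank-sum formulation)."""
    groups = sorted(vals)
    data = [vals[g] for g in groups]
    H, p = sps.kruskal(*data)
    pooled = np.concatenate(data)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1)) if N > 1 else 0.0
    mean_ranks = {}
    start = 0
    for g, v in zip(groups, data):
        mean_ranks[g] = ranks[start : start + len(v)].mean()
        start += len(v)
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = {}
    raw = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            ni, nj = len(vals[gi]), len(vals[gj])
            se = np.sqrt((N * (N + 1) / 12 - tie_term) * (1 / ni + 1 / nj))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            praw = 2 * sps.norm.sf(abs(z))
            raw[(gi, gj)] = float(praw)
            pairwise[(gi, gj)] = float(min(1.0, praw * m))
    return GroupComparison(
        test="kruskal_wallis_dunn_bonferroni",
        statistic=float(H),
        p_value=float(p),
        pairwise=pairwise,
        detail={"pairwise_raw": raw, "n_comparisons": m},
    )


def _two_sample(vals: dict[str, np.ndarray], test: str) -> GroupComparison:
    if len(vals) != 2:
        raise ValueError("t-test / Mann-Whitney require exactly two groups")
    a, b = (vals[g] for g in sorted(vals))
    if test == "t_test":
        stat, p = sps.ttest_ind(a, b)
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(test=test, statistic=float(stat), p_value=float(p))


def _normality_gate(vals: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """Shapiro–Wilk on each group: any rejection routes to Mann–Whitney."""
    for v in vals.values():
        if len(v) < 3 or np.ptp(v) == 0:
            return "mann_whitney_u"
        if sps.shapiro(v).pvalue < alpha:
            return "mann_whitney_u"
    return "t_test"


def compare_groups(
    samples: dict[str, list[SampleRates]],
    design: str,
    metric: str = "total_hdr_pct",
    normality_alpha: float = 0.05,
) -> list[GroupComparison]:
    """Run the study's group-comparison battery.

    ``design``: ``anova_blocked`` (symmetric-template contrasts, replicate
    as block), ``kruskal_wallis_dunn_bonferroni`` (asymmetric templates),
    ``t_test``, ``mann_whitney_u``, or ``auto`` (two groups; Shapiro–Wilk
    at ``normality_alpha`` chooses t vs Mann–Whitney).
    """
    if len(samples) < 2:
        raise ValueError("degenerate design: need at least two groups")
    vals = _values(samples, metric)
    if any(len(v) < 2 for v in vals.values()):
        raise ValueError("degenerate design: every group needs >= 2 replicates")
    if design == "anova_blocked":
        return [_anova_blocked(vals)]
    if design == "kruskal_wallis_dunn_bonferroni":
        return [_dunn_bonferroni(vals)]
    if design in ("t_test", "mann_whitney_u"):
        return [_two_sample(vals, design)]
    if design == "auto":
        return [_two_sample(vals, _normality_gate(vals, normality_alpha))]
    raise ValueError(f"unknown design {design!r}")


def screen_founders(
    samples: list[tuple[str, SampleRates]], threshold: float = 10.0
) -> pd.DataFrame:
    """Flag founders whose germ-cell perfect (scarless) repair percentage
    exceeds ``threshold`` — candidates for germline transmission."""
    rows = [
        {
            "founder_id": fid,
            "n_analyzed": r.n_analyzed,
            "perfect_pct": r.perfect_pct,
            "erroneous_pct": r.erroneous_pct,
            "total_hdr_pct": r.total_hdr_pct,
            "flagged": r.perfect_pct > threshold,
        }
        for fid, r in samples
    ]
    return pd.DataFrame(rows, columns=["founder_id", "n_analyzed", "perfect_pct", "erroneous_pct", "total_hdr_pct", "flagged"])
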