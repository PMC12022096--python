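"""Control-calibrated screen QC.

The depletion threshold is the 5th percentile of the negative-control LFC
distribution; guides strictly below it count as depleted.  Screen
performance is summarised as the ROC AUC separating positive from negative
controls, computed as the normalized Mann-Whitney U statistic of depletion
scores (ties counted one half), which equals the area under the empirical
ROC curve and is invariant to monotone transformations of the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats


class QcError(ValueError):
    pass


def _unfiltered(lfc_table: pd.DataFrame) -> pd.DataFrame:
    if "filtered" in lfc_table.columns:
        return lfc_table[~lfc_table["filtered"]]
    return lfc_table


def depletion_threshold(
    lfc_table: pd.DataFrame, percentile: float = 5, category: str = "NEG"
) -> float:
    """Percentile (linear interpolation) of the control-category LFCs."""
    sub = _unfiltered(lfc_table)
    vals = sub.loc[sub["category"] == category, "lfc_mean"].to_numpy()
    if len(vals) < 5:
        raise QcError(
            f"need >=5 {category} guides for a percentile threshold, "
            f"got {len(vals)}"
        )
    return float(np.percentile(vals, percentile, method="linear"))


def category_rates(
    lfc_table: pd.DataFrame, threshold: float, direction: str = "below"
) -> dict[str, float]:
    """Per-category fraction of unfiltered guides strictly past threshold."""
    if direction not in ("below", "above"):
        raise QcError("direction must be 'below' or 'above'")
    sub = _unfiltered(lfc_table)
    rates: dict[str, float] = {}
    for cat, grp in sub.groupby("category"):
        vals = grp["lfc_mean"].to_numpy()
        if len(vals) == 0:
            rates[cat] = float("nan")
        elif direction == "below":
            rates[cat] = float((vals < threshold).mean())
        else:
            rates[cat] = float((vals > threshold).mean())
    return rates


def roc_auc(
    lfc_table: pd.DataFrame,
    positives: str = "POS",
    negatives: str = "NEG",
) -> float:
    """AUC separating control sets, scoring more-depleted guides higher.

    Equals U / (|POS| * |NEG|) with ties counted one half -- the integral
    of the empirical ROC curve.
    """
    sub = _unfiltered(lfc_table)
    pos = -sub.loc[sub["category"] == positives, "lfc_mean"].to_numpy()
    neg = -sub.loc[sub["category"] == negatives, "lfc_mean"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise QcError("both control sets must be non-empty")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def rank_sum_compare(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise QcError("each group needs at least 3 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class QcReport:
    """Threshold, per-category depletion rates, control AUC, group tests."""

    threshold: float
    category_rates: dict[str, float]
    auc: float
    group_tests: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def __str__(self) -> str:
        lines = [
            f"depletion threshold (NEG 5th pct): {self.threshold:.3f}",
            f"POS-vs-NEG ROC AUC: {self.auc:.3f}",
            "depleted fraction by category:",
        ]
        for cat, rate in sorted(self.category_rates.items()):
            lines.append(f"  {cat}: {rate:.1%}")
        for t in self.group_tests:
            lines.append(
                f"rank-sum {t['groups']}: U={t['statistic']:.1f} p={t['p']:.3g}"
            )
        return "\n".join(lines)


def qc_report(
    lfc_table: pd.DataFrame,
    percentile: float = 5,
    direction: str = "below",
    compare: tuple[str, str] | None = ("CDS", "NEG"),
) -> QcReport:
    """Standard drop-out QC: threshold, rates, AUC, optional group test."""
    thr = depletion_threshold(lfc_table, percentile)
    rates = category_rates(lfc_table, thr, direction)
    auc = roc_auc(lfc_table)
    tests = []
    if compare is not None:
        sub = _unfiltered(lfc_table)
        a = sub.loc[sub["category"] == compare[0], "lfc_mean"]
        b = sub.loc[sub["category"] == compare[1], "lfc_mean"]
        if len(a) >= 3 and len(b) >= 3:
            u, p = rank_sum_compare(a, b)
            tests.append({"groups": list(compare), "statistic": u, "p": p})
    return QcReport(thr, rates, auc, tests)
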