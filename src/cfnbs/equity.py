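"""Equity statistics: 2x2 odds ratios, rank tests, median/IQR summaries.

Odds ratios follow the univariable-logistic convention: for a binary
exposure the sample OR ``(a*d)/(b*c)`` equals the logistic-regression
estimate, with a Wald 95% CI on the log scale and a two-sided Wald p-value.
Zero cells receive the Haldane-Anscombe +0.5 continuity correction (applied
to all four cells and flagged in the result).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MINORITIZED_RACES  # noqa: F401  (re-exported convenience)

__all__ = [
    "ContingencyTable",
    "ORResult",
    "build_table",
    "odds_ratio",
    "rank_test",
    "kruskal",
    "median_iqr",
    "or_table",
    "OUTCOME_CONTRASTS",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 group-by-outcome counts.

    a = exposed with the outcome, b = exposed without,
    c = reference with, d = reference without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency counts must be non-negative")
        # an all-zero table is representable (empty registry) but has no
        # defined odds ratio; odds_ratio() rejects it


@dataclass(frozen=True)
class ORResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool


def build_table(
    registry: pd.DataFrame,
    group_var: str,
    exposed_level: str,
    reference_level: str,
    outcome,
) -> ContingencyTable:
    """Tabulate CF records by group level and outcome predicate.

    ``outcome`` is a callable mapping the classified registry to a boolean
    Series (or an outcome-contrast name from :data:`OUTCOME_CONTRASTS`).
    Records at neither level are excluded.
    """
    if group_var not in registry.columns:
        raise KeyError(f"unknown grouping column {group_var!r}")
    cf = registry[registry["has_cf"]] if "has_cf" in registry.columns else registry
    if isinstance(outcome, str):
        cf, flag = OUTCOME_CONTRASTS[outcome](cf)
    else:
        flag = outcome(cf)
    exposed = cf[group_var] == exposed_level
    reference = cf[group_var] == reference_level
    flag = np.asarray(flag, dtype=bool)
    return ContingencyTable(
        a=int((exposed & flag).sum()),
        b=int((exposed & ~flag).sum()),
        c=int((reference & flag).sum()),
        d=int((reference & ~flag).sum()),
    )


def odds_ratio(table: ContingencyTable, correction_policy: str = "haldane") -> ORResult:
    """Odds ratio with Wald 95% CI and two-sided Wald p-value.

    ``correction_policy='haldane'`` adds 0.5 to every cell when any cell is
    zero; ``'none'`` raises on zero cells instead.
    """
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    if cells.sum() == 0:
        raise ValueError("odds ratio undefined for an all-zero table")
    corrected = False
    if (cells == 0).any():
        if correction_policy == "haldane":
            cells = cells + 0.5
            corrected = True
        else:
            raise ValueError("zero cell without continuity correction")
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ORResult(
        or_estimate=math.exp(log_or),
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        p_value=float(p),
        corrected=corrected,
    )


def rank_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have n <= 8 and no ties; otherwise
    the tie-corrected normal approximation. Returns (U statistic, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank test requires nonempty samples")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test (chi-square approximation, tie-corrected)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis requires nonempty groups")
    allvals = np.concatenate(groups)
    if np.all(allvals == allvals[0]):
        return 0.0, 1.0  # a single tied value everywhere: no separation
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) by linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a nonempty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# outcome contrasts (denominators derived by exclusion, not hard-coded)
# ---------------------------------------------------------------------------

_MISSED = ("missed_low_irt", "missed_genetics")


def _delayed_or_missed(cf: pd.DataFrame):
    keep = cf["category"].isin(("on_time", "delayed") + _MISSED)
    sub = cf[keep]
    return sub, sub["category"] != "on_time"


def _missed_only(cf: pd.DataFrame):
    keep = cf["category"].isin(("on_time",) + _MISSED)
    sub = cf[keep]
    return sub, sub["category"].isin(_MISSED)


def _delayed_only(cf: pd.DataFrame):
    keep = cf["category"].isin(("on_time", "delayed"))
    sub = cf[keep]
    return sub, sub["category"] == "delayed"


OUTCOME_CONTRASTS = {
    "delayed_or_missed": _delayed_or_missed,
    "missed_only": _missed_only,
    "delayed_only": _delayed_only,
}

#: race contrast groups: reference is White; "OtherCombined" pools the small
#: race categories as registries commonly report them
_RACE_GROUPS = {"Black": ("Black",), "OtherCombined": ("OtherRace", "Multiracial")}


def or_table(classified: pd.DataFrame, correction_policy: str = "haldane") -> pd.DataFrame:
    """Odds-ratio table across race/ethnicity contrasts and outcome columns.

    Rows: Black vs White, pooled-other-race vs White, Hispanic vs NonHispanic;
    one per outcome contrast (delayed-or-missed / missed-only / delayed-only
    vs on-time). Denominators differ per contrast because the excluded
    category is dropped from both arms.
    """
    cf = classified[classified["has_cf"]]
    rows = []
    for contrast in OUTCOME_CONTRASTS:
        sub, flag = OUTCOME_CONTRASTS[contrast](cf)
        flag = np.asarray(flag, dtype=bool)
        comparisons = [
            ("race", "Black", _RACE_GROUPS["Black"], ("White",)),
            ("race", "OtherCombined", _RACE_GROUPS["OtherCombined"], ("White",)),
            ("ethnicity", "Hispanic", ("Hispanic",), ("NonHispanic",)),
        ]
        for var, label, exp_levels, ref_levels in comparisons:
            exposed = sub[var].isin(exp_levels).to_numpy()
            reference = sub[var].isin(ref_levels).to_numpy()
            table = ContingencyTable(
                a=int((exposed & flag).sum()),
                b=int((exposed & ~flag).sum()),
                c=int((reference & flag).sum()),
                d=int((reference & ~flag).sum()),
            )
            res = odds_ratio(table, correction_policy)
            rows.append(
                {
                    "contrast": contrast,
                    "group": label,
                    "reference": ref_levels[0],
                    "n": int(exposed.sum() + reference.sum()),
                    "or": res.or_estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "corrected": res.corrected,
                }
            )
    return pd.DataFrame(rows)
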