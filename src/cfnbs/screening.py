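"""Two-tier screening algorithm, outcome classification and counterfactuals.

Tier 1 compares the dried-blood-spot IRT with the day's effective cut-off.
Specimens at or above the cut-off are genotyped against a CFTR variant
panel; zero detected variants is reported as a *negative* screen even though
IRT was elevated, one variant routes to confirmatory sweat-chloride testing,
two variants route directly to a CF centre.

Children with CF whose screen was negative are *missed* — split into
missed-low-IRT (tier 1) and missed-genetics (tier 2). Children with CF and a
positive screen whose diagnosis lands after 28 days of age are *delayed*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cutoffs import CutoffModel
from .registry import QNS, genotype_of

__all__ = [
    "PanelDefinition",
    "ScreenResult",
    "DiagnosisOutcome",
    "load_panel",
    "screen_infant",
    "screen_registry",
    "classify_outcome",
    "classify_registry",
    "sweat_classify",
    "counterfactual_cutoffs",
    "counterfactual_panels",
    "cohort_summary",
    "TwoTierScreener",
    "DISPOSITIONS",
    "CATEGORIES",
    "DELAY_REASONS",
]

DISPOSITIONS = (
    "negative_low_irt",
    "negative_no_variants",
    "positive_one_variant",
    "positive_two_variants",
)

CATEGORIES = ("on_time", "delayed", "missed_low_irt", "missed_genetics", "not_cf")

#: sentinel for CF cases with a positive screen but no recorded diagnosis date
UNDIAGNOSED = "undiagnosed"

DELAY_REASONS = (
    "sweat_qns",
    "sweat_intermediate",
    "sweat_scheduling",
    "contact_difficulty",
    "sample_quality",
    "minimal_delay",
    "genetics_delay",
    "unknown",
)

#: number of days between birth and specimen collection assumed when
#: converting diagnosis dates to ages (heel pricks happen at 24-48 h of age)
BIRTH_OFFSET_DAYS = 2

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    return _WS.sub(" ", name.strip())


@dataclass(frozen=True)
class PanelDefinition:
    """A named set of CFTR variants assayed at tier 2."""

    name: str
    variants: frozenset[str]

    def __post_init__(self):
        if not self.name:
            raise ValueError("panel name must be nonempty")
        object.__setattr__(self, "variants", frozenset(_norm(v) for v in self.variants))

    def __contains__(self, variant: str) -> bool:
        return _norm(variant) in self.variants

    def detected(self, genotype: list[str]) -> int:
        """Alleles of ``genotype`` on this panel (a panel homozygote counts 2)."""
        return sum(1 for v in genotype if v in self)


def load_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a panel file: UTF-8, one variant name per line, ``#`` comments."""
    path = Path(path)
    variants: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            variants.append(_norm(line))
    if len(set(variants)) != len(variants):
        dupes = sorted({v for v in variants if variants.count(v) > 1})
        raise ValueError(f"panel {path.name}: duplicate variant name(s) {dupes}")
    return PanelDefinition(name or path.stem, frozenset(variants))


@dataclass(frozen=True)
class ScreenResult:
    """Routing outcome of the two-tier algorithm for one infant."""

    tier1: str  # below_cutoff | above_cutoff
    variants_detected: int | None  # defined only when tier1 == above_cutoff
    disposition: str
    applied_cutoff: float


@dataclass(frozen=True)
class DiagnosisOutcome:
    category: str
    age_at_diagnosis_days: int | None = None
    delay_reason: str | None = None


def screen_infant(record, panel: PanelDefinition, cutoff: float) -> ScreenResult:
    """Route one infant through the two-tier algorithm at a given cut-off."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    irt = float(record["irt"])
    if irt < cutoff:
        return ScreenResult("below_cutoff", None, "negative_low_irt", float(cutoff))
    detected = panel.detected(genotype_of(record))
    disposition = {
        0: "negative_no_variants",
        1: "positive_one_variant",
        2: "positive_two_variants",
    }[detected]
    return ScreenResult("above_cutoff", detected, disposition, float(cutoff))


def screen_registry(registry: pd.DataFrame, panel: PanelDefinition, cutoffs) -> pd.DataFrame:
    """Vectorised :func:`screen_infant` over a registry.

    ``cutoffs`` is a scalar or a per-row array of effective cut-offs.
    Returns columns ``tier1, variants_detected, disposition, applied_cutoff``.
    """
    cut = np.broadcast_to(np.asarray(cutoffs, dtype=float), (len(registry),)).copy()
    if (cut <= 0).any():
        raise ValueError("cutoffs must be > 0")
    irt = registry["irt"].to_numpy(dtype=float)
    above = irt >= cut
    detected = np.array(
        [panel.detected(genotype_of(row)) if a else -1 for a, (_, row) in zip(above, registry.iterrows())]
    )
    disposition = np.where(
        ~above,
        "negative_low_irt",
        np.choose(np.clip(detected, 0, 2), ["negative_no_variants", "positive_one_variant", "positive_two_variants"]),
    )
    return pd.DataFrame(
        {
            "tier1": np.where(above, "above_cutoff", "below_cutoff"),
            "variants_detected": pd.array(np.where(above, detected, pd.NA), dtype="Int64"),
            "disposition": disposition,
            "applied_cutoff": cut,
        },
        index=registry.index,
    )


def classify_outcome(
    record, screen: ScreenResult, birth_offset_days: int = BIRTH_OFFSET_DAYS
) -> DiagnosisOutcome:
    """Diagnostic outcome category for one infant given its screen result.

    Birth is anchored at ``specimen_date - birth_offset_days``; a diagnosis
    strictly more than 28 days after birth despite a positive screen is
    *delayed*. CF cases with a positive screen but no diagnosis date are
    flagged with the ``undiagnosed`` sentinel rather than silently dropped.
    """
    if not bool(record["has_cf"]):
        return DiagnosisOutcome("not_cf")

    diag = record["diagnosis_date"]
    age = None
    if pd.notna(diag):
        birth = pd.Timestamp(record["specimen_date"]) - pd.Timedelta(days=birth_offset_days)
        age = int((pd.Timestamp(diag) - birth).days)

    if screen.disposition == "negative_low_irt":
        return DiagnosisOutcome("missed_low_irt", age)
    if screen.disposition == "negative_no_variants":
        return DiagnosisOutcome("missed_genetics", age)

    if age is None:
        return DiagnosisOutcome(UNDIAGNOSED, None)
    reason = record.get("delay_reason") if hasattr(record, "get") else None
    reason = reason if isinstance(reason, str) and reason else None
    if age > 28:
        return DiagnosisOutcome("delayed", age, reason or "unknown")
    return DiagnosisOutcome("on_time", age)


def classify_registry(
    registry: pd.DataFrame, screens: pd.DataFrame, birth_offset_days: int = BIRTH_OFFSET_DAYS
) -> pd.DataFrame:
    """Per-row outcome classification; returns category/age/delay_reason columns."""
    out = []
    for (_, row), (_, scr) in zip(registry.iterrows(), screens.iterrows()):
        res = classify_outcome(
            row,
            ScreenResult(scr["tier1"], scr["variants_detected"], scr["disposition"], scr["applied_cutoff"]),
            birth_offset_days,
        )
        out.append((res.category, res.age_at_diagnosis_days, res.delay_reason))
    return pd.DataFrame(
        out,
        columns=["category", "age_at_diagnosis_days", "delay_reason"],
        index=registry.index,
    ).astype({"age_at_diagnosis_days": "Int64"})


def sweat_classify(chloride) -> str:
    """Classify a sweat-chloride result: >=60 CF-range, 30-59 intermediate,
    <30 negative, ``QNS`` token for insufficient collections."""
    if isinstance(chloride, str):
        if chloride.strip().upper() == QNS:
            return "qns"
        chloride = float(chloride)
    value = float(chloride)
    if value < 0:
        raise ValueError("sweat chloride cannot be negative")
    if value >= 60:
        return "cf_range"
    if value >= 30:
        return "intermediate"
    return "negative"


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------

class TwoTierScreener(BaseEstimator):
    """The full two-tier screen as a fit/transform estimator.

    ``fit`` fits the tier-1 cut-off model on the registry's specimen stream;
    ``predict`` returns dispositions; ``transform`` returns the screen result
    columns joined with the diagnostic outcome classification.
    """

    def __init__(self, panel: PanelDefinition = None, cutoff: CutoffModel = None,
                 birth_offset_days: int = BIRTH_OFFSET_DAYS):
        self.panel = panel
        self.cutoff = cutoff
        self.birth_offset_days = birth_offset_days

    def fit(self, X: pd.DataFrame, y=None) -> "TwoTierScreener":
        if self.panel is None:
            raise ValueError("TwoTierScreener requires a panel")
        base = self.cutoff if self.cutoff is not None else CutoffModel()
        self.cutoff_model_ = CutoffModel(**base.get_params()).fit(X)
        return self

    def screen(self, X: pd.DataFrame) -> pd.DataFrame:
        cutoffs = self.cutoff_model_.effective_cutoffs(X["specimen_date"])
        return screen_registry(X, self.panel, cutoffs)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.screen(X)["disposition"].to_numpy()

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        screens = self.screen(X)
        outcomes = classify_registry(X, screens, self.birth_offset_days)
        return pd.concat([screens, outcomes], axis=1)


def classify_cohort(
    registry: pd.DataFrame,
    panel: PanelDefinition,
    cutoff: CutoffModel | None = None,
    birth_offset_days: int = BIRTH_OFFSET_DAYS,
) -> pd.DataFrame:
    """Registry joined with its screen results and outcome classification.

    Fits the cut-off model on the registry's own specimen stream. The
    classification's ``delay_reason`` column supersedes any input column of
    the same name.
    """
    screener = TwoTierScreener(panel=panel, cutoff=cutoff, birth_offset_days=birth_offset_days)
    result = screener.fit(registry).transform(registry)
    base = registry.drop(columns=[c for c in result.columns if c in registry.columns])
    return pd.concat([base, result], axis=1)


# ---------------------------------------------------------------------------
# counterfactual evaluation
# ---------------------------------------------------------------------------

def _outcome_counts(outcomes: pd.DataFrame) -> dict[str, int]:
    counts = outcomes["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES + (UNDIAGNOSED,)}


def counterfactual_cutoffs(
    registry: pd.DataFrame,
    strategies: list[CutoffModel],
    panel: PanelDefinition,
    stream: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-screen a registry under each cut-off strategy.

    ``stream`` is the specimen stream the floating percentiles are estimated
    from (defaults to the registry itself). Returns one row per strategy with
    outcome-category counts, the second-tier volume over the stream, and the
    ids of CF cases whose category differs from the first strategy's.
    """
    if registry.empty:
        raise ValueError("counterfactual_cutoffs needs a nonempty registry")
    stream = registry if stream is None else stream

    rows = []
    base_categories: pd.Series | None = None
    for strat in strategies:
        screener = TwoTierScreener(panel=panel, cutoff=strat).fit(stream)
        result = screener.transform(registry)
        counts = _outcome_counts(result)
        volume = int(screener.cutoff_model_.predict(stream).sum())
        cats = result["category"]
        if base_categories is None:
            base_categories = cats
            changed: list[str] = []
        else:
            moved = (cats != base_categories) & registry["has_cf"].to_numpy()
            changed = sorted(registry.loc[moved, "infant_id"])
        rows.append(
            {"strategy": _strategy_label(strat), **counts,
             "second_tier_volume": volume, "changed_cases": ";".join(changed)}
        )
    return pd.DataFrame(rows)


def _strategy_label(model: CutoffModel) -> str:
    if model.mode == "fixed":
        return f"fixed:{model.fixed_value:g}"
    if model.mode == "floating":
        return f"floating:{model.percentile:g}"
    return f"hybrid:{model.percentile:g}:{model.fixed_value:g}"


def counterfactual_panels(
    cases: pd.DataFrame, panels: list[PanelDefinition]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection of missed-genetics cases under alternative variant panels.

    Every case must carry a two-allele genotype. Returns (per-case table with
    one detected-count column per panel, per-panel summary with cases having
    >=1 and ==2 alleles detected and the corresponding fractions).
    """
    per_case = pd.DataFrame({"infant_id": cases["infant_id"].to_numpy()})
    for panel in panels:
        detected = []
        for _, row in cases.iterrows():
            genotype = genotype_of(row)
            if len(genotype) != 2:
                raise ValueError(f"case {row['infant_id']} lacks a two-allele genotype")
            detected.append(panel.detected(genotype))
        per_case[panel.name] = detected

    n = len(cases)
    summary_rows = []
    for panel in panels:
        det = per_case[panel.name]
        ge1, eq2 = int((det >= 1).sum()), int((det == 2).sum())
        summary_rows.append(
            {"panel": panel.name, "n_cases": n, "n_ge1": ge1, "n_eq2": eq2,
             "frac_ge1": ge1 / n if n else np.nan, "frac_eq2": eq2 / n if n else np.nan}
        )
    return per_case, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# demographic summary
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ("overall", "missed", "missed_low_irt", "missed_genetics", "delayed")


def cohort_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Demographic count/percent table over the CF cohort.

    Rows: total, each race, each ethnicity, each sex; columns: overall /
    missed / missed-low-IRT / missed-genetics / delayed, as ``n`` and whole
    percents of each column total.
    """
    cf = classified[classified["has_cf"]] if len(classified) else classified
    masks = {
        "overall": pd.Series(True, index=cf.index),
        "missed": cf["category"].isin(["missed_low_irt", "missed_genetics"])
        if len(cf) else pd.Series(dtype=bool),
        "missed_low_irt": cf["category"] == "missed_low_irt" if len(cf) else pd.Series(dtype=bool),
        "missed_genetics": cf["category"] == "missed_genetics" if len(cf) else pd.Series(dtype=bool),
        "delayed": cf["category"] == "delayed" if len(cf) else pd.Series(dtype=bool),
    }
    rows: list[dict] = []

    def add(characteristic: str, level: str, level_mask) -> None:
        row: dict = {"characteristic": characteristic, "level": level}
        for col, mask in masks.items():
            total = int(mask.sum())
            n = int((mask & level_mask).sum()) if total else 0
            row[f"{col}_n"] = n
            row[f"{col}_pct"] = int(round(100 * n / total)) if total else 0
        rows.append(row)

    everyone = pd.Series(True, index=cf.index)
    add("total", "all", everyone)
    for race in ("Black", "Multiracial", "OtherRace", "White", "Unknown"):
        mask = cf["race"] == race if len(cf) else everyone
        if len(cf) == 0 or mask.any():
            add("race", race, mask)
    for eth in ("Hispanic", "NonHispanic", "Unknown"):
        mask = cf["ethnicity"] == eth if len(cf) else everyone
        if len(cf) == 0 or mask.any():
            add("ethnicity", eth, mask)
    for sex in ("F", "M"):
        mask = cf["sex"] == sex if len(cf) else everyone
        if len(cf) == 0 or mask.any():
            add("sex", sex, mask)
    return pd.DataFrame(rows)
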