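"""Deterministic 390-record CF cohort fixture.

The fixture is an enumerated (randomness-free) registry of children with CF
whose marginal demographic counts reproduce a published statewide cohort
cell-for-cell: 390 children, 18 missed by screening (12 low-IRT, 6 with no
panel variant detected), 30 with delayed diagnosis, and the printed race /
ethnicity / sex breakdown of each column.

The missed column is by definition the union of its low-IRT and genetics
sub-columns. Two printed marginal cells (Black missed = 3, Multiracial
missed = 1) contradict that partition given the printed sub-columns
(Black 3 low-IRT + 1 genetics, Multiracial 0 + 0); the fixture follows the
sub-columns, whose values are corroborated by the narrative case detail, so
its Black missed total is 4 and its Multiracial missed total 0.

Constraints honoured beyond the marginal table:

* 4 of the 12 low-IRT missed have meconium ileus;
* the 3 minoritized low-IRT missed are the 3 Black children (25%);
* 4 of the 6 genetics-missed are Hispanic (67%) and 5 of 6 minoritized,
  which forces exactly one Hispanic genetics-missed child to be of a
  minoritized race (here OtherRace) with the other three White;
* 13 of the 30 delayed are minoritized (6 Black + 2 OtherRace + 5 White
  Hispanic, with one OtherRace child Hispanic);
* 74 children overall (19%) are minoritized, which fixes the cohort-wide
  Hispanic-White joint cell at 18;
* 99 children have specimens dated 2018-2022, one of them (on-time) with
  an IRT of 63.5 ng/mL just above the 55 ng/mL fixed cut-off.

The race-by-ethnicity joint assignment is only partially determined by the
published marginals; unforced joint cells (documented inline) are arbitrary
but fixed. IRT values are representative constants consistent with each
record's category (low-IRT missed < 55 ng/mL, everyone else >= 55 ng/mL).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .registry import REGISTRY_COLUMNS
from .screening import PanelDefinition, load_panel

__all__ = ["make_table1_fixture", "fixture_panel", "fixture_panel_names"]

_PANEL_FILES = {
    "core": "panel_core.txt",
    "expanded139": "panel_expanded139.txt",
    "expanded689": "panel_expanded689.txt",
    "ngs1085": "panel_ngs1085.txt",
}


def fixture_panel_names() -> list[str]:
    return list(_PANEL_FILES)


def fixture_panel(name: str = "core") -> PanelDefinition:
    """Load one of the shipped synthetic panel files."""
    fname = _PANEL_FILES[name]
    with resources.as_file(resources.files("cfnbs.data") / fname) as path:
        return load_panel(Path(path), name=name)


def _row(
    infant_id, specimen, irt, race, eth, sex, v1, v2,
    mi=False, age=None, reason="", sweat=("", ""),
):
    specimen = pd.Timestamp(specimen)
    diagnosis = specimen + pd.Timedelta(days=age - 2) if age is not None else pd.NaT
    return {
        "infant_id": infant_id,
        "specimen_date": specimen,
        "kit_id": f"GSP-{'ABC'[specimen.year % 3]}",
        "irt": float(irt),
        "race": race,
        "ethnicity": eth,
        "sex": sex,
        "has_cf": True,
        "variant1": v1,
        "variant2": v2,
        "meconium_ileus": bool(mi),
        "diagnosis_date": diagnosis,
        "sweat_dates": sweat[0],
        "sweat_results": sweat[1],
        "delay_reason": reason,
    }


def _low_irt_missed() -> list[dict]:
    # 12 records: 3 Black + 9 White, all non-Hispanic; 4 F / 8 M; 4 with
    # meconium ileus (the 3 Black children plus one White, an unforced choice).
    specs = [
        # (date, irt, race, sex, mi, v1, v2, age_days)
        ("2008-03-12", 30.2, "Black", "F", True, "F508del", "3120G->A", 150),
        ("2012-07-21", 21.4, "Black", "M", True, "F508del", "2307insA", 95),
        ("2016-01-08", 27.3, "Black", "M", True, "F508del", "F508del", 210),
        ("2010-05-30", 18.9, "White", "F", True, "F508del", "F508del", 88),
        # narrated-style case: normal screen at 44.5 ng/mL, diagnosed ~20 months
        ("2014-09-17", 44.5, "White", "F", False, "F508del", "3120G->A", 610),
        ("2007-11-02", 49.8, "White", "F", False, "F508del", "G542X", 300),
        ("2011-04-25", 52.1, "White", "M", False, "F508del", "N1303K", 420),
        ("2015-08-14", 41.0, "White", "M", False, "G551D", "F508del", 760),
        # four low-IRT misses fall in the 2018-2022 specimen window
        ("2018-06-19", 38.7, "White", "M", False, "F508del", "F508del", 1342),
        ("2019-10-05", 35.5, "White", "M", False, "F508del", "621+1G->T", 530),
        ("2021-02-11", 46.2, "White", "M", False, "F508del", "W1282X", 1100),
        ("2022-08-27", 24.6, "White", "M", False, "F508del", "F508del", 240),
    ]
    return [
        _row(f"M-L{i + 1:02d}", d, irt, race, "NonHispanic", sex, v1, v2, mi=mi, age=age)
        for i, (d, irt, race, sex, mi, v1, v2, age) in enumerate(specs)
    ]


def _genetics_missed() -> list[dict]:
    # 6 records: race Black 1 / OtherRace 1 / White 4; ethnicity Hispanic 4 /
    # NonHispanic 2; sex 4 F / 2 M. Exactly one Hispanic child is of a
    # minoritized race so that 5 of 6 (not all 6) are minoritized. Genotypes
    # sit off the core panel; their coverage by the expanded fixture panels is
    # deliberate (4/6 on expanded139, 5/6 on expanded689 with one
    # single-variant detection, 5/6 on ngs1085 which lacks large deletions).
    specs = [
        ("2013-04-09", 416.6, "Black", "NonHispanic", "F", True, "CFTRdele1", "CFTRdele21", 1460),
        ("2010-10-22", 246.4, "White", "Hispanic", "F", False, "1811+1634A->G", "3271delGG", 2190),
        ("2012-02-17", 138.2, "OtherRace", "Hispanic", "M", False, "3120G->A", "2307insA", 200),
        ("2008-12-03", 98.6, "White", "Hispanic", "F", False, "H199Y", "2184insA", 400),
        ("2016-06-28", 152.3, "White", "Hispanic", "F", False, "711+3A->G", "1898+5G->T", 310),
        ("2019-03-15", 188.0, "White", "NonHispanic", "M", True, "Q1100P", "c.4242+2T>C", 90),
    ]
    return [
        _row(f"M-G{i + 1:02d}", d, irt, race, eth, sex, v1, v2, mi=mi, age=age)
        for i, (d, irt, race, eth, sex, mi, v1, v2, age) in enumerate(specs)
    ]


# delayed-diagnosis reason mix: sweat-test related reasons cover 15/30 (50%)
_DELAY_REASONS = (
    ["sweat_scheduling"] * 7
    + ["sweat_qns"] * 5
    + ["sweat_intermediate"] * 3
    + ["contact_difficulty"] * 4
    + ["sample_quality"] * 3
    + ["minimal_delay"] * 5
    + ["genetics_delay"] * 3
)


def _delayed() -> list[dict]:
    # 30 records, specimens 2011-2022 (12 of them 2018-2022).
    # Race: Black 6 / OtherRace 2 / White 22; ethnicity Hispanic 6 (one
    # OtherRace + five White, an unforced joint choice); sex 18 F / 12 M.
    # 15 one-variant screens (older at diagnosis) and 15 two-variant screens.
    demo = (
        [("Black", "NonHispanic")] * 6
        + [("OtherRace", "Hispanic"), ("OtherRace", "NonHispanic")]
        + [("White", "Hispanic")] * 5
        + [("White", "NonHispanic")] * 17
    )
    sexes = ["F"] * 18 + ["M"] * 12
    years = [2011 + (i * 5) % 7 for i in range(18)] + [2018 + i % 5 for i in range(12)]
    one_variant_ages = [30, 45, 55, 48, 60, 62, 64, 70, 75, 85, 101, 110]
    two_variant_ages = [29, 30, 31, 31, 32, 33, 34, 34, 35, 36, 38, 39, 41, 43, 45]

    rows: list[dict] = []
    # three narrated-style one-variant cases with recorded sweat tests
    rows.append(
        _row("D01", "2020-04-06", 176.7, "White", "Hispanic", "F", "3876delA", "c.1811del",
             age=92, reason="sweat_scheduling",
             sweat=("2020-07-02;2020-07-02", "104;116"))
    )
    rows.append(
        _row("D02", "2019-09-14", 172.1, "White", "Hispanic", "M", "F508del", "S466X",
             age=36, reason="sweat_scheduling", sweat=("2019-10-17", "90"))
    )
    rows.append(
        _row("D03", "2018-01-23", 120.4, "White", "NonHispanic", "M", "F508del", "622-1G->C",
             age=98, reason="sweat_qns", sweat=("2018-04-09;2018-04-28", "QNS;89"))
    )
    used = {("White", "Hispanic"): 2, ("White", "NonHispanic"): 1}
    used_sex = {"F": 1, "M": 2}

    remaining_demo: list[tuple[str, str]] = []
    for pair in demo:
        if used.get(pair, 0) > 0:
            used[pair] -= 1
        else:
            remaining_demo.append(pair)
    remaining_sexes: list[str] = []
    for s in sexes:
        if used_sex.get(s, 0) > 0:
            used_sex[s] -= 1
        else:
            remaining_sexes.append(s)

    reasons = [r for r in _DELAY_REASONS]
    for r in ("sweat_scheduling", "sweat_scheduling", "sweat_qns"):
        reasons.remove(r)

    one_var_genos = [("F508del", "R1066C"), ("G542X", "A559T"), ("F508del", "405+3A->C")]
    two_var_genos = [("F508del", "F508del"), ("F508del", "G542X"), ("G551D", "F508del")]
    ages = one_variant_ages + two_variant_ages
    for i, ((race, eth), sex, age, reason) in enumerate(
        zip(remaining_demo, remaining_sexes, ages, reasons)
    ):
        one_variant = i < len(one_variant_ages)
        v1, v2 = (one_var_genos if one_variant else two_var_genos)[i % 3]
        year = years[i % len(years)]
        date = f"{year}-{1 + (i * 5) % 12:02d}-{1 + (i * 7) % 28:02d}"
        irt = 58.0 + (i * 9) % 90 + 0.3
        rows.append(
            _row(f"D{i + 4:02d}", date, irt, race, eth, sex, v1, v2, age=age, reason=reason)
        )
    return rows


def _on_time() -> list[dict]:
    # 342 records. Race/ethnicity joint cells (only the totals per race and
    # per ethnicity are forced; the split of the 17 Hispanic children across
    # races is the arbitrary-but-documented remainder of the cohort-wide
    # Hispanic-White cell of 18): Black 4H+23NH, Multiracial 2H+8NH,
    # OtherRace 1H+5NH, White 10H+289NH. Sex alternates F/M (171 each).
    demo = (
        [("Black", "Hispanic")] * 4
        + [("Black", "NonHispanic")] * 23
        + [("Multiracial", "Hispanic")] * 2
        + [("Multiracial", "NonHispanic")] * 8
        + [("OtherRace", "Hispanic")] * 1
        + [("OtherRace", "NonHispanic")] * 5
        + [("White", "Hispanic")] * 10
        + [("White", "NonHispanic")] * 289
    )
    assert len(demo) == 342
    genos = [
        ("F508del", "F508del"), ("F508del", "G542X"), ("F508del", "N1303K"),
        ("G551D", "F508del"), ("F508del", "621+1G->T"), ("W1282X", "F508del"),
        ("F508del", "3849+10kbC->T"), ("F508del", "1717-1G->A"), ("R553X", "F508del"),
    ]
    rows = []
    for i, (race, eth) in enumerate(demo):
        sex = "F" if i % 2 == 0 else "M"
        if i < 260:
            year = 2007 + i % 11  # 2007-2017
        else:
            year = 2018 + i % 5  # 82 specimens in 2018-2022
        date = f"{year}-{1 + (i * 7) % 12:02d}-{1 + (i * 3) % 28:02d}"
        irt = 64.5 + (i * 13) % 80
        v1, v2 = ("F508del", "R1066C") if i % 10 == 0 else genos[i % 9]
        age = 12 + i % 17  # 12..28 days: on time
        if i == 300:
            irt = 63.5  # near-miss IRT barely above the 55 ng/mL fixed cut-off
        rows.append(_row(f"C{i + 1:03d}", date, irt, race, eth, sex, v1, v2, age=age))
    return rows


def make_table1_fixture() -> pd.DataFrame:
    """Build the deterministic 390-record CF cohort registry."""
    rows = _low_irt_missed() + _genetics_missed() + _delayed() + _on_time()
    df = pd.DataFrame(rows)
    assert len(df) == 390
    return df[REGISTRY_COLUMNS + ["delay_reason"]]
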