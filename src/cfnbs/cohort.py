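"""Synthetic screening-registry generation.

The generator emulates the statistical structure a two-tier IRT/DNA
newborn-screening analysis assumes: a right-skewed (lognormal) background IRT
distribution whose upper tail sits near a fixed 55 ng/mL cut-off, a seasonal
sinusoid (winter-higher, summer-lower), multiplicative reagent-kit shifts,
CF cases with elevated IRT except a meconium-ileus subgroup with suppressed
values, ancestry-dependent CFTR allele composition with panel-coverage gaps
concentrated in minoritized groups, and diagnosis-delay draws that place some
diagnoses beyond 28 days of age.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .registry import ETHNICITIES, RACES, REGISTRY_COLUMNS

__all__ = [
    "CohortParams",
    "DelayGroup",
    "CohortConfigError",
    "default_params",
    "seasonal_factor",
    "sample_irt",
    "generate_cohort",
]

_PROB_TOL = 1e-9

#: day-of-year of the seasonal peak (mid-January) and the annual period
_PEAK_DOY = 15
_YEAR_DAYS = 365.25


class CohortConfigError(ValueError):
    """Invalid cohort configuration (unknown kit, missing allele table...)."""


class DelayGroup(BaseModel):
    """Lognormal age-at-diagnosis model for one demographic group.

    ``median_days`` is the median age at CF diagnosis in days;
    ``log_sigma`` the lognormal spread on the log scale.
    """

    model_config = ConfigDict(extra="forbid")

    median_days: float = Field(gt=0)
    log_sigma: float = Field(ge=0)


class CohortParams(BaseModel):
    """Parameters of the synthetic screening cohort.

    IRT draws are lognormal: ``log IRT ~ Normal(mu, sigma)`` with ``mu`` the
    sum of ``log_irt_mu`` and the log multiplicative season, kit, CF and
    meconium-ileus effects. Ancestry keys are ``"Race|Ethnicity"`` strings.
    """

    model_config = ConfigDict(extra="forbid")

    n_infants: int = Field(gt=0)
    cf_prevalence: float = Field(ge=0, le=1)
    start_date: dt.date
    end_date: dt.date
    log_irt_mu: float = 3.267
    log_irt_sigma: float = Field(default=0.45, ge=0)
    seasonal_amplitude: float = Field(default=0.06, ge=0, lt=1)
    kit_effects: dict[str, float] = Field(
        default_factory=lambda: {"GSP-A": 1.0, "GSP-B": 1.10, "GSP-C": 0.92}
    )
    cf_irt_shift: float = Field(default=4.0, gt=0)
    mi_fraction: float = Field(default=0.18, ge=0, le=1)
    mi_irt_suppression: float = Field(default=0.35, gt=0)
    ancestry_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MIX))
    allele_tables: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_ALLELES.items()}
    )
    delay_model: dict[str, DelayGroup] = Field(
        default_factory=lambda: {
            "reference": DelayGroup(median_days=20.0, log_sigma=0.45),
            "minoritized": DelayGroup(median_days=28.0, log_sigma=0.55),
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        if self.end_date < self.start_date:
            raise ValueError("end_date must be >= start_date")
        if abs(sum(self.ancestry_mix.values()) - 1.0) > _PROB_TOL:
            raise ValueError("ancestry_mix probabilities must sum to 1")
        for key in self.ancestry_mix:
            race, _, eth = key.partition("|")
            if race not in RACES or eth not in ETHNICITIES:
                raise ValueError(f"ancestry_mix key {key!r} is not 'Race|Ethnicity'")
        for name, table in self.allele_tables.items():
            if abs(sum(table.values()) - 1.0) > _PROB_TOL:
                raise ValueError(f"allele_tables[{name!r}] must sum to 1")
        for kit, eff in self.kit_effects.items():
            if eff <= 0:
                raise ValueError(f"kit_effects[{kit!r}] must be > 0")
        if not {"reference", "minoritized"} <= set(self.delay_model):
            raise ValueError("delay_model needs 'reference' and 'minoritized' groups")
        return self


# Defaults: the background distribution puts its 95th percentile at the fixed
# 55 ng/mL cut-off (exp(3.267 + 1.645*0.45) ~= 55, median ~26 ng/mL), matching
# the convention that fixed cut-offs sit near the 95th-99th percentile.
# The ancestry mix loosely mirrors a southeastern-US birth cohort; allele
# tables concentrate off-panel alleles in minoritized groups. All values are
# synthetic defaults, not estimates from any real registry.
_DEFAULT_MIX = {
    "White|NonHispanic": 0.44,
    "Black|NonHispanic": 0.32,
    "White|Hispanic": 0.12,
    "Multiracial|NonHispanic": 0.04,
    "OtherRace|NonHispanic": 0.04,
    "OtherRace|Hispanic": 0.02,
    "Black|Hispanic": 0.01,
    "Unknown|Unknown": 0.01,
}

_DEFAULT_ALLELES = {
    "White|NonHispanic": {
        "F508del": 0.78, "G542X": 0.05, "G551D": 0.04, "N1303K": 0.03,
        "W1282X": 0.02, "R553X": 0.02, "621+1G->T": 0.02, "1717-1G->A": 0.02,
        "3849+10kbC->T": 0.02,
    },
    "Black|NonHispanic": {
        "F508del": 0.46, "3120G->A": 0.14, "2307insA": 0.08, "G542X": 0.06,
        "A559T": 0.06, "621+1G->T": 0.05, "R553X": 0.05, "405+3A->C": 0.05,
        "444delA": 0.05,
    },
    "White|Hispanic": {
        "F508del": 0.52, "G542X": 0.08, "3876delA": 0.07, "1811+1634A->G": 0.07,
        "3271delGG": 0.06, "W1282X": 0.05, "R1066C": 0.05, "S466X": 0.05,
        "H199Y": 0.05,
    },
    "Multiracial|NonHispanic": {
        "F508del": 0.55, "3120G->A": 0.10, "G542X": 0.08, "2307insA": 0.07,
        "R553X": 0.07, "A559T": 0.07, "621+1G->T": 0.06,
    },
    "OtherRace|NonHispanic": {
        "F508del": 0.50, "W1282X": 0.12, "G542X": 0.10, "N1303K": 0.08,
        "Q1100P": 0.08, "1898+5G->T": 0.07, "2184insA": 0.05,
    },
    "OtherRace|Hispanic": {
        "F508del": 0.45, "3876delA": 0.12, "1811+1634A->G": 0.10, "G542X": 0.08,
        "R1066C": 0.09, "S466X": 0.08, "711+3A->G": 0.08,
    },
    "Black|Hispanic": {
        "F508del": 0.40, "3120G->A": 0.15, "G542X": 0.10, "2307insA": 0.10,
        "3876delA": 0.10, "S466X": 0.08, "A559T": 0.07,
    },
    "Unknown|Unknown": {"F508del": 0.70, "G542X": 0.15, "N1303K": 0.15},
}

MINORITIZED_RACES = frozenset({"Black", "Multiracial", "OtherRace"})


def default_params(**overrides) -> CohortParams:
    """Default cohort parameters, optionally overridden field-by-field."""
    base = dict(
        n_infants=10_000,
        cf_prevalence=0.00025,
        start_date=dt.date(2018, 1, 1),
        end_date=dt.date(2022, 12, 31),
    )
    base.update(overrides)
    return CohortParams(**base)


def seasonal_factor(dates: pd.Series | np.ndarray, amplitude: float) -> np.ndarray:
    """Multiplicative seasonal IRT factor: peak mid-January, trough mid-July.

    ``1 + amplitude * cos(2*pi*(doy - 15)/365.25)`` for day-of-year ``doy``.
    """
    doy = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[ns]")).dayofyear.to_numpy()
    return 1.0 + amplitude * np.cos(2.0 * math.pi * (doy - _PEAK_DOY) / _YEAR_DAYS)


def sample_irt(
    has_cf: np.ndarray,
    meconium_ileus: np.ndarray,
    specimen_date: np.ndarray,
    kit_id: np.ndarray,
    params: CohortParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw IRT concentrations (ng/mL) for a vector of record contexts."""
    has_cf = np.asarray(has_cf, dtype=bool)
    meconium_ileus = np.asarray(meconium_ileus, dtype=bool)
    kit_id = np.asarray(kit_id, dtype=object)

    unknown = set(kit_id) - set(params.kit_effects)
    if unknown:
        raise CohortConfigError(f"unknown kit_id(s) {sorted(unknown)}; not in kit_effects")

    kit_eff = np.array([params.kit_effects[k] for k in kit_id], dtype=float)
    mu = (
        params.log_irt_mu
        + np.log(seasonal_factor(specimen_date, params.seasonal_amplitude))
        + np.log(kit_eff)
        + has_cf * math.log(params.cf_irt_shift)
        + (has_cf & meconium_ileus) * math.log(params.mi_irt_suppression)
    )
    return np.exp(mu + params.log_irt_sigma * rng.standard_normal(len(mu)))


def _draw_categorical(rng: np.random.Generator, table: dict[str, float], n: int) -> np.ndarray:
    keys = sorted(table)
    p = np.array([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=p)


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a synthetic screening registry of ``params.n_infants`` rows.

    Deterministic for a fixed seed: identical parameters yield a byte-identical
    CSV via :func:`cfnbs.registry.write_registry`.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_infants

    span = (params.end_date - params.start_date).days
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    dates = pd.to_datetime(params.start_date) + pd.to_timedelta(offsets, unit="D")

    kits = _draw_categorical(rng, {k: 1.0 for k in params.kit_effects}, n)
    ancestry = _draw_categorical(rng, params.ancestry_mix, n)
    race = np.array([a.partition("|")[0] for a in ancestry], dtype=object)
    ethnicity = np.array([a.partition("|")[2] for a in ancestry], dtype=object)
    sex = rng.choice(np.array(["F", "M"], dtype=object), size=n)

    has_cf = rng.random(n) < params.cf_prevalence
    mi = has_cf & (rng.random(n) < params.mi_fraction)

    missing = {a for a in ancestry[has_cf]} - set(params.allele_tables)
    if missing:
        raise CohortConfigError(f"no allele table for ancestry group(s) {sorted(missing)}")

    variant1 = np.full(n, "", dtype=object)
    variant2 = np.full(n, "", dtype=object)
    for idx in np.flatnonzero(has_cf):
        table = params.allele_tables[ancestry[idx]]
        variant1[idx], variant2[idx] = _draw_categorical(rng, table, 2)

    irt = sample_irt(has_cf, mi, dates.to_numpy(), kits, params, rng)

    # ages at diagnosis: lognormal per demographic group; birth is taken as
    # specimen_date - 2 days downstream, so diagnosis = specimen + (age - 2)
    minoritized = np.isin(race, list(MINORITIZED_RACES)) | (ethnicity == "Hispanic")
    diagnosis = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    sweat_dates = np.full(n, "", dtype=object)
    sweat_results = np.full(n, "", dtype=object)
    for idx in np.flatnonzero(has_cf):
        group = params.delay_model["minoritized" if minoritized[idx] else "reference"]
        age = max(
            3,
            int(round(float(np.exp(math.log(group.median_days) + group.log_sigma * rng.standard_normal())))),
        )
        diag = dates[idx] + pd.Timedelta(days=age - 2)
        diagnosis[idx] = diag.to_datetime64()
        chloride = float(np.round(rng.uniform(65, 110), 1))
        sweat_day = (diag - pd.Timedelta(days=1)).strftime("%Y-%m-%d")
        if rng.random() < 0.05:
            sweat_dates[idx] = ";".join([sweat_day, diag.strftime("%Y-%m-%d")])
            sweat_results[idx] = f"QNS;{chloride:g}"
        else:
            sweat_dates[idx] = sweat_day
            sweat_results[idx] = f"{chloride:g}"

    df = pd.DataFrame(
        {
            "infant_id": [f"SYN{i:07d}" for i in range(n)],
            "specimen_date": dates,
            "kit_id": kits,
            "irt": np.round(irt, 1),
            "race": race,
            "ethnicity": ethnicity,
            "sex": sex,
            "has_cf": has_cf,
            "variant1": variant1,
            "variant2": variant2,
            "meconium_ileus": mi,
            "diagnosis_date": diagnosis,
            "sweat_dates": sweat_dates,
            "sweat_results": sweat_results,
        }
    )
    return df[REGISTRY_COLUMNS]
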