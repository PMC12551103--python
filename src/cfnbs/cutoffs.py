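"""Daily trimmed floating-IRT percentile cut-offs.

Three tier-1 positivity rules are supported:

fixed     a constant IRT threshold (e.g. 55 ng/mL);
floating  the trimmed q-th percentile of each day's specimens;
hybrid    the floating value capped by a back-up fixed threshold, so an
          unusually high daily percentile cannot raise the cut-off above it.

Percentile estimation removes outliers at or above ``trim_threshold``
(default 170 ng/mL) first; trimming affects estimation only, never the
screening comparison itself — an IRT of 400 still screens positive.
Positivity is inclusive (irt >= cutoff) at every rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CutoffModel",
    "EmptyInputError",
    "NoCutoffError",
    "trim_outliers",
    "percentile",
    "daily_cutoff_series",
    "effective_cutoff",
    "second_tier_volume",
    "seasonal_summary",
    "kit_summary",
    "season_of",
]

SEASONS = ("winter", "spring", "summer", "fall")
_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


class EmptyInputError(ValueError):
    """Percentile of an empty sample requested."""


class NoCutoffError(ValueError):
    """A floating cut-off was required for a day with no estimate."""


def trim_outliers(values, threshold: float) -> np.ndarray:
    """Drop values at or above ``threshold`` (order preserved, input untouched)."""
    if threshold <= 0:
        raise ValueError("trim threshold must be > 0")
    arr = np.asarray(values, dtype=float)
    return arr[arr < threshold]


def percentile(values, q: float, estimator: str = "linear") -> float:
    """q-th percentile with linear interpolation (or nearest-rank).

    Linear interpolation: with sorted ``x[1..n]`` and ``h = (n-1)q/100 + 1``,
    the estimate is ``x[floor(h)] + (h - floor(h)) * (x[floor(h)+1] - x[floor(h)])``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("cannot take a percentile of an empty sample")
    if not 0 < q < 100:
        raise ValueError("percentile q must lie in (0, 100)")
    method = {"linear": "linear", "nearest_rank": "inverted_cdf"}[estimator]
    return float(np.percentile(arr, q, method=method))


def _as_observations(observations) -> pd.DataFrame:
    df = pd.DataFrame(observations) if not isinstance(observations, pd.DataFrame) else observations
    if "specimen_date" not in df.columns or "irt" not in df.columns:
        raise ValueError("observations need 'specimen_date' and 'irt' columns")
    out = df.copy()
    out["specimen_date"] = pd.to_datetime(out["specimen_date"]).dt.normalize()
    return out


def daily_cutoff_series(
    observations,
    q: float = 95.0,
    trim_threshold: float = 170.0,
    min_daily_n: int = 50,
    estimator: str = "linear",
) -> pd.DataFrame:
    """Per-day trimmed percentile cut-offs over a (date, irt) stream.

    Days with fewer than ``min_daily_n`` trimmed specimens pool backwards over
    prior days in the series until the count is reached (``pooled_flag`` set);
    if even the full backward window is too small the day's cutoff is NaN.
    Unsorted input is sorted internally; duplicate dates are merged.

    Returns a DataFrame with columns
    ``date, n_specimens, n_trimmed, cutoff, pooled_flag``.
    """
    df = _as_observations(observations)
    if df.empty:
        return pd.DataFrame(
            columns=["date", "n_specimens", "n_trimmed", "cutoff", "pooled_flag"]
        ).astype({"n_specimens": int, "n_trimmed": int, "cutoff": float, "pooled_flag": bool})

    grouped = df.groupby("specimen_date")["irt"]
    days = sorted(grouped.groups)
    trimmed_by_day = {d: trim_outliers(grouped.get_group(d).to_numpy(), trim_threshold) for d in days}

    rows = []
    for i, day in enumerate(days):
        values = trimmed_by_day[day]
        n_specimens = int(grouped.get_group(day).size)
        n_trimmed = int(values.size)
        pooled = False
        pool = [values]
        count = n_trimmed
        j = i
        while count < min_daily_n and j > 0:
            j -= 1
            pool.append(trimmed_by_day[days[j]])
            count += trimmed_by_day[days[j]].size
            pooled = True
        if count >= min_daily_n:
            cutoff = percentile(np.concatenate(pool), q, estimator=estimator)
        else:
            cutoff, pooled = np.nan, False
        rows.append((day, n_specimens, n_trimmed, cutoff, pooled))

    return pd.DataFrame(rows, columns=["date", "n_specimens", "n_trimmed", "cutoff", "pooled_flag"])


def effective_cutoff(mode: str, fixed_value: float, day_value: float | None) -> float:
    """Resolve the cut-off applied on one day under a strategy.

    fixed: the fixed value. floating: the day's floating value (error when
    absent). hybrid: min(floating, fixed back-up), falling back to the fixed
    value when the day has no floating estimate.
    """
    absent = day_value is None or (isinstance(day_value, float) and np.isnan(day_value))
    if mode == "fixed":
        return float(fixed_value)
    if mode == "floating":
        if absent:
            raise NoCutoffError("no floating cut-off available for this day")
        return float(day_value)
    if mode == "hybrid":
        return float(fixed_value) if absent else float(min(day_value, fixed_value))
    raise ValueError(f"unknown cut-off mode {mode!r}")


class CutoffModel(BaseEstimator):
    """Tier-1 IRT positivity rule as a scikit-learn style estimator.

    ``fit`` estimates the daily trimmed percentile series from a specimen
    stream (a DataFrame with ``specimen_date`` and ``irt``); ``predict``
    returns boolean tier-1 flags (``irt >= effective cut-off`` on the row's
    specimen day). For ``mode='fixed'`` fitting is a no-op.

    Parameters
    ----------
    mode : {'fixed', 'floating', 'hybrid'}
    fixed_value : fixed threshold ng/mL (also the hybrid back-up)
    percentile : daily percentile in (0, 100) for floating/hybrid
    trim_threshold : outlier-removal bound for estimation, ng/mL
    min_daily_n : minimum trimmed specimens for a stand-alone daily estimate
    estimator : 'linear' or 'nearest_rank' quantile estimator
    """

    def __init__(
        self,
        mode: str = "fixed",
        fixed_value: float = 55.0,
        percentile: float = 95.0,
        trim_threshold: float = 170.0,
        min_daily_n: int = 50,
        estimator: str = "linear",
    ):
        self.mode = mode
        self.fixed_value = fixed_value
        self.percentile = percentile
        self.trim_threshold = trim_threshold
        self.min_daily_n = min_daily_n
        self.estimator = estimator

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if self.mode not in ("fixed", "floating", "hybrid"):
            raise ValueError(f"unknown cut-off mode {self.mode!r}")
        if self.fixed_value <= 0:
            raise ValueError("fixed_value must be > 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.trim_threshold <= self.fixed_value:
            raise ValueError("trim_threshold must exceed fixed_value")

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y=None) -> "CutoffModel":
        self._validate()
        if self.mode == "fixed":
            self.daily_series_ = None
        else:
            self.daily_series_ = daily_cutoff_series(
                X,
                q=self.percentile,
                trim_threshold=self.trim_threshold,
                min_daily_n=self.min_daily_n,
                estimator=self.estimator,
            )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "daily_series_"):
            raise RuntimeError("CutoffModel is not fitted; call fit() first")

    def effective_cutoffs(self, dates) -> np.ndarray:
        """Effective cut-off (ng/mL) applied on each of the given days."""
        self._check_fitted()
        days = pd.to_datetime(pd.Series(dates)).dt.normalize()
        if self.mode == "fixed":
            return np.full(len(days), float(self.fixed_value))
        lookup = self.daily_series_.set_index("date")["cutoff"]
        day_values = days.map(lookup)
        return np.array(
            [effective_cutoff(self.mode, self.fixed_value, dv) for dv in day_values],
            dtype=float,
        )

    def predict(self, X) -> np.ndarray:
        """Boolean tier-1 positivity flags for each specimen row."""
        df = _as_observations(X)
        cutoffs = self.effective_cutoffs(df["specimen_date"])
        return df["irt"].to_numpy(dtype=float) >= cutoffs

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def second_tier_volume(observations, strategy: CutoffModel) -> int:
    """Number of specimens at or above their day's effective cut-off."""
    df = _as_observations(observations)
    if df.empty:
        raise EmptyInputError("second_tier_volume needs a nonempty stream")
    model = CutoffModel(**strategy.get_params()) if strategy is not None else CutoffModel()
    return int(model.fit(df).predict(df).sum())


def season_of(date) -> str:
    """Meteorological season of a date (winter = Dec-Feb, etc.).

    Labelling convention: December belongs to the winter labelled with the
    following January's year (the Dec 2019 - Feb 2020 winter is "winter 2020").
    """
    return _SEASON_BY_MONTH[pd.Timestamp(date).month]


def season_year_of(date) -> int:
    ts = pd.Timestamp(date)
    return ts.year + 1 if ts.month == 12 else ts.year


def seasonal_summary(series: pd.DataFrame) -> dict[str, float]:
    """Mean daily cut-off per season; seasons with no days are absent."""
    if series.empty:
        raise EmptyInputError("seasonal_summary needs a nonempty series")
    df = series.dropna(subset=["cutoff"]).copy()
    df["season"] = [season_of(d) for d in df["date"]]
    means = df.groupby("season")["cutoff"].mean()
    return {s: float(means[s]) for s in SEASONS if s in means.index}


def kit_summary(
    observations,
    q: float = 95.0,
    trim_threshold: float = 170.0,
    estimator: str = "linear",
) -> pd.DataFrame:
    """Per-reagent-kit trimmed specimen count, mean IRT and percentile.

    Kits whose every value is trimmed away report n=0 and NaN statistics.
    """
    df = _as_observations(observations)
    if "kit_id" not in df.columns:
        raise ValueError("observations need a 'kit_id' column")
    rows = []
    for kit, grp in df.groupby("kit_id"):
        trimmed = trim_outliers(grp["irt"].to_numpy(), trim_threshold)
        if trimmed.size:
            rows.append((kit, trimmed.size, float(trimmed.mean()), percentile(trimmed, q, estimator)))
        else:
            rows.append((kit, 0, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["kit_id", "n", "mean", f"p{q:g}"])
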