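"""Lag-aligned temporal aggregation of environmental observations.

Reproduction in this population happens over winter, so environmental
covariates are aligned with a 6-month lag: the annual window predicting the
number of offspring a female produces in year t runs from July 1 of year
t-1 through June 30 of year t; the window predicting how many of those
offspring survive to year t+1 runs from July 1 of year t through June 30
of year t+1.  Within an annual window, per-scene values are first averaged
within each meteorological season and the season means are then averaged,
so unevenly timed scenes cannot bias the annual covariate.  Two sub-annual
windows target the region's rainy seasons: summer (July-August) and winter
(December 1 - March 31).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .geolink import CellSet
from .spectral_indices import IndexStack

__all__ = [
    "LagWindow",
    "EnvSummary",
    "meteorological_season",
    "season_equalized_mean",
    "rainy_season_mean",
    "summarize_unit",
    "summarize_climate",
    "validate_climate",
]

WINDOW_KINDS = ("annual", "summer_rainy", "winter_rainy")
RESPONSE_KINDS = ("offspring", "survival")

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def meteorological_season(date: Date) -> str:
    """DJF -> winter, MAM -> spring, JJA -> summer, SON -> autumn."""
    return SEASON_OF_MONTH[date.month]


@dataclass(frozen=True)
class LagWindow:
    """One lag-aligned covariate window for a response measured in ``response_year``."""

    response_year: int
    window_kind: str
    response_kind: str = "offspring"

    def __post_init__(self) -> None:
        if self.window_kind not in WINDOW_KINDS:
            raise ValueError(f"window_kind must be one of {WINDOW_KINDS}")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(f"response_kind must be one of {RESPONSE_KINDS}")

    @property
    def _base_year(self) -> int:
        # survival windows for year t equal offspring windows for year t+1
        t = self.response_year
        return t if self.response_kind == "offspring" else t + 1

    @property
    def start_date(self) -> Date:
        t = self._base_year
        if self.window_kind == "annual":
            return Date(t - 1, 7, 1)
        if self.window_kind == "summer_rainy":
            return Date(t - 1, 7, 1)
        return Date(t - 1, 12, 1)  # winter_rainy

    @property
    def end_date(self) -> Date:
        """Inclusive end date."""
        t = self._base_year
        if self.window_kind == "annual":
            return Date(t, 6, 30)
        if self.window_kind == "summer_rainy":
            return Date(t - 1, 8, 31)
        return Date(t, 3, 31)  # winter_rainy

    def contains(self, date: Date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass
class EnvSummary:
    """Lag-aligned covariate means for one female-year or landscape-year.

    Index values are in pooled z-units, surface temperature in °C.  The
    climate fields (daily precipitation mm, air temperatures °C) are only
    populated for landscape units: the gridded climate product has a single
    value for the whole site, so it carries no individual-level signal.
    """

    unit_id: str
    response_year: int
    window_kind: str
    values: dict[str, float]
    n_obs: int = 0
    coverage_flag: bool = False


def season_equalized_mean(dates, values) -> tuple[float, bool]:
    """Mean over meteorological seasons of per-season means.

    Seasons with no observations are omitted from the outer mean; a partial
    season set flips the returned coverage flag (and emits a warning).
    Returns (value, incomplete_coverage).  No observations -> (nan, True).
    """
    dates = list(dates)
    values = np.asarray(values, dtype=float)
    if len(dates) != len(values):
        raise ValueError("dates and values must align")
    ok = ~np.isnan(values)
    if not ok.any():
        return (float("nan"), True)
    buckets: dict[str, list[float]] = {}
    for d, v in zip(dates, values):
        if not np.isnan(v):
            buckets.setdefault(meteorological_season(d), []).append(v)
    season_means = [float(np.mean(v)) for v in buckets.values()]
    incomplete = len(buckets) < 4
    if incomplete:
        warnings.warn(
            f"only {len(buckets)}/4 seasons observed; annual mean is partial",
            stacklevel=2,
        )
    return (float(np.mean(season_means)), incomplete)


def rainy_season_mean(dates, values, window: LagWindow) -> tuple[float, bool]:
    """Plain mean of observations falling inside a rainy-season window."""
    if window.window_kind not in ("summer_rainy", "winter_rainy"):
        raise ValueError("rainy_season_mean requires a rainy-season window")
    values = np.asarray(values, dtype=float)
    inside = [
        v for d, v in zip(dates, values) if window.contains(d) and not np.isnan(v)
    ]
    if not inside:
        warnings.warn(
            f"no observations inside {window.window_kind} window of "
            f"year {window.response_year}",
            stacklevel=2,
        )
        return (float("nan"), True)
    return (float(np.mean(inside)), False)


def summarize_unit(
    stacks: dict[str, IndexStack],
    cell_set: CellSet,
    window: LagWindow,
    unit_id: str = "",
) -> EnvSummary:
    """Lag-aligned covariate summary for one spatial unit (home range or
    landscape): per scene-date, mean over the unit's non-masked cells; then
    season-equalized (annual) or plain (rainy) mean over dates per index.
    """
    cells = sorted(cell_set.cells if isinstance(cell_set, CellSet) else cell_set)
    if not cells:
        raise ValueError("empty cell set")
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    out: dict[str, float] = {}
    n_obs = 0
    flagged = False
    start64 = np.datetime64(window.start_date, "D")
    end64 = np.datetime64(window.end_date, "D")
    for name, stack in stacks.items():
        d64 = stack.dates64
        in_window = np.flatnonzero((d64 >= start64) & (d64 <= end64))
        if in_window.size == 0:
            out[name] = float("nan")
            flagged = True
            continue
        sub = np.ma.getdata(stack.grids)[:, rows, cols][in_window]
        if stack.has_masked_cells:
            m = np.ma.getmaskarray(stack.grids)[:, rows, cols][in_window]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = np.nanmean(np.where(m, np.nan, sub), axis=1)
        else:
            vals = sub.mean(axis=1)  # per-date mean over cells
        dates = [stack.dates[i] for i in in_window]
        if window.window_kind == "annual":
            value, partial = season_equalized_mean(dates, vals)
        else:
            value, partial = rainy_season_mean(dates, vals, window)
        out[name] = value
        flagged = flagged or partial
        n_obs = max(n_obs, int(np.sum(~np.isnan(vals))))
    return EnvSummary(
        unit_id=unit_id,
        response_year=window.response_year,
        window_kind=window.window_kind,
        values=out,
        n_obs=n_obs,
        coverage_flag=flagged,
    )


CLIMATE_VARS = ("precip", "tmin", "tmean", "tmax")


def validate_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Check a daily climate frame (date, precip, tmin, tmean, tmax)."""
    missing = set(("date",) + CLIMATE_VARS) - set(climate.columns)
    if missing:
        raise ValueError(f"climate frame missing columns {sorted(missing)}")
    out = climate.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    bad = (out["tmin"] > out["tmean"]) | (out["tmean"] > out["tmax"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} days violate tmin <= tmean <= tmax")
    return out


def summarize_climate(
    climate: pd.DataFrame,
    window: LagWindow,
    unit_id: str = "landscape",
) -> EnvSummary:
    """Window means of the daily climate series (precip mm/day, temps °C).

    Annual windows use season-equalized means of the daily values so the
    climate covariates are built the same way as the index covariates;
    rainy windows use plain means.  Gaps over 10% of window days raise a
    coverage warning.
    """
    climate = validate_climate(climate)
    inside = climate[[window.contains(d) for d in climate["date"]]]
    n_days = (window.end_date - window.start_date).days + 1
    flagged = False
    if len(inside) < 0.9 * n_days:
        warnings.warn(
            f"climate series covers {len(inside)}/{n_days} days of the "
            f"{window.window_kind} window for year {window.response_year}",
            stacklevel=2,
        )
        flagged = True
    out: dict[str, float] = {}
    for var in CLIMATE_VARS:
        if len(inside) == 0:
            out[var] = float("nan")
            continue
        if window.window_kind == "annual":
            value, partial = season_equalized_mean(
                inside["date"].tolist(), inside[var].to_numpy()
            )
            flagged = flagged or partial
        else:
            value = float(inside[var].mean())
        out[var] = value
    return EnvSummary(
        unit_id=unit_id,
        response_year=window.response_year,
        window_kind=window.window_kind,
        values=out,
        n_obs=len(inside),
        coverage_flag=flagged,
    )
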