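"""Individual- and population-level response variables from captures + pedigree.

Individual fitness is measured directly: the pedigree assigns each offspring
to its dam, so each adult female's annual offspring count (including zeros —
females known alive but producing nothing) and the number of those offspring
surviving to age one (operationalized as recapture in year t+1) are simple
counts.  Population-level metrics aggregate the same tables: adult female
count, total and per-female offspring production, the number of active
mounds (a field-surveyable population-size proxy), census size, and year-
over-year change in population size.

Expected table layouts:

* captures: individual_id, sex ('F'/'M'), age_class ('juvenile'/'adult'),
  year, mound_id, date
* pedigree: offspring_id, dam_id, birth_year
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "primary_mound",
    "offspring_counts",
    "surviving_counts",
    "build_female_years",
    "population_metrics",
]


def _check_captures(captures: pd.DataFrame) -> pd.DataFrame:
    need = {"individual_id", "sex", "age_class", "year", "mound_id", "date"}
    missing = need - set(captures.columns)
    if missing:
        raise ValueError(f"captures missing columns {sorted(missing)}")
    out = captures.copy()
    out["date"] = pd.to_datetime(out["date"])
    bad = out["year"] != out["date"].dt.year
    if bad.any():
        raise ValueError(f"{int(bad.sum())} capture rows where year != date.year")
    return out


def primary_mound(captures_of_female: pd.DataFrame) -> str:
    """Modal capture mound; ties broken by earliest capture date, then
    lexicographic mound_id."""
    if len(captures_of_female) == 0:
        raise ValueError("no captures")
    df = captures_of_female.copy()
    df["date"] = pd.to_datetime(df["date"])
    counts = df.groupby("mound_id").agg(n=("mound_id", "size"), first=("date", "min"))
    counts = counts.sort_values(
        ["n", "first", "mound_id"], ascending=[False, True, True]
    )
    return str(counts.index[0])


def offspring_counts(
    pedigree: pd.DataFrame, captures: pd.DataFrame, year: int
) -> pd.DataFrame:
    """One row per adult female captured in ``year`` with her offspring count.

    Zero-offspring females are included — the pedigree's key property is
    that adults known alive but producing nothing still enter the data.
    Returns (female_id, year, primary_mound, n_offspring).
    """
    captures = _check_captures(captures)
    females = captures[
        (captures["year"] == year)
        & (captures["sex"] == "F")
        & (captures["age_class"] == "adult")
    ]
    born = pedigree[pedigree["birth_year"] == year]
    dams_never_captured = set(pedigree["dam_id"]) - set(captures["individual_id"])
    if dams_never_captured:
        warnings.warn(
            f"{len(dams_never_captured)} pedigree dams never appear in captures",
            stacklevel=2,
        )
    n_off = born.groupby("dam_id").size()
    if len(females) == 0:
        return pd.DataFrame(
            columns=["female_id", "year", "primary_mound", "n_offspring"]
        )
    # modal mound per female, ties -> earliest capture date, then mound_id
    agg = (
        females.groupby(["individual_id", "mound_id"])
        .agg(n=("date", "size"), first=("date", "min"))
        .reset_index()
        .sort_values(
            ["individual_id", "n", "first", "mound_id"],
            ascending=[True, False, True, True],
            kind="stable",
        )
    )
    primary = agg.drop_duplicates("individual_id")
    out = pd.DataFrame(
        {
            "female_id": primary["individual_id"].astype(str),
            "year": year,
            "primary_mound": primary["mound_id"].astype(str),
        }
    )
    out["n_offspring"] = (
        out["female_id"].map(n_off).fillna(0).astype(int)
    )
    return out.sort_values("female_id", ignore_index=True)


def surviving_counts(
    female_years: pd.DataFrame,
    pedigree: pd.DataFrame,
    captures: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Add ``n_surviving`` for year-``year`` females with >= 1 offspring.

    An offspring born in year t survives to age one if it is captured in
    any session of year t+1.  If year t+1 has no capture data at all the
    value is left missing.  Rows with zero offspring get NaN (survival is
    defined only for reproducing females).
    """
    captures = _check_captures(captures)
    out = female_years.copy()
    if "n_surviving" not in out.columns:
        out["n_surviving"] = np.nan
    sel = (out["year"] == year) & (out["n_offspring"] >= 1)
    next_year_ids = set(
        captures.loc[captures["year"] == year + 1, "individual_id"].astype(str)
    )
    if not next_year_ids:
        warnings.warn(
            f"no captures in year {year + 1}; survival for year {year} missing",
            stacklevel=2,
        )
        return out
    born = pedigree[pedigree["birth_year"] == year]
    survived = born[born["offspring_id"].astype(str).isin(next_year_ids)]
    n_surv = survived.groupby("dam_id").size()
    out.loc[sel, "n_surviving"] = (
        out.loc[sel, "female_id"].map(n_surv).fillna(0).astype(float)
    )
    bad = out.loc[sel, "n_surviving"] > out.loc[sel, "n_offspring"]
    if bad.any():
        raise ValueError("n_surviving exceeds n_offspring; pedigree inconsistent")
    return out


def build_female_years(
    pedigree: pd.DataFrame, captures: pd.DataFrame
) -> pd.DataFrame:
    """Offspring and survival counts for every (adult female, year)."""
    captures = _check_captures(captures)
    years = sorted(captures["year"].unique())
    pieces = [offspring_counts(pedigree, captures, y) for y in years]
    fy = pd.concat(pieces, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-year coverage warned above
        for y in years:
            fy = surviving_counts(fy, pedigree, captures, y)
    return fy


def population_metrics(
    captures: pd.DataFrame,
    pedigree: pd.DataFrame,
    female_years: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annual population metrics table.

    Columns: year, n_adult_females, total_offspring,
    mean_offspring_per_female, mean_surviving_per_female, n_active_mounds
    (mounds with any resident capture — the population-size proxy),
    n_active_female_mounds (mounds where a female was captured — the seed
    of the active landscape), census_size, delta_N and prop_delta_N on
    census size ((N_t - N_{t-1}) / N_{t-1}, undefined in the first year).
    """
    captures = _check_captures(captures)
    if female_years is None:
        female_years = build_female_years(pedigree, captures)
    rows = []
    for year, grp in captures.groupby("year"):
        fy = female_years[female_years["year"] == year]
        n_females = len(fy)
        total_off = int(fy["n_offspring"].sum())
        surv = fy.loc[fy["n_offspring"] >= 1, "n_surviving"]
        rows.append(
            {
                "year": int(year),
                "n_adult_females": n_females,
                "total_offspring": total_off,
                "mean_offspring_per_female": (
                    total_off / n_females if n_females else np.nan
                ),
                "mean_surviving_per_female": (
                    float(fy["n_surviving"].sum()) / n_females
                    if n_females and surv.notna().all()
                    else np.nan
                ),
                "n_active_mounds": grp["mound_id"].nunique(),
                "n_active_female_mounds": grp.loc[
                    (grp["sex"] == "F") & (grp["age_class"] == "adult"), "mound_id"
                ].nunique(),
                "census_size": grp["individual_id"].nunique(),
            }
        )
    out = pd.DataFrame(rows).sort_values("year", ignore_index=True)
    n = out["census_size"].astype(float)
    out["delta_N"] = n.diff()
    out["prop_delta_N"] = n.diff() / n.shift(1)
    return out
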