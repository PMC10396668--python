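"""End-to-end analysis assembly.

Ties the stages together the way the study design prescribes: ingest and
physically scale the retained scenes, compute and z-score the Tasseled Cap
stacks, register mounds to grid cells, derive female-year fitness responses
from captures + pedigree, build lag-aligned covariate tables for home
ranges (individual scale) and the active landscape (population scale), and
fit the corresponding models.  Also hosts the simulation-based parameter
recovery study used to validate the whole chain against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import demography
from .geolink import active_landscape, assign_mounds, neighborhood3x3
from .inference import ModelResult, StepwiseTrace, backward_stepwise, fit_count_glm
from .scene_io import GridGeometry, read_catalog, read_scene, scale_scene
from .spectral_indices import build_index_stacks, normalize_stacks
from .synthetic_data import SimConfig, SimulatedStudy, simulate_study
from .temporal_agg import LagWindow, summarize_climate, summarize_unit

__all__ = [
    "ingest_scenes",
    "female_covariate_table",
    "landscape_covariate_table",
    "individual_fitness_models",
    "RecoveryResult",
    "run_recovery_replicate",
    "recovery_study",
]

COVARIATES = ("brightness", "greenness", "wetness", "surface_temperature")


def ingest_scenes(
    scene_dir,
    catalog_path,
    *,
    wrs_path: int = 35,
    date_window=None,
    extent=None,
):
    """Read, filter, crop and scale a directory of scenes.

    Returns (scaled scene list, retained catalog).  ``date_window`` is a
    half-open (start, end) date pair; ``extent`` an (xmin, ymin, xmax,
    ymax) crop applied before scaling.
    """
    from .scene_io import crop_to_extent, filter_scene_set

    catalog = read_catalog(catalog_path)
    if date_window is not None:
        catalog = filter_scene_set(catalog, wrs_path, date_window)
    else:
        catalog = catalog[(~catalog["excluded"]) & (catalog["path"] == wrs_path)]
        catalog = catalog.sort_values("date", kind="stable").reset_index(drop=True)
    scenes = []
    scene_dir = Path(scene_dir)
    for rec in catalog.itertuples(index=False):
        scene = read_scene(
            scene_dir / f"{rec.scene_id}.tif",
            scene_id=rec.scene_id,
            acquisition_date=rec.date,
            wrs_path=int(rec.path),
            wrs_row=int(rec.row),
        )
        if extent is not None:
            scene = crop_to_extent(scene, extent)
        scenes.append(scale_scene(scene))
    return scenes, catalog


def female_covariate_table(
    stacks,
    female_years: pd.DataFrame,
    mound_assignments: pd.DataFrame,
    grid: GridGeometry,
    window_kind: str = "annual",
    response_kind: str = "offspring",
) -> pd.DataFrame:
    """One row per female-year: lag-aligned home-range covariate means
    joined to the fitness response.

    The home range is the 3x3 block around the female's primary mound cell.
    """
    cells = mound_assignments.set_index("mound_id")[["row", "col"]]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-coverage warnings summarized by flag
        for rec in female_years.itertuples(index=False):
            if rec.primary_mound not in cells.index:
                continue
            r, c = cells.loc[rec.primary_mound]
            block = neighborhood3x3((int(r), int(c)), grid)
            window = LagWindow(
                response_year=int(rec.year),
                window_kind=window_kind,
                response_kind=response_kind,
            )
            summary = summarize_unit(stacks, block, window, unit_id=rec.female_id)
            rows.append(
                {
                    "female_id": rec.female_id,
                    "year": int(rec.year),
                    "n_offspring": rec.n_offspring,
                    "n_surviving": getattr(rec, "n_surviving", np.nan),
                    "coverage_flag": summary.coverage_flag,
                    **summary.values,
                }
            )
    return pd.DataFrame(rows)


def landscape_covariate_table(
    stacks,
    captures: pd.DataFrame,
    mound_assignments: pd.DataFrame,
    grid: GridGeometry,
    window_kind: str = "annual",
    response_kind: str = "offspring",
    climate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per year: active-landscape covariate means (+ optional
    climate means), lag-aligned for the given response.

    The active landscape of year t is the union of 3x3 blocks around every
    cell holding a mound where an adult female was captured in year t.
    """
    cells = mound_assignments.set_index("mound_id")[["row", "col"]]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for year, grp in captures.groupby("year"):
            female_mounds = grp.loc[
                (grp["sex"] == "F") & (grp["age_class"] == "adult"), "mound_id"
            ].unique()
            active = [
                (int(cells.loc[m, "row"]), int(cells.loc[m, "col"]))
                for m in female_mounds
                if m in cells.index
            ]
            if not active:
                continue
            landscape = active_landscape(active, grid)
            window = LagWindow(
                response_year=int(year),
                window_kind=window_kind,
                response_kind=response_kind,
            )
            summary = summarize_unit(stacks, landscape, window, unit_id="landscape")
            row = {"year": int(year), "n_active_cells": len(landscape),
                   **summary.values}
            if climate is not None:
                clim = summarize_climate(climate, window)
                row.update(clim.values)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IndividualFitnessModels:
    """Poisson + NB stepwise fits for one response/window combination."""

    full_nb: ModelResult
    stepwise_nb: StepwiseTrace
    stepwise_poisson: StepwiseTrace
    table: pd.DataFrame


def individual_fitness_models(
    table: pd.DataFrame, response: str = "n_offspring", alpha: float = 0.05
) -> IndividualFitnessModels:
    """Fit the individual-fitness count models on a covariate table."""
    data = table.dropna(subset=[response, *COVARIATES])
    y = data[response].astype(int)
    X = data[list(COVARIATES)]
    return IndividualFitnessModels(
        full_nb=fit_count_glm(y, X, family="negbin"),
        stepwise_nb=backward_stepwise(y, X, family="negbin", alpha=alpha),
        stepwise_poisson=backward_stepwise(y, X, family="poisson", alpha=alpha),
        table=data,
    )


# ---------------------------------------------------------------------------
# simulation-based parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    """Per-replicate estimates from the full simulated pipeline."""

    seed: int
    n_female_years: int
    estimates: dict[str, float]
    ses: dict[str, float]
    covered: dict[str, bool]
    retained: list[str]


def run_recovery_replicate(
    config: SimConfig, *, stepwise: bool = True
) -> RecoveryResult:
    """Simulate one study, re-derive everything through the analysis path,
    and fit the offspring-count NB model.

    Every stage is recomputed from the emitted artifacts: scenes are
    rescaled from DN, indices recomputed and re-z-scored, mounds
    re-registered from coordinates, fitness recounted from captures +
    pedigree.  Coverage is judged on the full four-predictor fit (the
    stepwise starting model); stepwise runs alongside to exercise
    selection.
    """
    study = simulate_study(config)
    grid = config.grid

    scaled = [scale_scene(s) for s in study.scenes if s.wrs_path == 35]
    stacks = normalize_stacks(build_index_stacks(scaled))
    assignments = assign_mounds(study.mounds, grid)
    female_years = demography.build_female_years(study.pedigree, study.captures)
    # final catalog year is the settling year of last survivors; not a response year
    female_years = female_years[
        female_years["year"].isin(config.response_years)
    ]
    table = female_covariate_table(stacks, female_years, assignments, grid)
    models = individual_fitness_models(table)

    truth = {"const": config.intercept, **config.true_beta}
    est, se, cover = {}, {}, {}
    for term in models.full_nb.params.index:
        est[term] = models.full_nb.coef(term)
        se[term] = float(models.full_nb.params.loc[term, "se"])
        lo, hi = models.full_nb.wald_ci(term)
        cover[term] = bool(lo <= truth[term] <= hi)
    retained = models.stepwise_nb.final.terms if stepwise else []
    return RecoveryResult(
        seed=config.seed,
        n_female_years=models.full_nb.n,
        estimates=est,
        ses=se,
        covered=cover,
        retained=retained,
    )


def recovery_study(
    n_replicates: int = 100,
    base_seed: int = 0,
    *,
    config_kwargs: dict | None = None,
    stepwise: bool = True,
) -> pd.DataFrame:
    """Run the recovery experiment: one simulated study per replicate with
    seeds base_seed, base_seed+1, ...  Returns a tidy per-replicate frame
    with estimate/se/covered columns per model term.
    """
    rows = []
    kwargs = config_kwargs or {}
    for r in range(n_replicates):
        config = SimConfig(seed=base_seed + r, **kwargs)
        res = run_recovery_replicate(config, stepwise=stepwise)
        row = {"seed": res.seed, "n": res.n_female_years}
        for term, v in res.estimates.items():
            row[f"est_{term}"] = v
            row[f"se_{term}"] = res.ses[term]
            row[f"cover_{term}"] = res.covered[term]
            row[f"retained_{term}"] = term in res.retained or term == "const"
        rows.append(row)
    return pd.DataFrame(rows)
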