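"""Tasseled Cap brightness/greenness/wetness and index-stack normalization.

The Tasseled Cap transformation recombines the six TM reflectance bands into
three interpretable axes: brightness (bare-soil albedo), greenness
(photosynthetic vegetation) and wetness (soil/vegetation moisture).  Index
values pooled over every retained scene are z-transformed per index so that
regression coefficients are in comparable per-SD units; the surface
temperature stack is deliberately left in physical units (°C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .scene_io import SceneRaster
from .tc_coefficients import CRIST_1985_TM_REFLECTANCE, TASSELED_CAP_INDICES, TM_BANDS

__all__ = [
    "IndexStack",
    "DegenerateStackError",
    "UndefinedCorrelationError",
    "tasseled_cap",
    "build_index_stacks",
    "z_transform",
    "pearson_correlation",
    "correlation_matrix",
    "scene_mean_series",
]

INDEX_NAMES = TASSELED_CAP_INDICES + ("surface_temperature",)


class DegenerateStackError(ValueError):
    """Zero pooled variance: the stack cannot be z-transformed."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (too few pairs or zero variance)."""


@dataclass
class IndexStack:
    """Per-cell, per-date values of one index over a scene series.

    ``grids`` is a (n_dates, n_rows, n_cols) masked array aligned with
    ``dates`` (ascending).  ``normalized`` records whether the pooled
    z-transform has been applied; ``norm_mean``/``norm_sd`` make it
    invertible.
    """

    index_name: str
    dates: list[Date]
    grids: np.ma.MaskedArray
    normalized: bool = False
    norm_mean: float = field(default=np.nan)
    norm_sd: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.grids = np.ma.asarray(self.grids)
        if self.grids.ndim != 3 or self.grids.shape[0] != len(self.dates):
            raise ValueError("grids must be (n_dates, n_rows, n_cols) aligned with dates")
        if any(b > a for a, b in zip(self.dates[1:], self.dates)):
            raise ValueError("dates must be ascending")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    @property
    def has_masked_cells(self) -> bool:
        """Whether any cell is masked (cached; used for fast paths)."""
        v = getattr(self, "_has_masked", None)
        if v is None:
            v = bool(np.ma.getmaskarray(self.grids).any())
            self._has_masked = v
        return v

    @property
    def dates64(self) -> np.ndarray:
        """Acquisition dates as a datetime64[D] array (cached)."""
        d = getattr(self, "_dates64", None)
        if d is None or len(d) != len(self.dates):
            d = np.array([np.datetime64(x, "D") for x in self.dates])
            self._dates64 = d
        return d


def tasseled_cap(scene: SceneRaster) -> dict[str, np.ma.MaskedArray]:
    """Compute the three Tasseled Cap index grids for one scaled scene.

    Each index is a fixed linear combination (dot product) of the six
    reflectance bands using the Crist (1985) coefficients; a cell masked in
    any input band is masked in every index.
    """
    if not scene.scaled:
        raise ValueError(
            f"scene {scene.scene_id} is unscaled; apply scale_scene first"
        )
    missing = [b for b in TM_BANDS if b not in scene.bands]
    if missing:
        raise ValueError(f"scene {scene.scene_id} lacks reflectance bands {missing}")
    data = np.stack([np.ma.getdata(scene.bands[b]) for b in TM_BANDS])  # (6, H, W)
    mask = np.any(
        [np.ma.getmaskarray(scene.bands[b]) for b in TM_BANDS], axis=0
    )
    out: dict[str, np.ma.MaskedArray] = {}
    for index in TASSELED_CAP_INDICES:
        coef = np.array(CRIST_1985_TM_REFLECTANCE[index])
        vals = np.einsum("k,khw->hw", coef, data)
        out[index] = np.ma.MaskedArray(vals, mask=mask.copy())
    return out


def build_index_stacks(scenes: list[SceneRaster]) -> dict[str, IndexStack]:
    """Tasseled Cap + surface temperature stacks from a series of scaled scenes."""
    if not scenes:
        raise ValueError("no scenes")
    scenes = sorted(scenes, key=lambda s: s.acquisition_date)
    dates = [s.acquisition_date for s in scenes]
    shape = scenes[0].shape
    for s in scenes:
        if s.shape != shape:
            raise ValueError("scenes do not share grid geometry")
    per_index: dict[str, list[np.ma.MaskedArray]] = {n: [] for n in INDEX_NAMES}
    for s in scenes:
        tc = tasseled_cap(s)
        for n in TASSELED_CAP_INDICES:
            per_index[n].append(tc[n])
        per_index["surface_temperature"].append(s.bands["st"])

    def fast_stack(grids):
        data = np.stack([np.ma.getdata(g) for g in grids])
        mask = np.stack([np.ma.getmaskarray(g) for g in grids])
        return np.ma.MaskedArray(data, mask=mask)

    return {
        n: IndexStack(index_name=n, dates=list(dates), grids=fast_stack(g))
        for n, g in per_index.items()
    }


def z_transform(stack: IndexStack) -> IndexStack:
    """Pooled z-transform: every value becomes (x - mean)/sd, where mean and
    sd (sample, n-1 denominator) pool all non-masked cells of all dates.
    """
    if stack.normalized:
        raise ValueError(f"stack {stack.index_name} is already normalized")
    if stack.index_name == "surface_temperature":
        raise ValueError("surface temperature is kept in physical units, not z-scored")
    values = stack.grids.compressed().astype(np.float64)
    if values.size < 2:
        raise DegenerateStackError("need at least 2 non-masked values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStackError(f"stack {stack.index_name} has zero pooled variance")
    # float64 so the pooled mean/sd of the output are 0/1 to ~1e-12
    data = np.ma.getdata(stack.grids).astype(np.float64, copy=False)
    z = np.ma.MaskedArray(
        (data - mean) / sd,
        mask=np.ma.getmaskarray(stack.grids).copy(),
    )
    return IndexStack(
        index_name=stack.index_name,
        dates=list(stack.dates),
        grids=z,
        normalized=True,
        norm_mean=mean,
        norm_sd=sd,
    )


def normalize_stacks(stacks: dict[str, IndexStack]) -> dict[str, IndexStack]:
    """z-transform every Tasseled Cap stack; pass surface temperature through."""
    out = {}
    for name, stack in stacks.items():
        out[name] = stack if name == "surface_temperature" else z_transform(stack)
    return out


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation with pairwise-complete masking."""
    x = np.ma.masked_invalid(np.ma.asarray(x, dtype=float)).ravel()
    y = np.ma.masked_invalid(np.ma.asarray(y, dtype=float)).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = ~(np.ma.getmaskarray(x) | np.ma.getmaskarray(y))
    xv = np.asarray(x[ok], dtype=float)
    yv = np.asarray(y[ok], dtype=float)
    if xv.size < 3:
        raise UndefinedCorrelationError("need at least 3 complete pairs")
    if xv.std() == 0 or yv.std() == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(np.corrcoef(xv, yv)[0, 1])


def correlation_matrix(stacks: dict[str, IndexStack]) -> pd.DataFrame:
    """Pairwise Pearson correlations between index stacks, pooled over all
    dates and cells (pairwise-complete)."""
    names = list(stacks)
    r = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r[i, j] = r[j, i] = pearson_correlation(
                stacks[a].grids, stacks[names[j]].grids
            )
    return pd.DataFrame(r, index=names, columns=names)


def scene_mean_series(
    stacks: dict[str, IndexStack],
    cell_set,
) -> pd.DataFrame:
    """Per-scene (date) mean and SD of each index over a set of cells.

    This is the per-timepoint landscape summary used both to eyeball
    seasonal patterns and as the per-path bias diagnostic (compute it
    separately per WRS path and compare temporally adjacent values).
    Returns a tidy frame (date, index, mean, sd, n_cells).
    """
    cells = sorted(set(getattr(cell_set, "cells", cell_set)))
    if not cells:
        raise ValueError("empty cell set")
    rows_idx = np.array([c[0] for c in cells])
    cols_idx = np.array([c[1] for c in cells])
    records = []
    for name, stack in stacks.items():
        sub = stack.grids[:, rows_idx, cols_idx]  # (n_dates, n_cells)
        counts = sub.count(axis=1)
        means = np.ma.mean(sub, axis=1)
        sds = np.ma.std(sub, axis=1, ddof=1) if sub.shape[1] > 1 else np.ma.zeros(sub.shape[0])
        for k, date in enumerate(stack.dates):
            if counts[k] == 0:
                warnings.warn(
                    f"{name} on {date}: all cells masked; mean missing", stacklevel=2
                )
                records.append((date, name, np.nan, np.nan, 0))
            else:
                sd = float(sds[k]) if counts[k] > 1 else 0.0
                records.append((date, name, float(means[k]), sd, int(counts[k])))
    return pd.DataFrame(records, columns=["date", "index", "mean", "sd", "n_cells"])
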