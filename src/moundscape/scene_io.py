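"""Reading, cropping, quality-filtering and physical scaling of satellite scenes.

Scenes are Landsat-5-TM-like Collection 2 Level 2 products: six surface
reflectance bands (b1-b5, b7) plus one surface temperature band (st), stored
as digital numbers (DN) on a 30 m grid.  DNs are converted to physical units
with the published affine scale factors:

* reflectance = DN * 0.0000275 - 0.2
* temperature (K) = DN * 0.00341802 + 149

Files are plain multiband TIFFs (or per-band TIFFs named
``<scene_id>_<band>.tif``) with an ESRI world-file (``.tfw``) sidecar
carrying the georeferencing; no reprojection or resampling is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "REFLECTANCE_BANDS",
    "DEFAULT_BAND_LAYOUT",
    "REFLECTANCE_SCALE",
    "REFLECTANCE_OFFSET",
    "TEMPERATURE_SCALE",
    "TEMPERATURE_OFFSET",
    "GridGeometry",
    "SceneRaster",
    "BandLayoutError",
    "GeoreferencingError",
    "EmptyCropError",
    "read_scene",
    "write_scene",
    "crop_to_extent",
    "scale_reflectance",
    "scale_temperature",
    "scale_scene",
    "read_catalog",
    "filter_scene_set",
]

REFLECTANCE_BANDS = ("b1", "b2", "b3", "b4", "b5", "b7")
DEFAULT_BAND_LAYOUT = REFLECTANCE_BANDS + ("st",)

REFLECTANCE_SCALE = 0.0000275
REFLECTANCE_OFFSET = -0.2
TEMPERATURE_SCALE = 0.00341802
TEMPERATURE_OFFSET = 149.0
KELVIN_ZERO_C = 273.15

#: plausibility interval for scaled surface reflectance
REFLECTANCE_RANGE = (-0.2, 1.6)

#: Collection 2 fill DN, masked before any scaling
DEFAULT_FILL_DN = 0


class BandLayoutError(ValueError):
    """A scene file does not provide the bands the layout requires."""


class GeoreferencingError(ValueError):
    """Band grids disagree in shape or georeferencing."""


class EmptyCropError(ValueError):
    """Requested crop extent does not intersect the scene."""


@dataclass(frozen=True)
class GridGeometry:
    """North-up 30 m grid: row 0 is the northernmost row, col 0 the westernmost.

    ``x_west``/``y_north`` are the projected coordinates of the grid's
    north-west corner (cell edges, not centers).  A point belongs to cell
    (r, c) via half-open intervals measured from that corner: eastward
    offset in ``[c*s, (c+1)*s)`` and southward offset in ``[r*s, (r+1)*s)``.
    """

    x_west: float
    y_north: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_east(self) -> float:
        return self.x_west + self.n_cols * self.cell_size

    @property
    def y_south(self) -> float:
        return self.y_north - self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return (self.x_west + (col + 0.5) * s, self.y_north - (row + 0.5) * s)

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass
class SceneRaster:
    """One dated multiband grid (reflectance + thermal) with georeferencing."""

    scene_id: str
    acquisition_date: Date
    wrs_path: int
    wrs_row: int
    grid: GridGeometry
    bands: dict[str, np.ma.MaskedArray] = field(default_factory=dict)
    scaled: bool = False

    def __post_init__(self) -> None:
        shapes = {b: g.shape for b, g in self.bands.items()}
        expected = (self.grid.n_rows, self.grid.n_cols)
        for band, shape in shapes.items():
            if shape != expected:
                raise GeoreferencingError(
                    f"band {band!r} has shape {shape}, grid says {expected}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid.n_rows, self.grid.n_cols)


def scale_reflectance(dn):
    """DN -> surface reflectance via the Collection 2 Level 2 affine scaling."""
    return np.multiply(dn, REFLECTANCE_SCALE) + REFLECTANCE_OFFSET


def scale_temperature(dn, unit: str = "celsius"):
    """DN -> surface temperature in Kelvin or Celsius."""
    if unit not in ("kelvin", "celsius"):
        raise ValueError(f"unknown temperature unit {unit!r}")
    kelvin = np.multiply(dn, TEMPERATURE_SCALE) + TEMPERATURE_OFFSET
    if unit == "kelvin":
        return kelvin
    return kelvin - KELVIN_ZERO_C


def scale_scene(
    scene: SceneRaster,
    *,
    fill_dn: float | None = DEFAULT_FILL_DN,
    temperature_unit: str = "celsius",
    reflectance_range: tuple[float, float] = REFLECTANCE_RANGE,
) -> SceneRaster:
    """Mask the fill sentinel, then scale every band to physical units.

    Reflectance values outside ``reflectance_range`` after scaling raise a
    warning and are masked (they indicate saturated or corrupt cells).
    """
    if scene.scaled:
        raise ValueError(f"scene {scene.scene_id} is already scaled")
    out: dict[str, np.ma.MaskedArray] = {}
    for band, grid in scene.bands.items():
        arr = np.ma.asarray(grid)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float32)
        arr = np.ma.masked_invalid(arr)
        if fill_dn is not None:
            arr = np.ma.masked_values(arr, fill_dn)
        if band == "st":
            out[band] = scale_temperature(arr, unit=temperature_unit)
        else:
            refl = scale_reflectance(arr)
            lo, hi = reflectance_range
            bad = ((refl < lo) | (refl > hi)).filled(False)
            if bad.any():
                warnings.warn(
                    f"scene {scene.scene_id} band {band}: "
                    f"{int(bad.sum())} cells outside plausible reflectance "
                    f"range {reflectance_range}; masked",
                    stacklevel=2,
                )
                refl = np.ma.masked_where(bad, refl)
            out[band] = refl
    return replace(scene, bands=out, scaled=True)


# ---------------------------------------------------------------------------
# file I/O: multiband TIFF + world file
# ---------------------------------------------------------------------------


def _world_file_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".tfw")


def _read_world_file(tif_path: Path, shape: tuple[int, int]) -> GridGeometry:
    tfw = _world_file_path(tif_path)
    if not tfw.exists():
        raise GeoreferencingError(f"no world file next to {tif_path}")
    vals = [float(v) for v in tfw.read_text().split()]
    if len(vals) != 6:
        raise GeoreferencingError(f"malformed world file {tfw}")
    dx, rot1, rot2, dy, xc, yc = vals
    if rot1 != 0 or rot2 != 0:
        raise GeoreferencingError("rotated grids are not supported")
    if dy >= 0 or dx <= 0:
        raise GeoreferencingError("grid must be north-up, west-to-east")
    # world file stores the CENTER of the top-left cell
    return GridGeometry(
        x_west=xc - dx / 2.0,
        y_north=yc - dy / 2.0,
        cell_size=dx,
        n_rows=shape[0],
        n_cols=shape[1],
    )


def _write_world_file(tif_path: Path, grid: GridGeometry) -> None:
    s = grid.cell_size
    xc, yc = grid.cell_center(0, 0)
    _world_file_path(tif_path).write_text(
        f"{s:.6f}\n0.0\n0.0\n{-s:.6f}\n{xc:.6f}\n{yc:.6f}\n"
    )


def read_scene(
    path,
    band_layout: tuple[str, ...] = DEFAULT_BAND_LAYOUT,
    *,
    scene_id: str | None = None,
    acquisition_date: Date | None = None,
    wrs_path: int = 0,
    wrs_row: int = 0,
) -> SceneRaster:
    """Read one scene from a multiband TIFF or a set of per-band TIFFs.

    ``path`` is either a single multiband TIFF whose planes follow
    ``band_layout``, or a directory containing ``<scene_id>_<band>.tif``
    files (then ``scene_id`` is required).  Returns an unscaled scene
    (``scaled=False``) with DN values; georeferencing comes from the
    ``.tfw`` sidecar(s).
    """
    path = Path(path)
    if path.is_dir():
        if scene_id is None:
            raise ValueError("scene_id is required when reading per-band files")
        bands: dict[str, np.ndarray] = {}
        grid: GridGeometry | None = None
        for band in band_layout:
            bpath = path / f"{scene_id}_{band}.tif"
            if not bpath.exists():
                raise BandLayoutError(f"missing band {band!r}: {bpath} not found")
            arr = tifffile.imread(bpath)
            g = _read_world_file(bpath, arr.shape)
            if grid is None:
                grid = g
            elif g != grid:
                raise GeoreferencingError(
                    f"band {band!r} georeferencing disagrees with previous bands"
                )
            bands[band] = arr
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] < len(band_layout):
            missing = band_layout[stack.shape[0] :]
            raise BandLayoutError(
                f"{path.name}: file has {stack.shape[0]} planes, layout "
                f"needs {len(band_layout)} (missing {list(missing)})"
            )
        grid = _read_world_file(path, stack.shape[1:])
        bands = {band: stack[i] for i, band in enumerate(band_layout)}
        if scene_id is None:
            scene_id = path.stem
    assert grid is not None
    masked = {b: np.ma.asarray(np.asarray(a, dtype=float)) for b, a in bands.items()}
    return SceneRaster(
        scene_id=scene_id,
        acquisition_date=acquisition_date,
        wrs_path=wrs_path,
        wrs_row=wrs_row,
        grid=grid,
        bands=masked,
        scaled=False,
    )


def write_scene(
    scene: SceneRaster,
    out_dir,
    band_layout: tuple[str, ...] = DEFAULT_BAND_LAYOUT,
    dtype=np.uint16,
) -> Path:
    """Write a DN scene as ``<scene_id>.tif`` (+ ``.tfw``) under ``out_dir``."""
    if scene.scaled:
        raise ValueError("write_scene expects DN (unscaled) scenes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [b for b in band_layout if b not in scene.bands]
    if missing:
        raise BandLayoutError(f"scene {scene.scene_id} lacks bands {missing}")
    stack = np.stack(
        [np.ma.filled(scene.bands[b], DEFAULT_FILL_DN) for b in band_layout]
    ).astype(dtype)
    tif_path = out_dir / f"{scene.scene_id}.tif"
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    _write_world_file(tif_path, scene.grid)
    return tif_path


def crop_to_extent(scene: SceneRaster, extent_xy: tuple[float, float, float, float]) -> SceneRaster:
    """Crop to (xmin, ymin, xmax, ymax), snapping edges OUTWARD to cell
    boundaries so every cell intersecting the requested extent is kept.
    """
    xmin, ymin, xmax, ymax = extent_xy
    if xmin >= xmax or ymin >= ymax:
        raise ValueError("degenerate extent")
    g = scene.grid
    s = g.cell_size
    if xmax <= g.x_west or xmin >= g.x_east or ymax <= g.y_south or ymin >= g.y_north:
        raise EmptyCropError("extent does not intersect scene")
    c0 = max(0, math.floor((xmin - g.x_west) / s))
    c1 = min(g.n_cols, math.ceil((xmax - g.x_west) / s))
    r0 = max(0, math.floor((g.y_north - ymax) / s))
    r1 = min(g.n_rows, math.ceil((g.y_north - ymin) / s))
    if c1 <= c0 or r1 <= r0:
        raise EmptyCropError("extent does not intersect scene")
    new_grid = GridGeometry(
        x_west=g.x_west + c0 * s,
        y_north=g.y_north - r0 * s,
        cell_size=s,
        n_rows=r1 - r0,
        n_cols=c1 - c0,
    )
    new_bands = {b: arr[r0:r1, c0:c1] for b, arr in scene.bands.items()}
    return replace(scene, grid=new_grid, bands=new_bands)


# ---------------------------------------------------------------------------
# scene catalog
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["scene_id", "date", "path", "row", "excluded", "reason"]


def read_catalog(path) -> pd.DataFrame:
    """Read a scene catalog CSV (scene_id,date,path,row,excluded,reason).

    The ``excluded`` flag replaces manual cloud screening: a scene is kept
    only if its flag is false; an excluded scene must carry a reason.
    """
    cat = pd.read_csv(path, dtype={"scene_id": str, "reason": str})
    missing = set(CATALOG_COLUMNS[:5]) - set(cat.columns)
    if missing:
        raise ValueError(f"catalog missing columns {sorted(missing)}")
    if "reason" not in cat.columns:
        cat["reason"] = ""
    cat["date"] = pd.to_datetime(cat["date"]).dt.date
    cat["excluded"] = cat["excluded"].astype(bool)
    _validate_catalog(cat)
    return cat


def _validate_catalog(cat: pd.DataFrame) -> None:
    if cat["scene_id"].duplicated().any():
        dups = cat.loc[cat["scene_id"].duplicated(), "scene_id"].tolist()
        raise ValueError(f"duplicate scene_ids in catalog: {dups}")
    bad = cat["excluded"] & (cat["reason"].isna() | (cat["reason"].astype(str) == ""))
    if bad.any():
        raise ValueError(
            "excluded scenes must carry a reason: "
            f"{cat.loc[bad, 'scene_id'].tolist()}"
        )


def filter_scene_set(
    catalog: pd.DataFrame,
    wrs_path: int,
    date_window: tuple[Date, Date],
) -> pd.DataFrame:
    """Retain non-excluded scenes on one WRS path inside a half-open date
    window ``[start, end)``, in stable acquisition-date order.
    """
    if len(catalog) == 0:
        raise ValueError("empty scene catalog")
    _validate_catalog(catalog)
    start, end = date_window
    keep = (
        (~catalog["excluded"])
        & (catalog["path"] == wrs_path)
        & (catalog["date"] >= start)
        & (catalog["date"] < end)
    )
    out = catalog.loc[keep].sort_values("date", kind="stable").reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("scene filter retained no scenes", stacklevel=2)
    return out
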