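"""Register mound coordinates to the raster grid; home ranges and landscape.

Mounds surveyed with GPS carry projected coordinates and drop straight into
grid cells.  Mounds mapped only in the site's historical meter-based survey
frame are registered with a least-squares similarity transform (translation,
rotation, optional uniform scale) estimated from the mounds that carry both
coordinate systems, then assigned to the nearest containing cell; a manual
override table can correct individual assignments.

A female's raster home range is the 3x3 block of 30 m cells centered on her
mound cell; the active landscape for a year is the union of such blocks over
all active mounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene_io import GridGeometry

__all__ = [
    "MoundRecord",
    "CellSet",
    "SimilarityTransform",
    "RegistrationError",
    "OutOfBoundsError",
    "fit_local_to_map_transform",
    "assign_cell",
    "neighborhood3x3",
    "active_landscape",
    "assign_mounds",
]

#: warn when registration RMS exceeds half a cell
RMS_WARN_METERS = 15.0


class RegistrationError(ValueError):
    """Too few or degenerate anchors for coordinate registration."""


class OutOfBoundsError(ValueError):
    """Point or cell falls outside the grid extent."""


@dataclass
class MoundRecord:
    mound_id: str
    gps_xy: tuple[float, float] | None = None
    local_xy: tuple[float, float] | None = None
    cell: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.gps_xy is None and self.local_xy is None:
            raise ValueError(f"mound {self.mound_id}: need gps_xy or local_xy")


@dataclass(frozen=True)
class CellSet:
    cells: frozenset
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", frozenset(self.cells))

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(sorted(self.cells))

    def union(self, other: "CellSet", label: str = "") -> "CellSet":
        return CellSet(self.cells | other.cells, label or self.label)


@dataclass(frozen=True)
class SimilarityTransform:
    """Map local (site-frame) meters to projected map meters:
    ``map = scale * R(theta) @ local + t``."""

    scale: float
    rotation_rad: float
    translation: tuple[float, float]

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)


def fit_local_to_map_transform(
    local_xy,
    map_xy,
    *,
    allow_scale: bool = True,
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity transform from anchor pairs (Umeyama/Procrustes).

    Returns the transform and the RMS residual in map meters.  Requires at
    least 3 non-collinear anchors; warns if RMS exceeds half a cell (15 m),
    which usually means a mis-recorded anchor.
    """
    A = np.atleast_2d(np.asarray(local_xy, dtype=float))
    B = np.atleast_2d(np.asarray(map_xy, dtype=float))
    if A.shape != B.shape or A.shape[1] != 2:
        raise ValueError("anchor arrays must both be (n, 2)")
    n = A.shape[0]
    if n < 3:
        raise RegistrationError(f"need >= 3 anchors, got {n}")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    if np.linalg.matrix_rank(Ac, tol=1e-9) < 2:
        raise RegistrationError("anchors are collinear")
    # Umeyama: rotation from SVD of the cross-covariance
    H = Ac.T @ Bc / n
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    var_a = (Ac**2).sum() / n
    scale = float(np.trace(np.diag(S) @ D) / var_a) if allow_scale else 1.0
    t = B.mean(axis=0) - scale * R @ A.mean(axis=0)
    tf = SimilarityTransform(
        scale=scale,
        rotation_rad=float(np.arctan2(R[1, 0], R[0, 0])),
        translation=(float(t[0]), float(t[1])),
    )
    resid = tf.apply(A) - B
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    if rms > RMS_WARN_METERS:
        warnings.warn(
            f"registration RMS {rms:.1f} m exceeds {RMS_WARN_METERS} m; "
            "check anchor coordinates",
            stacklevel=2,
        )
    return tf, rms


def assign_cell(point_xy, grid: GridGeometry) -> tuple[int, int]:
    """Cell (row, col) containing a projected point, half-open convention.

    A point on a shared edge belongs to the cell for which it is the
    north-west corner (offsets measured eastward/southward are in
    ``[edge, edge + cell_size)``).
    """
    x, y = float(point_xy[0]), float(point_xy[1])
    s = grid.cell_size
    col = int(np.floor((x - grid.x_west) / s))
    row = int(np.floor((grid.y_north - y) / s))
    if not grid.contains_cell(row, col):
        raise OutOfBoundsError(f"point ({x}, {y}) outside grid extent")
    return (row, col)


def neighborhood3x3(cell: tuple[int, int], grid: GridGeometry, label: str = "home_range") -> CellSet:
    """The <=9 in-bounds cells of the 3x3 block centered on ``cell``.

    Blocks truncated at the grid edge keep whatever cells exist.
    """
    r, c = cell
    if not grid.contains_cell(r, c):
        raise OutOfBoundsError(f"cell {cell} outside grid")
    cells = {
        (rr, cc)
        for rr in range(r - 1, r + 2)
        for cc in range(c - 1, c + 2)
        if grid.contains_cell(rr, cc)
    }
    return CellSet(cells, label)


def active_landscape(active_cells, grid: GridGeometry) -> CellSet:
    """Union of 3x3 neighborhoods over all active-mound cells, deduplicated."""
    cells = set()
    active = list(active_cells)
    if not active:
        warnings.warn("no active cells; landscape is empty", stacklevel=2)
        return CellSet(frozenset(), "active_landscape")
    for cell in active:
        cells |= neighborhood3x3(tuple(cell), grid).cells
    return CellSet(cells, "active_landscape")


def assign_mounds(
    mounds: pd.DataFrame,
    grid: GridGeometry,
    *,
    overrides: pd.DataFrame | None = None,
    allow_scale: bool = True,
) -> pd.DataFrame:
    """Assign every mound to a raster cell.

    ``mounds`` columns: mound_id, gps_x, gps_y, local_x, local_y (gps or
    local may be missing per row).  Mounds with GPS are assigned directly;
    the GPS-less remainder go through the local->map similarity transform
    fitted on mounds carrying both systems.  ``overrides`` (mound_id, row,
    col) wins over everything and is recorded as source='manual'.

    Returns a frame (mound_id, row, col, source) with source in
    {gps, registered, manual}.
    """
    df = mounds.copy()
    has_gps = df["gps_x"].notna() & df["gps_y"].notna()
    has_local = df["local_x"].notna() & df["local_y"].notna()
    if not (has_gps | has_local).all():
        bad = df.loc[~(has_gps | has_local), "mound_id"].tolist()
        raise ValueError(f"mounds with no coordinates at all: {bad}")

    out_rows = []
    anchors = df[has_gps & has_local]
    transform = None
    if (~has_gps).any():
        if len(anchors) < 3:
            raise RegistrationError(
                "mounds lack GPS but fewer than 3 anchors carry both systems"
            )
        transform, _ = fit_local_to_map_transform(
            anchors[["local_x", "local_y"]].to_numpy(),
            anchors[["gps_x", "gps_y"]].to_numpy(),
            allow_scale=allow_scale,
        )
    for rec in df.itertuples(index=False):
        if pd.notna(rec.gps_x) and pd.notna(rec.gps_y):
            xy, source = (rec.gps_x, rec.gps_y), "gps"
        else:
            xy = transform.apply([(rec.local_x, rec.local_y)])[0]
            source = "registered"
        row, col = assign_cell(xy, grid)
        out_rows.append((rec.mound_id, row, col, source))
    out = pd.DataFrame(out_rows, columns=["mound_id", "row", "col", "source"])
    if overrides is not None and len(overrides):
        ov = overrides.set_index("mound_id")
        hit = out["mound_id"].isin(ov.index)
        out.loc[hit, "row"] = out.loc[hit, "mound_id"].map(ov["row"]).astype(int)
        out.loc[hit, "col"] = out.loc[hit, "mound_id"].map(ov["col"]).astype(int)
        out.loc[hit, "source"] = "manual"
    return out
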