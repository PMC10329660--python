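"""Raster, admin-boundary, tabular and configuration I/O.

All downstream modules consume only the domain types defined here:
:class:`PixelGrid`, :class:`CovariateStack`, :class:`AdminFrame`,
:class:`NationalSeries` and :class:`RunConfig`.

Conventions (stated once, used everywhere):

* planar km coordinate system; distances are Euclidean in km,
* pixel indices are 0-based and row-major (``pixel = row * n_cols + col``),
* coordinates refer to cell centers,
* intervals are half-open.

Rasters are stored as plain (multi-page) TIFF files with a JSON sidecar
(``<name>.tif`` + ``<name>.tif.json``) carrying the grid geometry; admin
boundaries are GeoJSON polygons or a CSV pixel-membership table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("geovax")

__all__ = [
    "PixelGrid",
    "CovariateStack",
    "AdminFrame",
    "NationalSeries",
    "RunConfig",
    "GeometryError",
    "DataError",
    "ConfigError",
    "read_raster_stack",
    "write_raster",
    "read_admin",
    "load_config",
]


class GeometryError(ValueError):
    """Raster/vector geometry inconsistent with the requested grid."""


class DataError(ValueError):
    """Input data violates a content precondition (all-missing layer, ...)."""


class ConfigError(ValueError):
    """Run configuration fails validation."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PixelGrid:
    """Planar raster geometry.

    ``origin`` is the (x, y) km coordinate of the grid's lower-left corner;
    the center of pixel (row, col) is ``origin + (col + .5, row + .5) * cell_size``.
    """

    n_rows: int
    n_cols: int
    cell_size: float  # km
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise GeometryError("cell_size must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area(self) -> float:
        """Pixel area in km^2."""
        return self.cell_size**2

    def cell_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) cell-center coordinates, row-major."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = x0 + (cols + 0.5) * self.cell_size
        ys = y0 + (rows + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)  # yy varies with row
        return np.column_stack([xx.ravel(), yy.ravel()])

    def pixel_of_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major pixel index containing each (x, y); -1 when out of bounds."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "cell_size": self.cell_size,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PixelGrid":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            cell_size=float(d["cell_size"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
        )


@dataclass
class CovariateStack:
    """Per-covariate, per-year, per-pixel values with no missing cells.

    ``values`` has shape (n_covariates, n_years, n_pixels); time-invariant
    covariates are replicated along the year axis so every covariate has a
    value for every (pixel, year).
    """

    grid: PixelGrid
    years: list[int]
    names: list[str]
    values: np.ndarray
    is_time_varying: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.names), len(self.years), self.grid.n_pixels)
        if self.values.shape != expected:
            raise GeometryError(
                f"covariate values shape {self.values.shape} != {expected}"
            )
        if np.isnan(self.values).any():
            raise DataError("covariate stack contains missing values after load")
        if not self.is_time_varying:
            self.is_time_varying = [
                not all(
                    np.array_equal(self.values[j, 0], self.values[j, t])
                    for t in range(len(self.years))
                )
                for j in range(len(self.names))
            ]

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def at(self, pixel: np.ndarray, year: np.ndarray) -> np.ndarray:
        """Extract covariate vectors at (pixel, year) sites -> (n_sites, n_cov)."""
        year_index = {y: t for t, y in enumerate(self.years)}
        t = np.array([year_index[int(y)] for y in np.atleast_1d(year)])
        p = np.atleast_1d(pixel).astype(int)
        return self.values[:, t, p].T

    def design_matrix(self) -> np.ndarray:
        """All (year, pixel) sites stacked time-major -> (n_years*n_pixels, n_cov)."""
        n_cov, n_years, n_pix = self.values.shape
        return self.values.reshape(n_cov, n_years * n_pix).T


@dataclass
class AdminFrame:
    """Two-level admin partition of a grid with pixel membership.

    ``units`` is a DataFrame with columns (unit_id, level, parent_id) where
    level 1 = state, level 2 = LGA.  ``pixel_owner`` maps each pixel to its
    level-2 unit.  Optional shapely polygons are kept for plotting only.
    """

    grid: PixelGrid
    units: pd.DataFrame
    pixel_owner: np.ndarray  # level-2 unit id per pixel
    polygons: dict | None = None

    def __post_init__(self) -> None:
        self.pixel_owner = np.asarray(self.pixel_owner)
        if self.pixel_owner.shape != (self.grid.n_pixels,):
            raise GeometryError("pixel_owner must have one entry per pixel")
        lga_ids = set(self.lga_ids)
        owners = set(np.unique(self.pixel_owner).tolist())
        if not owners <= lga_ids:
            raise GeometryError(f"pixel owners {owners - lga_ids} not level-2 units")
        parents = self.units.set_index("unit_id")["parent_id"]
        state_ids = set(self.state_ids)
        for u in self.lga_ids:
            if parents[u] not in state_ids:
                raise GeometryError(f"LGA {u} has no level-1 parent")

    @property
    def lga_ids(self) -> list:
        return self.units.loc[self.units["level"] == 2, "unit_id"].tolist()

    @property
    def state_ids(self) -> list:
        return self.units.loc[self.units["level"] == 1, "unit_id"].tolist()

    def parent_of(self, lga_id) -> object:
        return self.units.set_index("unit_id").loc[lga_id, "parent_id"]

    def pixels_of(self, unit_id) -> np.ndarray:
        """Pixel indices of a unit at either level."""
        level = self.units.set_index("unit_id").loc[unit_id, "level"]
        if level == 2:
            return np.flatnonzero(self.pixel_owner == unit_id)
        children = self.units.loc[
            (self.units["level"] == 2) & (self.units["parent_id"] == unit_id),
            "unit_id",
        ]
        return np.flatnonzero(np.isin(self.pixel_owner, children))

    def state_of_pixel(self) -> np.ndarray:
        """Level-1 unit id per pixel."""
        parents = self.units.set_index("unit_id")["parent_id"]
        mapping = {u: parents[u] for u in self.lga_ids}
        return np.array([mapping[u] for u in self.pixel_owner])

    def unit_population(self, population: np.ndarray) -> pd.Series:
        """Sum a per-pixel population raster to units at both levels."""
        population = np.asarray(population, dtype=float)
        out = {}
        for u in self.lga_ids:
            out[u] = float(population[self.pixels_of(u)].sum())
        for s in self.state_ids:
            out[s] = float(population[self.pixels_of(s)].sum())
        return pd.Series(out, name="population")


@dataclass
class NationalSeries:
    """National coverage per dose per year; proportions in [0, 1]."""

    values: pd.DataFrame  # columns: year, dose, coverage

    def __post_init__(self) -> None:
        v = self.values
        if not {"year", "dose", "coverage"} <= set(v.columns):
            raise DataError("national series needs columns year, dose, coverage")
        if ((v["coverage"] < 0) | (v["coverage"] > 1)).any():
            raise DataError("national coverage must lie in [0, 1]")
        wide = v.pivot_table(index="year", columns="dose", values="coverage")
        if {"dtp1", "dtp3"} <= set(wide.columns):
            bad = wide["dtp3"] > wide["dtp1"] + 1e-12
            if bad.any():
                raise DataError(
                    f"dtp3 exceeds dtp1 in years {wide.index[bad].tolist()}"
                )

    def target(self, dose: str, year: int) -> float:
        sel = self.values[
            (self.values["dose"] == dose) & (self.values["year"] == int(year))
        ]
        if sel.empty:
            raise ConfigError(f"national series has no entry for {dose} in {year}")
        return float(sel["coverage"].iloc[0])

    @classmethod
    def from_csv(cls, path: str | Path) -> "NationalSeries":
        return cls(pd.read_csv(path))


_CONFIG_DEFAULTS: dict = {
    "out_dir": "geovax_run",
    "years": [2014, 2018],          # inclusive span [first, last]
    "doses": ["dtp1", "dtp3"],
    "vif_threshold": 5.0,
    "stacking_folds": 5,
    "stacking_spatial_folds": True,
    "n_draws": 1000,
    "raking_mode": "mean",
    "percentiles": [2.5, 97.5],
    "seed": 0,
    "grid": {"n_rows": 20, "n_cols": 20, "cell_size": 5.0},
    "n_covariates": 6,
    "n_states": 1,
    "lgas_per_state": 27,
    "n_clusters": 200,
    "children_per_cluster": 20,
    "conflict_dropout_prob": 1.0,
    "n_conflict_lgas": 21,
    "conflict_event_rate": 10.0,
    "conflict_fatality_mean": 7.0,
    "total_population": 500_000.0,
    "urban_centers": 3,
    "gp": {
        "spatial_range": None,       # default: 1/4 of domain diameter
        "spatial_variance": 1.0,
        "nu": 1.5,
        "rho": 0.7,
        "nugget_variance": 0.1,
        "group_effect_variance": 0.1,
    },
    "paths": {},
}


@dataclass
class RunConfig:
    """Resolved run configuration with documented defaults."""

    settings: dict

    def __getitem__(self, key: str):
        return self.settings[key]

    def get(self, key: str, default=None):
        return self.settings.get(key, default)

    @property
    def years(self) -> list[int]:
        lo, hi = self.settings["years"]
        return list(range(int(lo), int(hi) + 1))

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])


# ---------------------------------------------------------------------------
# operations


def write_raster(
    path: str | Path, grid: PixelGrid, layers: np.ndarray, names: Sequence[str] | None = None
) -> None:
    """Write layers (n_layers, n_pixels) or (n_pixels,) as a multi-page TIFF
    with a JSON geometry sidecar."""
    path = Path(path)
    layers = np.atleast_2d(np.asarray(layers, dtype=np.float64))
    pages = layers.reshape(layers.shape[0], grid.n_rows, grid.n_cols)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {"grid": grid.to_dict()}
    if names is not None:
        sidecar["names"] = list(names)
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _read_one_raster(path: Path) -> tuple[PixelGrid | None, np.ndarray, list[str] | None]:
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    sidecar_path = Path(str(path) + ".json")
    grid = None
    names = None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        grid = PixelGrid.from_dict(meta["grid"])
        names = meta.get("names")
    return grid, arr, names


def _fill_nearest(layer2d: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill NaN cells with the nearest valid neighbour (Euclidean on indices)."""
    from scipy import ndimage

    missing = np.isnan(layer2d)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return layer2d, 0
    if missing.all():
        raise DataError("raster layer has no valid cells")
    _, (ir, ic) = ndimage.distance_transform_edt(missing, return_indices=True)
    return layer2d[ir, ic], n_missing


def read_raster_stack(
    paths: Sequence[str | Path],
    grid: PixelGrid | None = None,
    years: Sequence[int] | None = None,
    names: Sequence[str] | None = None,
) -> CovariateStack:
    """Read one TIFF per covariate (pages = years, or one page replicated).

    Rasters must share geometry; when ``grid`` is given, mismatching rasters
    are resampled to it by nearest neighbour.  Missing cells are filled with
    the nearest valid neighbour and the fill count logged.
    """
    layers = []
    out_names = []
    ref_grid = grid
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise GeometryError(f"raster not found: {path}")
        file_grid, arr, file_names = _read_one_raster(path)
        this_grid = file_grid or PixelGrid(arr.shape[1], arr.shape[2], 1.0)
        if ref_grid is None:
            ref_grid = this_grid
        if (this_grid.n_rows, this_grid.n_cols) != (ref_grid.n_rows, ref_grid.n_cols):
            if grid is None:
                raise GeometryError(
                    f"{path}: geometry {this_grid.n_rows}x{this_grid.n_cols} does not "
                    f"match {ref_grid.n_rows}x{ref_grid.n_cols} and no target grid given"
                )
            arr = _resample_nearest(arr, this_grid, ref_grid)
        layers.append(arr)
        out_names.append(file_names[0] if file_names else path.stem)
    if names is not None:
        out_names = list(names)

    n_years = max(a.shape[0] for a in layers)
    if years is None:
        years = list(range(n_years))
    years = list(int(y) for y in years)
    if len(years) != n_years:
        raise GeometryError(
            f"{len(years)} years supplied for rasters with {n_years} pages"
        )

    values = np.empty((len(layers), n_years, ref_grid.n_pixels))
    time_varying = []
    total_filled = 0
    for j, arr in enumerate(layers):
        if arr.shape[0] not in (1, n_years):
            raise GeometryError(
                f"covariate {out_names[j]} has {arr.shape[0]} pages, expected 1 or {n_years}"
            )
        time_varying.append(arr.shape[0] == n_years and n_years > 1)
        for t in range(n_years):
            page = arr[min(t, arr.shape[0] - 1)]
            filled, n_fill = _fill_nearest(page)
            total_filled += n_fill
            values[j, t] = filled.ravel()
    if total_filled:
        logger.warning("filled %d missing raster cells by nearest neighbour", total_filled)
    return CovariateStack(
        grid=ref_grid, years=years, names=out_names, values=values,
        is_time_varying=time_varying,
    )


def _resample_nearest(arr: np.ndarray, src: PixelGrid, dst: PixelGrid) -> np.ndarray:
    """Nearest-neighbour resample pages from src geometry onto dst cell centers."""
    centers = dst.cell_centers()
    src_pix = src.pixel_of_xy(centers[:, 0], centers[:, 1])
    nearest = np.clip(src_pix, 0, src.n_pixels - 1)
    flat = arr.reshape(arr.shape[0], -1)[:, nearest]
    return flat.reshape(arr.shape[0], dst.n_rows, dst.n_cols)


def read_admin(
    path: str | Path,
    grid: PixelGrid,
    population: np.ndarray | None = None,
) -> AdminFrame:
    """Read an admin partition from GeoJSON polygons or a CSV membership table.

    GeoJSON features need properties ``unit_id``, ``level`` and (for level 2)
    ``parent_id``.  Pixels are assigned by cell-center point-in-polygon;
    overlap ties go to the lowest unit_id with a logged warning; any pixel
    covered by no polygon is an error listing the offending indices.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"admin file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_admin_csv(path, grid)
    return _read_admin_geojson(path, grid)


def _read_admin_csv(path: Path, grid: PixelGrid) -> AdminFrame:
    table = pd.read_csv(path)
    required = {"pixel_id", "unit_id"}
    if not required <= set(table.columns):
        raise DataError(f"membership table needs columns {sorted(required)}")
    owner = np.full(grid.n_pixels, None, dtype=object)
    owner[table["pixel_id"].to_numpy()] = table["unit_id"].to_numpy()
    missing = np.flatnonzero(pd.isna(owner.astype("object")))
    if len(missing):
        raise GeometryError(f"pixels without admin unit: {missing.tolist()[:20]}")
    if {"level", "parent_id"} <= set(table.columns):
        units = table[["unit_id", "level", "parent_id"]].drop_duplicates()
        states = (
            units.loc[units["level"] == 2, "parent_id"]
            .drop_duplicates()
            .to_frame(name="unit_id")
            .assign(level=1, parent_id=None)
        )
        units = pd.concat([states, units[units["level"] == 2]], ignore_index=True)
    else:
        lgas = sorted(pd.unique(table["unit_id"]))
        units = pd.DataFrame(
            {"unit_id": [0] + lgas, "level": [1] + [2] * len(lgas),
             "parent_id": [None] + [0] * len(lgas)}
        )
    return AdminFrame(grid=grid, units=units, pixel_owner=owner, polygons=None)


def _read_admin_geojson(path: Path, grid: PixelGrid) -> AdminFrame:
    from shapely.geometry import shape

    doc = json.loads(path.read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    rows, polys = [], {}
    for f in feats:
        props = f["properties"]
        rows.append(
            {"unit_id": props["unit_id"], "level": int(props["level"]),
             "parent_id": props.get("parent_id")}
        )
        polys[props["unit_id"]] = shape(f["geometry"])
    units = pd.DataFrame(rows)
    centers = grid.cell_centers()
    lga_rows = units[units["level"] == 2].sort_values("unit_id")
    owner = np.full(grid.n_pixels, None, dtype=object)
    overlaps = 0
    from shapely import contains_xy

    # ascending unit_id: first (lowest) id wins overlap ties
    for uid in lga_rows["unit_id"]:
        inside = contains_xy(polys[uid], centers[:, 0], centers[:, 1])
        newly = inside & (owner == None)  # noqa: E711
        overlaps += int((inside & (owner != None)).sum())  # noqa: E711
        owner[newly] = uid
    if overlaps:
        logger.warning(
            "%d pixel centers fell in overlapping polygons; kept lowest unit_id",
            overlaps,
        )
    missing = np.flatnonzero(owner == None)  # noqa: E711
    if len(missing):
        raise GeometryError(f"pixels without admin unit: {missing.tolist()[:20]}")
    return AdminFrame(grid=grid, units=units, pixel_owner=owner, polygons=polys)


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration, applying documented defaults.

    Unknown top-level keys and invalid values raise :class:`ConfigError`;
    the fully resolved configuration is echoed to the log.
    """
    user: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
    if overrides:
        user.update(overrides)

    unknown = set(user) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    settings = json.loads(json.dumps(_CONFIG_DEFAULTS))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(settings.get(key), dict):
            if key != "paths":  # paths is a free-form name -> file mapping
                sub_unknown = set(val) - set(settings[key])
                if sub_unknown:
                    raise ConfigError(f"unknown keys under {key}: {sorted(sub_unknown)}")
            settings[key].update(val)
        else:
            settings[key] = val

    if int(settings["n_draws"]) < 1:
        raise ConfigError("n_draws must be >= 1")
    for p in settings["percentiles"]:
        if not 0 < float(p) < 100:
            raise ConfigError("percentiles must lie in (0, 100)")
    if settings["raking_mode"] not in ("mean", "per-draw"):
        raise ConfigError("raking_mode must be 'mean' or 'per-draw'")
    for key, p in settings.get("paths", {}).items():
        if not Path(p).exists():
            raise ConfigError(f"configured path {key}={p} does not exist")
    logger.info("resolved config: %s", json.dumps(settings, sort_keys=True))
    return RunConfig(settings=settings)
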