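"""Gridded study areas: predictor stacks, occurrence sets, and text raster I/O.

Conventions shared by every raster in the package:

* row 0 is the northernmost row, column 0 the westernmost column;
* ``origin`` is the (longitude, latitude) of the *center* of cell (0, 0);
* all layers of a stack share one grid geometry;
* point coordinates are cell centers.

Layers are written as single-band ESRI ASCII grids (plain text, readable by
any GIS) with a YAML sidecar carrying stack-level metadata (variable tags,
land-use class table, cell size in km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geo import EARTH_RADIUS_KM

#: km spanned by one degree of latitude on the reference sphere
KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0

NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a north-up regular grid addressed by (row, col)."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    origin: tuple[float, float]  # lon, lat of cell (0, 0) center

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def dlat(self) -> float:
        """Cell height in degrees of latitude."""
        return self.cell_size_km / KM_PER_DEG

    @property
    def dlon(self) -> float:
        """Cell width in degrees of longitude at the origin latitude."""
        return self.cell_size_km / (KM_PER_DEG * math.cos(math.radians(self.origin[1])))

    def cell_center(self, row, col):
        """(lon, lat) of cell centers; accepts scalars or arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin[0] + col * self.dlon
        lat = self.origin[1] - row * self.dlat
        return lon, lat

    def lonlat_grids(self):
        """Longitude and latitude of every cell center as (n_rows, n_cols) arrays."""
        rows, cols = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        return self.cell_center(rows, cols)

    def cell_of(self, lon, lat):
        """Nearest cell (row, col) containing the point, or None if outside."""
        col = int(round((lon - self.origin[0]) / self.dlon))
        row = int(round((self.origin[1] - lat) / self.dlat))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2


@dataclass
class EnvStack:
    """Aligned stack of named predictor layers over one grid geometry.

    ``layers`` hold continuous variables (float grids), ``categorical_layers``
    integer class-coded grids. ``variable_meta`` tags each variable as one of
    ``climate``, ``terrain`` or ``human``; ``class_table`` maps integer codes
    of categorical layers to class names.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    categorical_layers: dict[str, np.ndarray] = field(default_factory=dict)
    variable_meta: dict[str, str] = field(default_factory=dict)
    class_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        shape = (self.geometry.n_rows, self.geometry.n_cols)
        for name, grid in {**self.layers, **self.categorical_layers}.items():
            if grid.shape != shape:
                raise ValueError(f"layer {name!r} has shape {grid.shape}, expected {shape}")

    @property
    def n_rows(self) -> int:
        return self.geometry.n_rows

    @property
    def n_cols(self) -> int:
        return self.geometry.n_cols

    @property
    def variables(self) -> list[str]:
        return list(self.layers) + list(self.categorical_layers)

    def layer(self, name: str) -> np.ndarray:
        if name in self.layers:
            return self.layers[name]
        if name in self.categorical_layers:
            return self.categorical_layers[name]
        raise KeyError(f"variable {name!r} not in stack")

    def add_layer(self, name, grid, meta="climate", categorical=False):
        grid = np.asarray(grid)
        if grid.shape != (self.n_rows, self.n_cols):
            raise ValueError(f"layer {name!r} shape mismatch")
        if categorical:
            self.categorical_layers[name] = grid.astype(int)
        else:
            self.layers[name] = grid.astype(float)
        self.variable_meta[name] = meta

    def valid_mask(self) -> np.ndarray:
        """True where every continuous layer is finite and not nodata."""
        mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        for grid in self.layers.values():
            mask &= np.isfinite(grid) & (grid != NODATA)
        return mask

    def values_at(self, lons, lats, variables=None) -> pd.DataFrame:
        """Predictor values at point locations (nearest cell), as a DataFrame.

        Points outside the grid extent yield NaN rows.
        """
        variables = variables if variables is not None else self.variables
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        out = np.full((len(lons), len(variables)), np.nan)
        for i, (lon, lat) in enumerate(zip(lons, lats)):
            cell = self.geometry.cell_of(lon, lat)
            if cell is None:
                continue
            r, c = cell
            out[i] = [self.layer(v)[r, c] for v in variables]
        return pd.DataFrame(out, columns=variables)

    def subset(self, variables) -> "EnvStack":
        """New stack restricted to the named variables (layers shared, not copied)."""
        sub = EnvStack(geometry=self.geometry, class_table=dict(self.class_table))
        for v in variables:
            if v in self.layers:
                sub.layers[v] = self.layers[v]
            elif v in self.categorical_layers:
                sub.categorical_layers[v] = self.categorical_layers[v]
            else:
                raise KeyError(f"variable {v!r} not in stack")
            sub.variable_meta[v] = self.variable_meta.get(v, "climate")
        return sub

    # ------------------------------------------------------------------ I/O

    def write(self, directory) -> None:
        """Write one ASCII grid per layer plus a ``stack.yaml`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", grid, self.geometry)
        for name, grid in self.categorical_layers.items():
            write_ascii_grid(directory / f"{name}.asc", grid, self.geometry, integer=True)
        meta = {
            "cell_size_km": float(self.geometry.cell_size_km),
            "origin": [float(self.geometry.origin[0]), float(self.geometry.origin[1])],
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "variable_meta": dict(self.variable_meta),
            "categorical": list(self.categorical_layers),
            "class_table": {int(k): v for k, v in self.class_table.items()},
        }
        (directory / "stack.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def read(cls, directory) -> "EnvStack":
        directory = Path(directory)
        meta = yaml.safe_load((directory / "stack.yaml").read_text())
        geom = GridGeometry(
            n_rows=meta["n_rows"],
            n_cols=meta["n_cols"],
            cell_size_km=meta["cell_size_km"],
            origin=tuple(meta["origin"]),
        )
        stack = cls(
            geometry=geom,
            variable_meta=dict(meta["variable_meta"]),
            class_table={int(k): v for k, v in meta.get("class_table", {}).items()},
        )
        categorical = set(meta.get("categorical", []))
        for name in meta["variable_meta"]:
            grid, _ = read_ascii_grid(directory / f"{name}.asc")
            if name in categorical:
                stack.categorical_layers[name] = grid.astype(int)
            else:
                stack.layers[name] = grid
        return stack


@dataclass
class OccurrenceSet:
    """Presence points with per-point provenance labels."""

    lons: np.ndarray
    lats: np.ndarray
    sources: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        if len(self.lons) != len(self.lats):
            raise ValueError("lon/lat length mismatch")
        if not self.sources:
            self.sources = ["unknown"] * len(self.lons)
        coords = set(zip(self.lons.tolist(), self.lats.tolist()))
        if len(coords) != len(self.lons):
            raise ValueError("duplicated coordinate pairs in occurrence set")

    def __len__(self) -> int:
        return len(self.lons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lons, "lat": self.lats, "source": self.sources})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy(), df["source"].astype(str).tolist())

    @classmethod
    def from_cells(cls, geometry: GridGeometry, rows, cols, source="synthetic") -> "OccurrenceSet":
        lon, lat = geometry.cell_center(np.asarray(rows), np.asarray(cols))
        return cls(lon, lat, [source] * len(np.atleast_1d(lon)))


# ---------------------------------------------------------------- ASCII I/O


def write_ascii_grid(path, grid, geometry: GridGeometry, integer=False, nodata=NODATA):
    """Write a single-band ESRI ASCII grid (cellsize in degrees of latitude)."""
    grid = np.asarray(grid)
    dlat = geometry.dlat
    xll = geometry.origin[0] - geometry.dlon / 2.0
    yll = geometry.origin[1] - (geometry.n_rows - 0.5) * dlat
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {xll:.10f}\n"
        f"yllcorner {yll:.10f}\n"
        f"cellsize {dlat:.10f}\n"
        f"NODATA_value {int(nodata) if integer else nodata}\n"
    )
    body = np.where(np.isfinite(grid), grid, nodata)
    fmt = "%d" if integer else "%.6g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=fmt)


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array with NaN for nodata, header dict)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:])
    grid = np.atleast_2d(grid)
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, header
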