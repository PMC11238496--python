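"""Gridded covariate stacks and plain-text raster I/O.

A :class:`CovariateStack` is one :class:`~mdfps.geometry.GridSpec` plus one
2-D layer per geostatistical covariate, with per-layer mean/sd metadata so
that cluster-level extraction and pixel-level prediction standardize
identically. Layers are interchanged as ESRI ASCII grids (.asc) with a YAML
sidecar holding the standardization metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import GridSpec

__all__ = ["CovariateStack", "extract_covariates", "read_ascii_grid", "write_ascii_grid"]


def write_ascii_grid(path: str, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 of the file is the north row)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.ny, grid.nx):
        raise ValueError(f"layer shape {values.shape} != grid ({grid.ny}, {grid.nx})")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.nx}\n")
        fh.write(f"nrows {grid.ny}\n")
        fh.write(f"xllcorner {grid.origin_x}\n")
        fh.write(f"yllcorner {grid.origin_y}\n")
        fh.write(f"cellsize {grid.pixel_km}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in out[::-1]:  # ASCII grids are stored north-to-south
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        nx, ny = int(header["ncols"]), int(header["nrows"])
        body = np.loadtxt(fh)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        pixel_km=header["cellsize"],
        nx=nx,
        ny=ny,
    )
    values = np.asarray(body, dtype=float).reshape(ny, nx)[::-1].copy()
    values[values == header["nodata_value"]] = np.nan
    return grid, values


@dataclass
class CovariateStack:
    """A grid plus named covariate layers and standardization metadata.

    ``meta[name]`` holds the layer's mean and sd recorded at creation time;
    these — not the moments of whatever subset is later extracted — define
    the standardization used by the geostatistical model at both fit and
    prediction time.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.ny, self.grid.nx):
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid shape")
            self.layers[name] = arr
            if name not in self.meta:
                self.meta[name] = {"mean": float(np.nanmean(arr)), "sd": float(np.nanstd(arr))}

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def standardized(self, name: str) -> np.ndarray:
        """Layer transformed to (x - mean)/sd; sd 0 (constant layer) maps to zeros."""
        m = self.meta[name]
        sd = m["sd"] if m["sd"] > 0 else 1.0
        return (self.layers[name] - m["mean"]) / sd

    def write(self, directory: str, prefix: str = "") -> None:
        os.makedirs(directory, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(os.path.join(directory, f"{prefix}{name}.asc"), self.grid, arr)
        meta = {"grid": self.grid.signature(), "layers": {k: dict(v) for k, v in self.meta.items()}}
        with open(os.path.join(directory, f"{prefix}stack.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)  # layer order is meaningful

    @classmethod
    def read(cls, directory: str, prefix: str = "") -> "CovariateStack":
        with open(os.path.join(directory, f"{prefix}stack.yaml")) as fh:
            meta = yaml.safe_load(fh)
        grid = GridSpec.from_signature(meta["grid"])
        layers = {}
        for name in meta["layers"]:
            g, arr = read_ascii_grid(os.path.join(directory, f"{prefix}{name}.asc"))
            if g.signature() != grid.signature():
                raise ValueError(f"layer {name!r} grid does not match the stack grid")
            layers[name] = arr
        return cls(grid=grid, layers=layers, meta=meta["layers"])


def extract_covariates(
    stack: CovariateStack,
    points: np.ndarray,
    standardize: bool = True,
    names: list[str] | None = None,
) -> np.ndarray:
    """Value of the containing pixel for each layer at each point.

    Points outside the raster extent raise (the offenders are listed); NaN
    pixels raise unless the stack has no missing data at those cells.
    Returns an (n_points, n_layers) matrix in ``names`` order.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x/y km coordinates")
    names = list(stack.names if names is None else names)
    row, col = stack.grid.pixel_index(points[:, 0], points[:, 1])
    cols = []
    for name in names:
        layer = stack.standardized(name) if standardize else stack.layers[name]
        vals = layer[row, col]
        if np.any(~np.isfinite(vals)):
            bad = points[~np.isfinite(vals)]
            raise ValueError(f"layer {name!r} has missing data at points {bad.tolist()}")
        cols.append(vals)
    return np.column_stack(cols)
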