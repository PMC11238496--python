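"""Admin-unit polygons and regular prediction grids.

Coordinates live in a projected kilometre plane so that Matérn range
parameters are in km and pixel sizes (default 5 km) are metric. Admin
units are plain shapely polygons with integer IDs, serialised as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.strtree import STRtree

__all__ = ["AdminUnits", "GridSpec", "make_admin_grid"]


@dataclass
class AdminUnits:
    """A set of non-overlapping administrative polygons with unique integer IDs."""

    ids: list[int]
    polygons: list[Polygon]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("admin IDs must be unique")
        self._tree = STRtree(self.polygons)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def union(self) -> Polygon:
        from shapely.ops import unary_union

        return unary_union(self.polygons)

    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Admin ID containing each point; -1 where no polygon contains it.

        Boundary points belong to every touching polygon; ties broken by
        lowest admin ID so membership is deterministic.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, -1, dtype=int)
        pts = [Point(xi, yi) for xi, yi in zip(x.ravel(), y.ravel())]
        order = np.argsort(self.ids, kind="stable")
        flat = out.ravel()
        for k, pt in enumerate(pts):
            hit = -1
            for j in self._tree.query(pt, predicate="intersects"):
                cand = self.ids[int(j)]
                if hit == -1 or cand < hit:
                    hit = cand
            flat[k] = hit
        return flat.reshape(x.shape)

    def sample_points(self, admin_id: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points inside one polygon by rejection from its bounding box."""
        poly = self.polygons[self.ids.index(admin_id)]
        minx, miny, maxx, maxy = poly.bounds
        got: list[tuple[float, float]] = []
        while len(got) < n:
            m = max(4 * (n - len(got)), 16)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            for xi, yi in zip(xs, ys):
                if poly.contains(Point(xi, yi)):
                    got.append((xi, yi))
                    if len(got) == n:
                        break
        return np.asarray(got)

    def to_geojson(self, path: str) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"admin_id": int(i)},
                "geometry": mapping(p),
            }
            for i, p in zip(self.ids, self.polygons)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path: str) -> "AdminUnits":
        with open(path) as fh:
            gj = json.load(fh)
        ids, polys = [], []
        for feat in gj["features"]:
            ids.append(int(feat["properties"]["admin_id"]))
            polys.append(shape(feat["geometry"]))
        return cls(ids=ids, polygons=polys)


def make_admin_grid(n_regions: int, extent_km: float, seed: int = 0) -> AdminUnits:
    """Tile a square study area of side ``extent_km`` into ``n_regions`` rectangles.

    The tiling uses the most square factor pair r x c of ``n_regions``
    (r = largest divisor <= sqrt(n)); primes therefore fall back to
    vertical strips. IDs run 1..n_regions in row-major order.
    """
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    if extent_km <= 0:
        raise ValueError(f"extent_km must be > 0, got {extent_km}")
    rows = 1
    for d in range(1, int(np.sqrt(n_regions)) + 1):
        if n_regions % d == 0:
            rows = d
    cols = n_regions // rows
    dx = extent_km / cols
    dy = extent_km / rows
    ids, polys = [], []
    k = 1
    for r in range(rows):
        for c in range(cols):
            polys.append(box(c * dx, r * dy, (c + 1) * dx, (r + 1) * dy))
            ids.append(k)
            k += 1
    return AdminUnits(ids=ids, polygons=polys)


@dataclass(frozen=True)
class GridSpec:
    """Regular raster grid: origin at the lower-left corner, square pixels.

    Pixel (row i, col j) spans [origin_x + j*px, origin_x + (j+1)*px] x
    [origin_y + i*px, origin_y + (i+1)*px]; arrays are stored (ny, nx) with
    row 0 the southernmost row.
    """

    origin_x: float
    origin_y: float
    pixel_km: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.pixel_km <= 0:
            raise ValueError("pixel_km must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one pixel per axis")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.nx) + 0.5) * self.pixel_km

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.ny) + 0.5) * self.pixel_km

    def centers(self) -> np.ndarray:
        """(n_pixels, 2) array of pixel-centre coordinates, row-major."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def pixel_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the pixel containing each point; raises if outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_km).astype(int)
        row = np.floor((y - self.origin_y) / self.pixel_km).astype(int)
        # points exactly on the far edge belong to the last pixel
        col = np.where((x == self.origin_x + self.nx * self.pixel_km), self.nx - 1, col)
        row = np.where((y == self.origin_y + self.ny * self.pixel_km), self.ny - 1, row)
        bad = (col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)
        if np.any(bad):
            offenders = np.column_stack([np.atleast_1d(x)[np.atleast_1d(bad)],
                                         np.atleast_1d(y)[np.atleast_1d(bad)]])
            raise ValueError(f"points outside raster extent: {offenders.tolist()}")
        return row, col

    def signature(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_km": self.pixel_km,
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_signature(cls, sig: dict) -> "GridSpec":
        return cls(**{k: sig[k] for k in ("origin_x", "origin_y", "pixel_km", "nx", "ny")})

    def mask_from_admin(self, admin: AdminUnits) -> np.ndarray:
        """Boolean (ny, nx) mask: True where the pixel centre lies in some admin unit."""
        pts = self.centers()
        ids = admin.locate(pts[:, 0], pts[:, 1])
        return (ids >= 0).reshape(self.ny, self.nx)
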