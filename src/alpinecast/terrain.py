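"""Topographic predictors derived from a DEM at fine resolution.

Five standard terrain variables feed the community area-fraction model:
slope (Horn 3x3 gradient, degrees), aspect (downslope compass direction,
degrees clockwise from north), general curvature (Zevenbergen-Thorne 3x3
quadratic, convex-up positive), topographic wetness index
``TWI = ln(a / tan(beta))`` with specific catchment area ``a`` from
single-direction (D8) flow accumulation, and Euclidean distance from the
ridgeline. Ridge cells are drainage divides: cells whose flow accumulation on
the *inverted* DEM exceeds a high quantile.

Finite differences are undefined on the outer one-cell border; derived values
there are NaN and model fitting excludes them.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import GridGeometry

__all__ = [
    "TerrainGrid",
    "slope_aspect",
    "curvature",
    "fill_pits",
    "d8_flow_accumulation",
    "twi",
    "ridge_distance",
    "derive_terrain",
]

TAN_SLOPE_FLOOR = 1e-3  # slope floor for TWI on (near-)flat cells
FLAT_EPS = 1e-9

# D8 neighbor offsets (row, col) and their grid distances in cell units
_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_D8_DIST = np.array([np.hypot(dr, dc) for dr, dc in _D8])


class DegenerateLandscapeError(ValueError):
    """Raised when the landscape admits no ridge cells."""


@dataclass
class TerrainGrid:
    """Elevation and the five derived topographic variables on the fine lattice."""

    elevation: np.ndarray
    slope: np.ndarray
    aspect: np.ndarray
    curvature: np.ndarray
    twi: np.ndarray
    ridge_distance: np.ndarray
    ridge_mask: np.ndarray
    geom: GridGeometry

    def predictor_table(self, zone_probability: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Flatten predictors to an (n, p) matrix over interior cells.

        Returns (X, valid_mask_flat, names); NaN rows (the border) are dropped.
        ``zone_probability`` on the same lattice adds a sixth column.
        """
        layers = [self.slope, self.aspect, self.curvature, self.twi,
                  self.ridge_distance]
        names = ["slope", "aspect", "curvature", "twi", "ridge_distance"]
        if zone_probability is not None:
            layers.append(np.asarray(zone_probability))
            names.append("zone_probability")
        stack = np.stack([l.ravel() for l in layers], axis=1)
        valid = ~np.isnan(stack).any(axis=1)
        return stack[valid], valid, names


def _check_grid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation grid must be at least 3x3")
    return z


def slope_aspect(elevation: np.ndarray, cell_size: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Horn (1981) 3x3 slope and downslope aspect.

    Slope in degrees in [0, 90); aspect in degrees clockwise from north of the
    steepest *descent* direction, NaN on flat cells and the border.
    """
    z = _check_grid(elevation)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell_size)
    dz_dn = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell_size)
    grad = np.hypot(dz_dx, dz_dn)
    slope = np.full(z.shape, np.nan)
    aspect = np.full(z.shape, np.nan)
    slope[1:-1, 1:-1] = np.degrees(np.arctan(grad))
    asp = np.degrees(np.arctan2(-dz_dx, -dz_dn)) % 360.0
    asp = np.where(grad < FLAT_EPS, np.nan, asp)
    aspect[1:-1, 1:-1] = asp
    return slope, aspect


def curvature(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Zevenbergen-Thorne general curvature (1/m), convex-up (ridges) positive."""
    z = _check_grid(elevation)
    z0 = z[1:-1, 1:-1]
    d = ((z[1:-1, :-2] + z[1:-1, 2:]) / 2.0 - z0) / cell_size**2
    e = ((z[:-2, 1:-1] + z[2:, 1:-1]) / 2.0 - z0) / cell_size**2
    curv = np.full(z.shape, np.nan)
    curv[1:-1, 1:-1] = -2.0 * (d + e)
    return curv


def fill_pits(elevation: np.ndarray) -> np.ndarray:
    """Minimal pit filling by priority-flood so every cell drains to the edge."""
    z = _check_grid(elevation).copy()
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(nr):
        for c in (0, nc - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    for c in range(1, nc - 1):
        for r in (0, nr - 1):
            heapq.heappush(heap, (z[r, c], r, c))
            visited[r, c] = True
    while heap:
        h, r, c = heapq.heappop(heap)
        filled[r, c] = h
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                visited[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], h), rr, cc))
    return filled


def d8_flow_accumulation(elevation: np.ndarray, cell_size: float,
                         fill: bool = True) -> np.ndarray:
    """D8 flow accumulation in cell counts (each cell contributes itself).

    Water in each cell moves to the steepest-descent neighbor (drop divided by
    center-to-center distance); cells with no lower neighbor do not drain.
    """
    z = fill_pits(elevation) if fill else _check_grid(elevation).copy()
    nr, nc = z.shape
    acc = np.ones((nr, nc))
    order = np.argsort(z, axis=None)[::-1]  # high to low
    rows, cols = np.unravel_index(order, z.shape)
    for r, c in zip(rows, cols):
        best_grade = 0.0
        target = None
        for (dr, dc), dist in zip(_D8, _D8_DIST):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                grade = (z[r, c] - z[rr, cc]) / dist
                if grade > best_grade:
                    best_grade = grade
                    target = (rr, cc)
        if target is not None:
            acc[target] += acc[r, c]
    return acc


def twi(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Topographic wetness index ln(a / tan(beta)).

    ``a`` is the specific catchment area (accumulated area per unit contour
    width, i.e. cell count x cell size); ``tan(beta)`` comes from the Horn
    slope with a small floor on flat cells. NaN on the border. Adding a
    constant to all elevations leaves TWI unchanged.
    """
    acc = d8_flow_accumulation(elevation, cell_size)
    sca = acc * cell_size
    slope_deg, _ = slope_aspect(elevation, cell_size)
    tan_b = np.maximum(np.tan(np.radians(slope_deg)), TAN_SLOPE_FLOOR)
    return np.log(sca / tan_b)


def ridge_distance(elevation: np.ndarray, cell_size: float,
                   ridge_threshold_quantile: float = 0.99
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge mask and Euclidean distance (m) to the nearest ridge cell.

    Ridges are drainage divides: cells whose D8 flow accumulation computed on
    the inverted DEM exceeds the given quantile of its distribution.
    """
    inv_acc = d8_flow_accumulation(-np.asarray(elevation, dtype=float), cell_size)
    thresh = np.quantile(inv_acc, ridge_threshold_quantile)
    mask = inv_acc >= thresh
    if not mask.any():
        raise DegenerateLandscapeError("no ridge cells found")
    dist = ndimage.distance_transform_edt(~mask) * cell_size
    return mask, dist


def derive_terrain(elevation: np.ndarray, geom: GridGeometry,
                   ridge_threshold_quantile: float = 0.99) -> TerrainGrid:
    """Compute all five topographic predictors from a DEM."""
    cs = geom.cell_size_m
    slope, aspect = slope_aspect(elevation, cs)
    curv = curvature(elevation, cs)
    wetness = twi(elevation, cs)
    mask, dist = ridge_distance(elevation, cs, ridge_threshold_quantile)
    # flat-cell aspect stays NaN; model fitting drops those rows
    return TerrainGrid(elevation=np.asarray(elevation, dtype=float), slope=slope,
                       aspect=aspect, curvature=curv, twi=wetness,
                       ridge_distance=dist, ridge_mask=mask, geom=geom)
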