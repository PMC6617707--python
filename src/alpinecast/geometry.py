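"""Grid geometry bookkeeping and plain-text raster I/O.

All layers in the cascade live on axis-aligned rectangular lattices that tile the
same domain: a fine terrain lattice (default 100 m), a coarse climate lattice
(default 1 km) and an intermediate territory lattice (default 300 m). Rows run
north to south (row 0 is the northern edge), columns west to east.

Rasters are persisted as ESRI ASCII grids (a plain-text format readable by any
GIS) so that every artifact of a run is human-inspectable text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GridGeometry",
    "n_cells",
    "cell_area_km2",
    "block_mean",
    "upsample_nearest",
    "write_ascii_grid",
    "read_ascii_grid",
]


class ConfigurationError(ValueError):
    """Invalid grid or landscape configuration."""


def n_cells(width_m: float, height_m: float, resolution_m: float) -> int:
    """Number of cells tiling a ``width_m`` x ``height_m`` domain at ``resolution_m``.

    Raises :class:`ConfigurationError` if the resolution does not divide both
    extents evenly.
    """
    if resolution_m <= 0 or width_m <= 0 or height_m <= 0:
        raise ConfigurationError("extents and resolution must be positive")
    nx = width_m / resolution_m
    ny = height_m / resolution_m
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ConfigurationError(
            f"resolution {resolution_m} m does not tile {width_m} x {height_m} m evenly"
        )
    return int(round(nx)) * int(round(ny))


def cell_area_km2(resolution_m: float) -> float:
    """Area of one square cell in km^2 (e.g. 300 m -> 0.09 km^2)."""
    return (resolution_m / 1000.0) ** 2


@dataclass(frozen=True)
class GridGeometry:
    """Shape and placement of a rectangular lattice.

    ``nrows`` x ``ncols`` cells of edge ``cell_size_m``; ``x0, y0`` is the
    north-west corner of the domain in meters.
    """

    nrows: int
    ncols: int
    cell_size_m: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1 or self.cell_size_m <= 0:
            raise ConfigurationError("grid must have positive shape and cell size")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def width_m(self) -> float:
        return self.ncols * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.nrows * self.cell_size_m

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates; x eastward, y southward from the NW corner."""
        x = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size_m
        y = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell_size_m
        return x, y

    def refine(self, factor: int) -> "GridGeometry":
        return GridGeometry(self.nrows * factor, self.ncols * factor,
                            self.cell_size_m / factor, self.x0, self.y0)

    def coarsen(self, factor: int) -> "GridGeometry":
        if self.nrows % factor or self.ncols % factor:
            raise ConfigurationError("coarsening factor must divide grid shape")
        return GridGeometry(self.nrows // factor, self.ncols // factor,
                            self.cell_size_m * factor, self.x0, self.y0)

    def factor_to(self, other: "GridGeometry") -> int:
        """Integer refinement factor from ``other`` (coarser) to this grid."""
        ratio = other.cell_size_m / self.cell_size_m
        f = int(round(ratio))
        if abs(ratio - f) > 1e-9 or f < 1:
            raise ConfigurationError(
                f"cell sizes {other.cell_size_m} and {self.cell_size_m} are not nested"
            )
        return f


def block_mean(values: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a fine grid to a coarse grid by block averaging.

    Each coarse cell is the mean of its ``factor x factor`` constituent fine
    cells; the fine shape must be an exact multiple of ``factor``.
    """
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    if nr % factor or nc % factor:
        raise ConfigurationError("block_mean: factor must divide the grid shape")
    return values.reshape(nr // factor, factor, nc // factor, factor).mean(axis=(1, 3))


def upsample_nearest(values: np.ndarray, factor: int) -> np.ndarray:
    """Replicate each coarse cell into ``factor x factor`` fine cells (nearest)."""
    return np.repeat(np.repeat(np.asarray(values), factor, axis=0), factor, axis=1)


def write_ascii_grid(path: str | Path, values: np.ndarray, geom: GridGeometry,
                     nodata: float = -9999.0) -> None:
    """Write a single-band raster as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != geom.shape:
        raise ValueError("raster shape does not match geometry")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {geom.ncols}\n"
        f"nrows {geom.nrows}\n"
        f"xllcorner {geom.x0}\n"
        f"yllcorner {geom.y0 - geom.height_m}\n"
        f"cellsize {geom.cell_size_m}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid back into (values, geometry); NODATA becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    cs = header["cellsize"]
    geom = GridGeometry(nrows, ncols, cs, x0=header["xllcorner"],
                        y0=header["yllcorner"] + nrows * cs)
    return values, geom
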