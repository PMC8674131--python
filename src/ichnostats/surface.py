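"""Elevation-grid handling: substrate plane fitting and regional depths.

A footprint is recorded as a regular elevation grid (mm, positive up) with
a boolean substrate mask marking undisturbed cells around the track.  A
least-squares plane through the masked substrate defines the reference
surface; the depth of each of the 14 anatomical regions is the drop from
that plane to the deepest cell inside a square window centred on the
region's landmark.

Grid convention (used everywhere): 0-based cell indices, lower-left
origin, x along columns, y along rows, elevations positive up, depths
positive down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .regions import REGIONS, validate_regions

logger = logging.getLogger(__name__)


@dataclass
class PlaneParams:
    """Plane z = a*x + b*y + c, slopes in mm/mm and offset in mm."""

    a: float
    b: float
    c: float

    def height(self, x, y):
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c


@dataclass
class SurfaceGrid:
    """Regular elevation grid of one footprint plus its substrate mask.

    ``elevations[j, i]`` is the height at cell column *i*, row *j*;
    world coordinates of a cell centre are
    ``(x0 + i * spacing, y0 + j * spacing)``.
    """

    elevations: np.ndarray  # (ny, nx), mm
    spacing: float  # mm per cell
    origin: tuple[float, float] = (0.0, 0.0)
    substrate_mask: np.ndarray | None = None

    def __post_init__(self):
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be a 2-D grid")
        if not np.all(np.isfinite(self.elevations)):
            raise ValueError("elevations contain non-finite values")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.substrate_mask is not None:
            self.substrate_mask = np.asarray(self.substrate_mask, dtype=bool)
            if self.substrate_mask.shape != self.elevations.shape:
                raise ValueError("substrate_mask shape differs from elevations")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def cell_coords(self):
        """World (x, y) coordinate arrays of all cell centres."""
        ny, nx = self.shape
        x = self.origin[0] + np.arange(nx) * self.spacing
        y = self.origin[1] + np.arange(ny) * self.spacing
        return np.meshgrid(x, y)

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell (col, row) for a world coordinate."""
        i = int(round((x - self.origin[0]) / self.spacing))
        j = int(round((y - self.origin[1]) / self.spacing))
        return i, j


def fit_substrate_plane(grid: SurfaceGrid) -> PlaneParams:
    """Least-squares plane through the masked substrate cells.

    Raises ValueError if the mask is missing, has fewer than three cells,
    or its cells are collinear (the normal equations are then singular).
    """
    if grid.substrate_mask is None:
        raise ValueError("substrate plane fit requires a substrate_mask")
    mask = grid.substrate_mask
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"substrate_mask has {n} cells; need >= 3 non-collinear")
    xx, yy = grid.cell_coords()
    x = xx[mask]
    y = yy[mask]
    z = grid.elevations[mask]
    design = np.column_stack([x, y, np.ones_like(x)])
    # Collinearity check: rank of the design must be 3.
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("substrate_mask cells are collinear; plane is underdetermined")
    coef, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
    plane = PlaneParams(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]))
    resid = z - design @ coef
    logger.debug(
        "substrate plane fit: n=%d cells, rms residual %.4g mm", n, float(np.sqrt(np.mean(resid**2)))
    )
    return plane


def measure_region_depths(
    grid: SurfaceGrid,
    landmarks: dict[str, tuple[float, float]],
    plane: PlaneParams,
    window_mm: float = 10.0,
) -> dict[str, float]:
    """Depth of each of the 14 regions below the substrate plane.

    depth(region) = plane height at the landmark minus the minimum
    elevation inside the square window (side ``window_mm``) centred on the
    landmark, clamped at zero.  Raised features therefore report zero
    depth (with a warning): the protocol measures depressions only.
    """
    if window_mm <= 0:
        raise ValueError("window_mm must be positive")
    validate_regions(landmarks.keys())
    half = window_mm / 2.0
    ny, nx = grid.shape
    depths: dict[str, float] = {}
    for region in REGIONS:
        x, y = landmarks[region]
        i0 = int(np.ceil((x - half - grid.origin[0]) / grid.spacing))
        i1 = int(np.floor((x + half - grid.origin[0]) / grid.spacing))
        j0 = int(np.ceil((y - half - grid.origin[1]) / grid.spacing))
        j1 = int(np.floor((y + half - grid.origin[1]) / grid.spacing))
        if i0 < 0 or j0 < 0 or i1 >= nx or j1 >= ny or i1 < i0 or j1 < j0:
            raise ValueError(
                f"window for region {region!r} at ({x}, {y}) mm falls off the grid"
            )
        window = grid.elevations[j0 : j1 + 1, i0 : i1 + 1]
        depth = float(plane.height(x, y) - window.min())
        if depth < 0:
            logger.warning(
                "region %s rises %.3g mm above the substrate plane; reporting 0 depth",
                region,
                -depth,
            )
            depth = 0.0
        depths[region] = depth
    return depths


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_esri_ascii(path) -> SurfaceGrid:
    """Read an ESRI ASCII grid (.asc) into a SurfaceGrid (no mask)."""
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != ncols * nrows:
        raise ValueError(
            f"grid body has {values.size} values, expected {ncols * nrows}"
        )
    # ASCII grids are stored top row first; flip to lower-left origin.
    elev = values.reshape(nrows, ncols)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        elev = np.where(elev == nodata, np.nan, elev)
        if np.isnan(elev).any():
            raise ValueError("grid contains nodata cells; not supported")
    spacing = float(header["cellsize"])
    # Header corners are cell edges; cell centres sit half a cell inward.
    x0 = header.get("xllcorner", 0.0) + spacing / 2.0
    y0 = header.get("yllcorner", 0.0) + spacing / 2.0
    return SurfaceGrid(elevations=elev, spacing=spacing, origin=(x0, y0))


def write_esri_ascii(path, grid: SurfaceGrid) -> None:
    """Write a SurfaceGrid as an ESRI ASCII grid (mask not stored)."""
    ny, nx = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.origin[0] - grid.spacing / 2.0:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1] - grid.spacing / 2.0:.6f}\n")
        fh.write(f"cellsize {grid.spacing:.6f}\n")
        for row in grid.elevations[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
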