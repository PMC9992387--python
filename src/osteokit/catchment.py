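"""Site-catchment analysis: travel-time isochrones on a DEM and
slope-threshold habitat partitioning.

Travel times are anisotropic: walking speed follows Tobler's hiking
function evaluated on the gradient *along the direction of movement*, so
uphill and downhill times between the same two cells differ.  Shortest
times from the site are computed with Dijkstra over a grid neighbourhood;
the default neighbourhood includes the eight queen moves plus the eight
knight moves (16 directions), which keeps the discrete travel-time metric
within about 1.4% of the true Euclidean cost on homogeneous terrain —
the classical 8-move stencil systematically underestimates reachable
areas by ~10% (its unit ball is an octagon of area 2*sqrt(2) vs pi).

The reachable area within an isochrone is split at a slope threshold
(default 30%) into plain (grazing-suitable lowland) and mountainous
terrain, mirroring how mountain-adapted prey (ibex, chamois) and plain
dwellers (bovines, deer) partition the landscape.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import HikingParameters


class CatchmentError(ValueError):
    pass


@dataclass
class DEMRaster:
    """Regular elevation grid in metres, projected coordinates."""

    elevation: np.ndarray               # 2-D, metres
    cell_size: float                    # metres
    origin: tuple[float, float] = (0.0, 0.0)   # (x, y) of lower-left corner
    nodata: np.ndarray | None = None    # bool mask, True = missing
    barriers: np.ndarray | None = None  # bool mask, True = insurmountable

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, float)
        if self.elevation.ndim != 2:
            raise CatchmentError("elevation must be a 2-D array")
        if self.cell_size <= 0:
            raise CatchmentError("cell size must be > 0")
        if self.nodata is None:
            self.nodata = ~np.isfinite(self.elevation)
        if self.barriers is None:
            self.barriers = np.zeros(self.elevation.shape, bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def blocked(self) -> np.ndarray:
        return self.nodata | self.barriers


def read_ascii_grid(path: str | Path) -> DEMRaster:
    """Read an Esri ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    elev = np.array(rows, float)
    nodata_value = header.get("nodata_value")
    nodata = (elev == nodata_value) if nodata_value is not None else None
    cell = header.get("cellsize", 1.0)
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0)
    if nodata is not None:
        elev = np.where(nodata, np.nan, elev)
    return DEMRaster(elevation=elev, cell_size=cell, origin=(x0, y0),
                     nodata=nodata)


def write_ascii_grid(dem: DEMRaster, path: str | Path,
                     nodata_value: float = -9999.0) -> None:
    nrows, ncols = dem.shape
    elev = np.where(dem.nodata, nodata_value, dem.elevation)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {dem.origin[0]!r}\n")
        fh.write(f"yllcorner {dem.origin[1]!r}\n")
        fh.write(f"cellsize {dem.cell_size!r}\n")
        fh.write(f"nodata_value {nodata_value!r}\n")
        for row in elev:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def slope_percent(dem: DEMRaster) -> np.ndarray:
    """Per-cell slope in percent (100 x tan of steepest descent), Horn 3x3.

    Border cells use edge-replicated padding; any cell whose 3x3 window
    touches nodata is itself nodata (NaN).
    """
    z = dem.elevation
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise CatchmentError("raster must be at least 3x3 for slope")
    zp = np.pad(np.where(dem.nodata, np.nan, z), 1, mode="edge")
    # 3x3 window shifts: [row offset, col offset] -> subarray
    w = {(di, dj): zp[1 + di:1 + di + z.shape[0], 1 + dj:1 + dj + z.shape[1]]
         for di in (-1, 0, 1) for dj in (-1, 0, 1)}
    cs = dem.cell_size
    dz_dx = ((w[(-1, 1)] + 2 * w[(0, 1)] + w[(1, 1)])
             - (w[(-1, -1)] + 2 * w[(0, -1)] + w[(1, -1)])) / (8 * cs)
    dz_dy = ((w[(1, -1)] + 2 * w[(1, 0)] + w[(1, 1)])
             - (w[(-1, -1)] + 2 * w[(-1, 0)] + w[(-1, 1)])) / (8 * cs)
    slope = 100.0 * np.hypot(dz_dx, dz_dy)
    slope[np.isnan(slope)] = np.nan
    return slope


_MOVES_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0),
            (1, 1)]
_MOVES_16 = _MOVES_8 + [(-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2),
                        (1, 2), (2, -1), (2, 1)]


def _knight_midcells(r: int, c: int, dr: int,
                     dc: int) -> list[tuple[int, int]]:
    """Cells a knight move passes between; both must be traversable."""
    if abs(dc) == 2:
        return [(r, c + dc // 2), (r + dr, c + dc // 2)]
    return [(r + dr // 2, c), (r + dr // 2, c + dc)]


def _step_allowed(blocked: np.ndarray, r: int, c: int, dr: int,
                  dc: int) -> bool:
    nr, nc = r + dr, c + dc
    nrows, ncols = blocked.shape
    if not (0 <= nr < nrows and 0 <= nc < ncols) or blocked[nr, nc]:
        return False
    if abs(dr) + abs(dc) == 3:  # knight move: cannot hop a barrier
        for mr, mc in _knight_midcells(r, c, dr, dc):
            if blocked[mr, mc]:
                return False
    return True


def travel_time(dem: DEMRaster, origin: tuple[int, int],
                hiking: HikingParameters | None = None,
                neighborhood: int = 16) -> np.ndarray:
    """Minutes of walking from ``origin`` to every cell (inf = unreachable).

    Dijkstra over the grid; per-step speed from the hiking function on the
    gradient along the step.  Barrier and nodata cells are never entered.
    """
    hiking = hiking or HikingParameters()
    nrows, ncols = dem.shape
    r0, c0 = origin
    if not (0 <= r0 < nrows and 0 <= c0 < ncols):
        raise CatchmentError(f"origin {origin} outside grid {dem.shape}")
    blocked = dem.blocked()
    if blocked[r0, c0]:
        raise CatchmentError("origin is a barrier or nodata cell")
    moves = {8: _MOVES_8, 16: _MOVES_16}.get(neighborhood)
    if moves is None:
        raise CatchmentError("neighborhood must be 8 or 16")
    z = dem.elevation
    cs = dem.cell_size
    time = np.full(dem.shape, np.inf)
    time[r0, c0] = 0.0
    done = np.zeros(dem.shape, bool)
    heap = [(0.0, r0, c0)]
    while heap:
        t, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        for dr, dc in moves:
            if not _step_allowed(blocked, r, c, dr, dc):
                continue
            nr, nc = r + dr, c + dc
            dist = math.hypot(dr, dc) * cs          # metres
            gradient = (z[nr, nc] - z[r, c]) / dist
            v = hiking.speed(gradient)              # km/h
            step = (dist / 1000.0) / v * 60.0       # minutes
            nt = t + step
            if nt < time[nr, nc]:
                time[nr, nc] = nt
                heapq.heappush(heap, (nt, nr, nc))
    return time


@dataclass
class IsochroneEntry:
    minutes: float
    mask: np.ndarray
    total_km2: float
    plain_km2: float
    mountain_km2: float

    @property
    def plain_pct(self) -> float:
        return 100.0 * self.plain_km2 / self.total_km2 if self.total_km2 else 0.0

    @property
    def mountain_pct(self) -> float:
        return 100.0 * self.mountain_km2 / self.total_km2 if self.total_km2 else 0.0


@dataclass
class CatchmentResult:
    time_minutes: np.ndarray
    slope_pct: np.ndarray
    entries: dict[float, IsochroneEntry] = field(default_factory=dict)


def isochrone_stats(time_raster: np.ndarray, slope_raster: np.ndarray,
                    minutes: float, slope_threshold_pct: float,
                    cell_size: float) -> IsochroneEntry:
    """Reachable area within ``minutes``, split at the slope threshold."""
    if minutes <= 0:
        raise CatchmentError("isochrone time must be > 0")
    mask = time_raster <= minutes
    cell_km2 = (cell_size / 1000.0) ** 2
    slope = np.where(np.isnan(slope_raster), 0.0, slope_raster)
    plain = mask & (slope <= slope_threshold_pct)
    return IsochroneEntry(
        minutes=minutes,
        mask=mask,
        total_km2=float(mask.sum() * cell_km2),
        plain_km2=float(plain.sum() * cell_km2),
        mountain_km2=float((mask & ~plain).sum() * cell_km2),
    )


def catchment_analysis(dem: DEMRaster, origin: tuple[int, int],
                       times_minutes: tuple[float, ...] = (72.0, 129.0),
                       slope_threshold_pct: float = 30.0,
                       hiking: HikingParameters | None = None,
                       neighborhood: int = 16) -> CatchmentResult:
    t = travel_time(dem, origin, hiking, neighborhood)
    s = slope_percent(dem)
    result = CatchmentResult(time_minutes=t, slope_pct=s)
    for m in times_minutes:
        result.entries[m] = isochrone_stats(t, s, m, slope_threshold_pct,
                                            dem.cell_size)
    return result


def travel_time_bruteforce(dem: DEMRaster, origin: tuple[int, int],
                           hiking: HikingParameters | None = None,
                           neighborhood: int = 8) -> np.ndarray:
    """All-simple-paths enumeration; oracle for tiny grids (<= ~16 cells)."""
    hiking = hiking or HikingParameters()
    nrows, ncols = dem.shape
    if nrows * ncols > 16:
        raise CatchmentError("brute force limited to grids of <= 16 cells")
    moves = {8: _MOVES_8, 16: _MOVES_16}[neighborhood]
    blocked = dem.blocked()
    z = dem.elevation
    cs = dem.cell_size
    best = np.full(dem.shape, np.inf)
    best[origin] = 0.0

    def rec(r: int, c: int, t: float, visited: set) -> None:
        for dr, dc in moves:
            nr, nc = r + dr, c + dc
            if not _step_allowed(blocked, r, c, dr, dc):
                continue
            if (nr, nc) in visited:
                continue
            dist = math.hypot(dr, dc) * cs
            v = hiking.speed((z[nr, nc] - z[r, c]) / dist)
            nt = t + (dist / 1000.0) / v * 60.0
            if nt < best[nr, nc]:
                best[nr, nc] = nt
            rec(nr, nc, nt, visited | {(nr, nc)})

    rec(*origin, 0.0, {origin})
    return best
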