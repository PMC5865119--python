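"""From raw GPS fixes and a habitat raster to per-animal use records.

Implements the preprocessing chain for third-order (within-home-range)
habitat selection: fix-quality and seasonal filtering, minimum convex
polygon home ranges, availability compositions from raster cell counts,
habitat use counts, and Schoener's ratio as a temporal-independence
check.

Fixes are handled as pandas DataFrames with columns
``animal_id, site, timestamp, x, y, pdop`` (projected coordinates in
metres).  Rasters are categorical 10 m grids read from Esri ASCII files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from .simplex_core import HABITATS, Composition, drop_category_renormalize

logger = logging.getLogger("triselect")

FIX_COLUMNS = ["animal_id", "site", "timestamp", "x", "y", "pdop"]

#: default integer raster codes
DEFAULT_CODE_MAP: dict[int, str] = {1: "shrub", 2: "pole", 3: "cws", 4: "grassland"}

#: GPS quality cutoff: fixes with positional dilution of precision at or
#: above this are discarded
PDOP_MAX = 5.0

#: seasonal window (month, day), inclusive: late gestation through the rut
SEASON_WINDOW = ((4, 1), (8, 31))


@dataclass
class HabitatRaster:
    """Categorical habitat grid.

    ``codes`` has shape (nrows, ncols) with row 0 at the *south* edge so
    that indices grow with the coordinates; ``origin`` is the lower-left
    corner.  ``code_map`` maps integer cell values to habitat labels;
    ``nodata`` cells carry no habitat.
    """

    origin: tuple[float, float]
    cell_size: float
    codes: np.ndarray
    code_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CODE_MAP))
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("raster codes must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        known = set(self.code_map) | {self.nodata}
        present = set(np.unique(self.codes).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"raster contains unmapped codes: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of all cell centers as (xs, ys) 2-D arrays."""
        nrows, ncols = self.codes.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) with half-open cells; also a validity mask."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        nrows, ncols = self.codes.shape
        inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
        return row, col, inside

    def habitat_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Habitat label per coordinate; None outside the extent or on nodata."""
        row, col, inside = self.cell_index(x, y)
        out = np.full(np.shape(row), None, dtype=object)
        codes = self.codes[row[inside], col[inside]]
        out[inside] = [self.code_map.get(int(c)) for c in codes]
        return out


@dataclass(frozen=True)
class HomeRange:
    """A home-range polygon for one animal."""

    animal_id: str
    polygon: Polygon
    method: str = "mcp"
    level: float = 100.0

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("home-range polygon must be simple with positive area")


@dataclass(frozen=True)
class UseCounts:
    """Relocation counts per habitat for one animal, with exclusion tallies."""

    n: np.ndarray            # counts in (shrub, pole, cws) order
    n_outside: int           # fixes outside the raster extent
    n_dropped: int           # fixes in grassland or nodata cells

    @property
    def N(self) -> int:
        return int(self.n.sum())


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_fixes(
    fixes: pd.DataFrame,
    pdop_max: float = PDOP_MAX,
    window: tuple[tuple[int, int], tuple[int, int]] = SEASON_WINDOW,
) -> pd.DataFrame:
    """Retain fixes with PDOP strictly below ``pdop_max`` and inside the
    seasonal window (month-day comparison, so multi-year collars contribute
    every season).  Order is preserved; the result may be empty."""
    if fixes.empty:
        return fixes.copy()
    ts = pd.to_datetime(fixes["timestamp"])
    monthday = ts.dt.month * 100 + ts.dt.day
    (m0, d0), (m1, d1) = window
    in_season = (monthday >= m0 * 100 + d0) & (monthday <= m1 * 100 + d1)
    good = (fixes["pdop"] < pdop_max) & in_season
    return fixes.loc[good].copy()


# ---------------------------------------------------------------------------
# Home range
# ---------------------------------------------------------------------------

def estimate_home_range(
    fixes: pd.DataFrame,
    method: str = "mcp",
    level: float = 100.0,
    animal_id: str | None = None,
) -> HomeRange:
    """Minimum convex polygon home range.

    The (100 - level)% of fixes farthest from the centroid are discarded
    before taking the convex hull — the standard MCP estimator.  The
    availability model downstream treats the resulting polygon as fixed
    and known.
    """
    if method != "mcp":
        raise ValueError(f"unknown home-range method {method!r}")
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need at least 3 distinct fixes for a home range")
    if not 0 < level <= 100:
        raise ValueError("level must be in (0, 100]")
    if level < 100:
        centroid = pts.mean(axis=0)
        dist = np.linalg.norm(pts - centroid, axis=1)
        n_keep = max(3, int(np.floor(len(pts) * level / 100 + 1e-9)))
        keep = np.argsort(dist, kind="stable")[:n_keep]
        pts = pts[keep]
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("fixes are collinear; convex hull is degenerate")
    if animal_id is None:
        ids = fixes["animal_id"].unique()
        animal_id = str(ids[0]) if len(ids) == 1 else "unknown"
    return HomeRange(animal_id=animal_id, polygon=hull, method=method, level=level)


# ---------------------------------------------------------------------------
# Availability and use
# ---------------------------------------------------------------------------

def availability_composition(hr: HomeRange, raster: HabitatRaster) -> Composition:
    """Availability proportions from raster cells whose centers fall in the
    home range (boundary inclusive), grassland and nodata dropped and the
    remaining three types re-closed."""
    xs, ys = raster.cell_centers()
    inside = shapely.intersects_xy(hr.polygon, xs.ravel(), ys.ravel())
    if not inside.any():
        raise ValueError("no raster cell center falls inside the home range")
    codes = raster.codes.ravel()[inside]
    tally = {label: 0 for label in (*HABITATS, "grassland")}
    for code, count in zip(*np.unique(codes, return_counts=True)):
        label = raster.code_map.get(int(code))
        if label is not None:
            tally[label] += int(count)
    if sum(tally[h] for h in HABITATS) == 0:
        raise ValueError("home range contains only grassland/nodata cells")
    return drop_category_renormalize(
        [tally["grassland"], tally["shrub"], tally["pole"], tally["cws"]]
    )


def use_counts(fixes: pd.DataFrame, raster: HabitatRaster) -> UseCounts:
    """Tally relocations per habitat type.

    Each fix is assigned the habitat of its containing cell (half-open cell
    intervals).  Fixes outside the raster or on grassland/nodata cells are
    excluded from both the counts and the total, and reported in the log.
    """
    hab = raster.habitat_at(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    n_outside = 0
    n_dropped = 0
    counts = dict.fromkeys(HABITATS, 0)
    row_valid = raster.cell_index(fixes["x"].to_numpy(), fixes["y"].to_numpy())[2]
    for label, inside in zip(hab, row_valid):
        if not inside:
            n_outside += 1
        elif label in counts:
            counts[label] += 1
        else:  # grassland or nodata
            n_dropped += 1
    if n_outside or n_dropped:
        logger.info(
            "use_counts: excluded %d fixes outside raster, %d on grassland/nodata",
            n_outside, n_dropped,
        )
    return UseCounts(
        n=np.array([counts[h] for h in HABITATS], dtype=int),
        n_outside=n_outside,
        n_dropped=n_dropped,
    )


def schoener_ratio(fixes: pd.DataFrame) -> float:
    """Schoener's ratio t^2 / r^2 of temporal independence.

    t^2 is the mean squared distance between temporally successive fixes
    (n - 1 pairs), r^2 the mean squared distance from the (population)
    centroid.  Independent fixes give a ratio near 2; strong temporal
    autocorrelation pushes it toward 0.
    """
    if len(fixes) < 3:
        raise ValueError("need at least 3 fixes")
    df = fixes.sort_values("timestamp", kind="stable")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    centroid = pts.mean(axis=0)
    r2 = float(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if r2 == 0:
        raise ValueError("all fixes coincide; Schoener's ratio undefined")
    steps = np.diff(pts, axis=0)
    t2 = float(np.mean(np.sum(steps**2, axis=1)))
    return t2 / r2


def prepare_use_records(
    fixes: pd.DataFrame,
    raster: HabitatRaster,
    pdop_max: float = PDOP_MAX,
    level: float = 100.0,
) -> pd.DataFrame:
    """Full preprocessing chain: filter fixes, estimate each animal's MCP,
    derive availability and use, and return a use-record table in the
    model's CSV schema (site, animal_id, n_*, d_*)."""
    kept = filter_fixes(fixes, pdop_max=pdop_max)
    rows = []
    for (site, animal), grp in kept.groupby(["site", "animal_id"], sort=True):
        hr = estimate_home_range(grp, level=level, animal_id=str(animal))
        d = availability_composition(hr, raster)
        uc = use_counts(grp, raster)
        if uc.N == 0:
            logger.warning("animal %s has no usable fixes; skipped", animal)
            continue
        rows.append(
            dict(
                site=site, animal_id=animal,
                n_shrub=int(uc.n[0]), n_pole=int(uc.n[1]), n_cws=int(uc.n[2]),
                d_shrub=d.p_shrub, d_pole=d.p_pole, d_cws=d.p_cws,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["site", "animal_id", "n_shrub", "n_pole", "n_cws",
                 "d_shrub", "d_pole", "d_cws"],
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fixes(path) -> pd.DataFrame:
    """Read a GPS fix table (animal_id, site, timestamp, x, y, pdop)."""
    df = pd.read_csv(path, comment="#")
    missing = set(FIX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in fix table")
    if (df["pdop"] < 0).any():
        raise ValueError("negative PDOP in fix table")
    return df[FIX_COLUMNS]


def write_fixes(df: pd.DataFrame, path) -> None:
    df[FIX_COLUMNS].to_csv(path, index=False)


def read_ascii_grid(
    path,
    code_map: Mapping[int, str] | None = None,
) -> HabitatRaster:
    """Read an Esri ASCII grid of integer habitat codes."""
    header: dict[str, float] = {}
    data_lines = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            } and len(parts) == 2:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    grid = np.loadtxt(data_lines, dtype=int)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return HabitatRaster(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        codes=np.flipud(grid),  # file stores the top row first
        code_map=dict(code_map or DEFAULT_CODE_MAP),
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(raster: HabitatRaster, path) -> None:
    nrows, ncols = raster.codes.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]}\n")
        fh.write(f"yllcorner {raster.origin[1]}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, np.flipud(raster.codes), fmt="%d")


def write_home_ranges(home_ranges: list[HomeRange], path) -> None:
    """Export home ranges as one WKT polygon per animal."""
    df = pd.DataFrame(
        dict(
            animal_id=[hr.animal_id for hr in home_ranges],
            method=[hr.method for hr in home_ranges],
            level=[hr.level for hr in home_ranges],
            wkt=[hr.polygon.wkt for hr in home_ranges],
        )
    )
    df.to_csv(path, index=False)
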