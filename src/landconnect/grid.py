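"""Grid data model, raster/vector I/O, focal scaling, and spatial screening.

All spatial surfaces in an analysis (predictors, suitability, resistance,
kernels, corridor strength) are carried by :class:`Grid`: a single-band,
square-cell raster in a projected metric CRS, with NaN as nodata.  Grids in
one analysis must share geometry exactly (shape, cell size, origin).

Rasters are stored on disk as ESRI ASCII grids (``.asc``), a plain-text
format readable by every GIS.  Points travel as CSV, polygons as GeoJSON.

Coordinate convention: origin is the upper-left corner of the upper-left
cell, rows increase downward (row-major), and the centre of cell
``(row, col)`` is at ``(x0 + (col + 0.5) * cell_size,
y0 - (row + 0.5) * cell_size)``.  All distances are in meters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Grid",
    "Stack",
    "OccurrenceSet",
    "MoranResult",
    "read_raster",
    "write_raster",
    "focal_mean_circular",
    "pearson_screen",
    "morans_i",
    "morans_i_from_weights",
    "euclidean_distance",
]

ASCII_NODATA = -9999.0


@dataclass
class Grid:
    """Single-band raster with square cells; NaN marks nodata.

    Parameters
    ----------
    values : 2-D float array
    cell_size : cell edge length in meters (> 0)
    origin : (x, y) of the upper-left corner of the raster
    crs : free-form metadata string naming the projected CRS (optional)
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"grid values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def assert_same_geometry(self, other: "Grid", what: str = "grid") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"geometry mismatch for {what}: "
                f"{self.shape}@{self.cell_size}m origin {self.origin} vs "
                f"{other.shape}@{other.cell_size}m origin {other.origin}"
            )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape = grid shape."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid bounds")
        return row, col

    def xy_of(self, row: int, col: int) -> tuple[float, float]:
        """Centre coordinates of cell (row, col)."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        return Grid(
            values=self.values.copy() if values is None else np.asarray(values, float),
            cell_size=self.cell_size,
            origin=self.origin,
            crs=self.crs,
        )


class Stack(Mapping):
    """Ordered mapping of variable name -> Grid, all sharing geometry."""

    def __init__(self, grids: Mapping[str, Grid]):
        if not grids:
            raise ValueError("empty stack")
        self._grids = dict(grids)
        first = next(iter(self._grids.values()))
        for name, g in self._grids.items():
            first.assert_same_geometry(g, what=f"stack variable '{name}'")

    def __getitem__(self, name: str) -> Grid:
        return self._grids[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    @property
    def names(self) -> list[str]:
        return list(self._grids)

    @property
    def geometry(self) -> Grid:
        return next(iter(self._grids.values()))

    def array(self) -> np.ndarray:
        """(n_vars, n_rows, n_cols) array of values."""
        return np.stack([g.values for g in self._grids.values()])

    def subset(self, names: Sequence[str]) -> "Stack":
        return Stack({n: self._grids[n] for n in names})

    def valid_mask(self) -> np.ndarray:
        """Cells where every variable holds data."""
        return np.all(np.isfinite(self.array()), axis=0)


@dataclass
class OccurrenceSet:
    """Species occurrence points with a source class per record.

    ``xy`` is an (n, 2) array of projected coordinates; ``source_class``
    labels the record origin (e.g. den / scat / sighting).  ``partitions``
    holds per-replicate (train_idx, test_idx) bookkeeping filled in by the
    model-fitting stage.
    """

    xy: np.ndarray
    source_class: np.ndarray | None = None
    partitions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.source_class is None:
            self.source_class = np.array(["occurrence"] * len(self.xy))
        else:
            self.source_class = np.asarray(self.source_class)
            if len(self.source_class) != len(self.xy):
                raise ValueError("source_class length does not match points")

    @property
    def n(self) -> int:
        return len(self.xy)

    def cells(self, grid: Grid) -> np.ndarray:
        """(n, 2) array of (row, col) grid indices of the points."""
        return np.array([grid.index_of(x, y) for x, y in self.xy], dtype=int)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"x": self.xy[:, 0], "y": self.xy[:, 1], "class": self.source_class}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        cls_col = df["class"] if "class" in df else None
        return cls(df[["x", "y"]].to_numpy(), None if cls_col is None else cls_col.to_numpy())


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_raster(grid: Grid, path: str | Path) -> None:
    """Write a Grid as an ESRI ASCII grid (text) with full float precision."""
    path = Path(path)
    vals = np.where(grid.mask, grid.values, ASCII_NODATA)
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {ASCII_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")


def read_raster(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid.  Rejects the non-square-cell dx/dy dialect."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(8):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        if "dx" in header or "dy" in header:
            raise ValueError(
                f"{path}: non-square cells (dx/dy header) are not supported; "
                "resample to square cells first"
            )
        for key in ("ncols", "nrows", "cellsize"):
            if key not in header:
                raise ValueError(f"{path}: missing '{key}' in ASCII grid header")
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", ASCII_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    cs = header["cellsize"]
    x0 = header.get("xllcorner", 0.0)
    y0 = header.get("yllcorner", 0.0) + n_rows * cs
    return Grid(values=vals, cell_size=cs, origin=(x0, y0))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Focal (moving-window) scaling
# ---------------------------------------------------------------------------

def circular_footprint(radius: float, cell_size: float) -> np.ndarray:
    """Boolean window of cells whose centres lie within ``radius`` of the
    focal cell centre."""
    k = int(np.floor(radius / cell_size))
    off = np.arange(-k, k + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    return (dr ** 2 + dc ** 2) * cell_size ** 2 <= radius ** 2 + 1e-9


def focal_mean_circular(grid: Grid, radius: float) -> Grid:
    """Mean within a circular neighbourhood of ``radius`` meters.

    Membership is by cell-centre distance <= radius.  Nodata cells are
    ignored and windows shrink at edges (mean of the available cells), so a
    constant field stays exactly constant.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius < grid.cell_size / 2:
        warnings.warn(
            f"focal radius {radius} m is below half a cell "
            f"({grid.cell_size / 2} m); returning the input unchanged"
        )
        return grid.copy()
    fp = circular_footprint(radius, grid.cell_size).astype(float)
    valid = grid.mask.astype(float)
    filled = np.where(grid.mask, grid.values, 0.0)
    num = ndimage.convolve(filled, fp, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, fp, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~grid.mask] = np.nan
    return grid.copy(values=out)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def pearson_screen(
    stack: Stack, threshold: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Greedy removal of collinear variables at |r| > threshold.

    While any pair exceeds the threshold, the pair with the largest |r| is
    found and the member with the larger mean absolute correlation to all
    other variables is dropped (ties: the later variable in stack order).
    Zero-variance variables have undefined correlations; they are flagged
    with a warning and retained (their r is treated as 0).

    Returns the retained variable names and the full correlation matrix.
    """
    names = stack.names
    if len(names) < 2:
        return list(names), pd.DataFrame(np.ones((len(names),) * 2), index=names, columns=names)
    arr = stack.array()
    valid = stack.valid_mask()
    if valid.sum() < 3:
        raise ValueError("need at least 3 jointly valid cells to screen")
    X = arr[:, valid]  # (k, n)
    sd = X.std(axis=1)
    degenerate = sd == 0
    for name, bad in zip(names, degenerate):
        if bad:
            warnings.warn(
                f"variable '{name}' has zero variance; correlation undefined, retained"
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=names, columns=names)

    keep = list(range(len(names)))
    while True:
        sub = np.abs(corr[np.ix_(keep, keep)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        # mean |r| of each member to all other retained variables
        mean_i = sub[i_loc].sum() / (len(keep) - 1)
        mean_j = sub[j_loc].sum() / (len(keep) - 1)
        drop_loc = j_loc if mean_j >= mean_i else i_loc
        # tie or worse goes to the later variable in stack order
        if mean_i == mean_j:
            drop_loc = max(i_loc, j_loc)
        keep.pop(drop_loc)
    return [names[i] for i in keep], corr_df


# ---------------------------------------------------------------------------
# Spatial autocorrelation (global Moran's I)
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    z_score: float
    n: int
    status: str = "ok"  # "ok" | "degenerate"


def morans_i_from_weights(values: np.ndarray, weights: np.ndarray) -> MoranResult:
    """Global Moran's I for an explicit weight matrix.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with z = x - mean,
    w_ii ignored.  The z-score uses the normality-assumption variance with
    E[I] = -1/(n-1).  A zero-variance value vector yields status
    "degenerate" (I undefined) rather than an exception.
    """
    x = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).copy()
    n = len(x)
    if w.shape != (n, n):
        raise ValueError("weight matrix shape does not match values")
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        return MoranResult(I=np.nan, z_score=np.nan, n=n, status="degenerate")
    s0 = w.sum()
    I = (n / s0) * (z @ w @ z) / denom
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var_i = (n ** 2 * s1 - n * s2 + 3 * s0 ** 2) / ((n ** 2 - 1) * s0 ** 2) - e_i ** 2
    zsc = (I - e_i) / np.sqrt(var_i) if var_i > 0 else np.nan
    return MoranResult(I=I, z_score=zsc, n=n, status="ok")


def morans_i(
    points: OccurrenceSet, geometry: Grid, aggregation_cell: float
) -> MoranResult:
    """Global Moran's I of occurrence intensity.

    Points are binned to counts over square aggregation cells of side
    ``aggregation_cell`` meters laid over the grid extent; the statistic is
    computed on counts of the *occupied* cells with inverse-distance weights
    w_ij = 1 / d_ij between occupied-cell centres.
    """
    if aggregation_cell <= 0:
        raise ValueError("aggregation_cell must be > 0")
    x0, y0 = geometry.origin
    xs = points.xy[:, 0]
    ys = points.xy[:, 1]
    ci = np.floor((xs - x0) / aggregation_cell).astype(int)
    ri = np.floor((y0 - ys) / aggregation_cell).astype(int)
    cells, counts = np.unique(np.stack([ri, ci], axis=1), axis=0, return_counts=True)
    if len(cells) < 2:
        raise ValueError("need at least 2 occupied aggregation cells")
    cx = x0 + (cells[:, 1] + 0.5) * aggregation_cell
    cy = y0 - (cells[:, 0] + 0.5) * aggregation_cell
    d = np.hypot(cx[:, None] - cx[None, :], cy[:, None] - cy[None, :])
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return morans_i_from_weights(counts.astype(float), w)


# ---------------------------------------------------------------------------
# Euclidean distance to features
# ---------------------------------------------------------------------------

def euclidean_distance(features: Grid) -> Grid:
    """Per-cell distance (meters) from the cell centre to the nearest
    feature-cell centre of a rasterized binary feature layer."""
    feat = features.values == 1
    if not feat.any():
        raise ValueError("no feature cells in layer")
    dist = ndimage.distance_transform_edt(~feat, sampling=features.cell_size)
    out = np.where(features.mask, dist, np.nan)
    return features.copy(values=out)
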