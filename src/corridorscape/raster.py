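"""Gridded raster data model and shared spatial primitives.

A :class:`RasterGrid` is a single-band, north-up, row-major grid with
cell-center semantics: row 0 is the northernmost row, column 0 the
westernmost, and all distances are measured center-to-center in km.
This module also provides the raster I/O (ESRI ASCII grid and TIFF),
Euclidean distance surfaces, resampling/alignment, and the Pearson
collinearity screen applied to covariate stacks before model fitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RasterGrid",
    "CovariateStack",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "euclidean_distance_surface",
    "align_and_resample",
    "collinearity_filter",
]

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Raised when a raster file does not parse under its declared format."""


@dataclass
class RasterGrid:
    """Single-band gridded surface.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; cells equal to ``nodata`` are treated as missing.
    cellsize : float
        Cell edge length in km; must be positive.
    origin : tuple of float
        ``(x, y)`` of the grid's upper-left *corner*.
    nodata : float
        Sentinel marking missing cells.
    """

    values: np.ndarray
    cellsize: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if not self.cellsize > 0:
            raise ValueError(f"cellsize must be > 0, got {self.cellsize}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata cells (NaN also counts as missing)."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centers, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin[0] + (cols + 0.5) * self.cellsize
        y = self.origin[1] - (rows + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + (col + 0.5) * self.cellsize,
            self.origin[1] - (row + 0.5) * self.cellsize,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cellsize))
        row = int(np.floor((self.origin[1] - y) / self.cellsize))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.index_of(x, y)
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's geometry with different values."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class CovariateStack:
    """Named, pairwise-aligned set of covariate grids.

    Invariant: all grids share shape, cellsize and origin; names are unique.
    """

    names: list[str] = field(default_factory=list)
    grids: dict[str, RasterGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("covariate names must be unique")
        if set(self.names) != set(self.grids):
            raise ValueError("names and grids keys must match")
        ref = self.grids[self.names[0]] if self.names else None
        for name in self.names:
            if not self.grids[name].aligned_with(ref):
                raise ValueError(f"covariate {name!r} is not aligned with {self.names[0]!r}")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    @property
    def template(self) -> RasterGrid:
        return self.grids[self.names[0]]

    def add(self, name: str, grid: RasterGrid) -> None:
        if name in self.grids:
            raise ValueError(f"duplicate covariate name {name!r}")
        if self.names and not grid.aligned_with(self.template):
            raise ValueError(f"grid {name!r} not aligned with stack")
        self.names.append(name)
        self.grids[name] = grid

    def subset(self, names: list[str]) -> "CovariateStack":
        return CovariateStack(names=list(names), grids={n: self.grids[n] for n in names})

    def joint_valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.template.shape, dtype=bool)
        for name in self.names:
            mask &= self.grids[name].valid_mask()
        return mask

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack values at masked cells into an (n_cells, n_covariates) matrix."""
        if mask is None:
            mask = self.joint_valid_mask()
        return np.column_stack([self.grids[n].values[mask] for n in self.names])

    def rows_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Covariate matrix for explicit cell indices."""
        return np.column_stack([self.grids[n].values[rows, cols] for n in self.names])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii_grid(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS + ("nodata_value",):
                try:
                    header[key] = float(tokens[1])
                except (IndexError, ValueError) as exc:
                    raise RasterFormatError(
                        f"{path}: malformed header line for {key!r}: {line.rstrip()!r}"
                    ) from exc
            else:
                data_lines.append(line)
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path}: missing required header field {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    try:
        flat = np.array(" ".join(data_lines).split(), dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value in data block") from exc
    if flat.size != nrows * ncols:
        raise RasterFormatError(
            f"{path}: data block has {flat.size} values, header nrows*ncols={nrows * ncols}"
        )
    values = flat.reshape(nrows, ncols)
    cellsize = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cellsize)
    return RasterGrid(values=values, cellsize=cellsize, origin=origin, nodata=nodata)


def _write_ascii_grid(grid: RasterGrid, path: Path) -> None:
    yll = grid.origin[1] - grid.nrows * grid.cellsize
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_tiff(path: Path) -> RasterGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = {}
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterFormatError(f"{path}: not a readable TIFF: {exc}") from exc
    if values.ndim != 2:
        raise RasterFormatError(f"{path}: expected single-band 2-D TIFF, got shape {values.shape}")
    return RasterGrid(
        values=np.asarray(values, dtype=float),
        cellsize=float(meta.get("cellsize", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=float(meta.get("nodata", DEFAULT_NODATA)),
    )


def _write_tiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    meta = {"cellsize": grid.cellsize, "origin": list(grid.origin), "nodata": grid.nodata}
    tifffile.imwrite(path, grid.values.astype(np.float64), description=json.dumps(meta))


_FORMATS = {
    "ascii-grid": (_read_ascii_grid, _write_ascii_grid),
    "geotiff": (_read_tiff, _write_tiff),
}


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported raster format {fmt!r}; choose from {sorted(_FORMATS)}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    return "ascii-grid"


def read_raster(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read a raster file; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    return _FORMATS[fmt][0](path)


def write_raster(grid: RasterGrid, path: str | Path, format: str | None = None) -> Path:
    """Write a raster file; ASCII grids round-trip bitwise (repr precision)."""
    path = Path(path)
    fmt = _resolve_format(path, format)
    _FORMATS[fmt][1](grid, path)
    return path


# ---------------------------------------------------------------------------
# Distance surfaces
# ---------------------------------------------------------------------------


def euclidean_distance_surface(mask: RasterGrid) -> RasterGrid:
    """Distance (km, center-to-center) from every cell to the nearest true cell.

    The source ``mask`` is a binary grid; cells with value > 0 are sources and
    receive distance 0. Exact Euclidean distances, not a chamfer approximation.
    """
    src = mask.values > 0
    if not src.any():
        raise ValueError("distance surface requires at least one true cell in the mask")
    rows, cols = np.nonzero(src)
    tree = cKDTree(np.column_stack([rows, cols]).astype(float))
    rr, cc = np.meshgrid(np.arange(mask.nrows), np.arange(mask.ncols), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = tree.query(pts)
    values = dist.reshape(mask.shape) * mask.cellsize
    return mask.copy_with(values)


# ---------------------------------------------------------------------------
# Alignment / resampling
# ---------------------------------------------------------------------------


def align_and_resample(grid: RasterGrid, target: RasterGrid, rule: str = "mean") -> RasterGrid:
    """Resample ``grid`` onto the geometry of ``target``.

    ``mean`` bins source cell centers into target cells and averages the
    non-nodata contributors (requires target cellsize >= source cellsize);
    ``nearest`` samples the source cell containing each target center.
    """
    if rule not in ("mean", "nearest"):
        raise ValueError(f"unknown resampling rule {rule!r}")
    sx0, sy0 = grid.origin
    tx0, ty0 = target.origin
    s_xmax = sx0 + grid.ncols * grid.cellsize
    s_ymin = sy0 - grid.nrows * grid.cellsize
    t_xmax = tx0 + target.ncols * target.cellsize
    t_ymin = ty0 - target.nrows * target.cellsize
    if s_xmax <= tx0 or t_xmax <= sx0 or sy0 <= t_ymin or ty0 <= s_ymin:
        raise ValueError("source and target extents are disjoint")

    out = np.full(target.shape, target.nodata, dtype=float)
    if rule == "mean":
        if target.cellsize < grid.cellsize - 1e-12:
            raise ValueError("mean rule requires target cellsize >= source cellsize")
        xs, ys = grid.cell_centers()
        valid = grid.valid_mask()
        tc = np.floor((xs - tx0) / target.cellsize).astype(int)
        tr = np.floor((ty0 - ys) / target.cellsize).astype(int)
        inside = (tr >= 0) & (tr < target.nrows) & (tc >= 0) & (tc < target.ncols) & valid
        flat = tr[inside] * target.ncols + tc[inside]
        sums = np.bincount(flat, weights=grid.values[inside], minlength=target.nrows * target.ncols)
        counts = np.bincount(flat, minlength=target.nrows * target.ncols)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        out_flat = out.ravel()
        out_flat[counts > 0] = means[counts > 0]
        out = out_flat.reshape(target.shape)
    else:  # nearest
        xs, ys = target.cell_centers()
        sc = np.floor((xs - sx0) / grid.cellsize).astype(int)
        sr = np.floor((sy0 - ys) / grid.cellsize).astype(int)
        inside = (sr >= 0) & (sr < grid.nrows) & (sc >= 0) & (sc < grid.ncols)
        out[inside] = grid.values[sr[inside], sc[inside]]
    return RasterGrid(out, cellsize=target.cellsize, origin=target.origin, nodata=target.nodata)


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation with zero-variance columns mapped to r = 0."""
    std = X.std(axis=0)
    degenerate = std == 0
    Xc = X - X.mean(axis=0)
    safe_std = np.where(degenerate, 1.0, std)
    Z = Xc / safe_std
    r = (Z.T @ Z) / X.shape[0]
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def collinearity_filter(
    stack: CovariateStack, threshold: float = 0.7
) -> tuple[CovariateStack, list[str], np.ndarray]:
    """Drop covariates until every retained pair has |r| <= ``threshold``.

    Pairs are scanned in listed order; the later-listed member of an offending
    pair is dropped (so e.g. a ruggedness layer listed after the slope layer it
    duplicates is the one removed). Correlations are computed over cells valid
    in *all* layers. Returns the filtered stack, the dropped names, and the
    full correlation matrix in the original layer order.
    """
    if len(stack) < 2:
        raise ValueError("collinearity filter requires at least 2 covariates")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    X = stack.to_matrix()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 jointly valid cells to compute correlations")
    r = _pearson_matrix(X)
    if (X.std(axis=0) == 0).any():
        degen = [stack.names[i] for i in np.nonzero(X.std(axis=0) == 0)[0]]
        warnings.warn(f"zero-variance covariates (r defined as 0): {degen}", stacklevel=2)

    keep = list(range(len(stack.names)))
    dropped: list[str] = []
    i = 0
    while i < len(keep):
        j = i + 1
        while j < len(keep):
            if abs(r[keep[i], keep[j]]) > threshold:
                dropped.append(stack.names[keep[j]])
                del keep[j]
            else:
                j += 1
        i += 1
    retained = [stack.names[k] for k in keep]
    return stack.subset(retained), dropped, r
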