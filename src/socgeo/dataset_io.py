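"""Sample-table and raster I/O.

The pipeline's tabular interchange format is a long-format CSV with one
row per location x depth layer, holding planar coordinates in metres,
the SOC concentration (g kg^-1), the coarse-fragment ("stones") mass
percentage, the fine-earth texture fractions (sand/silt/clay, %) and the
bulk density (g cm^-3).  Kriged surfaces are written as ESRI ASCII grids
so any GIS can render them.

Coordinates are planar metres with the origin at the south-west corner
of the survey area; y increases northward.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: Ordered depth-layer labels (cm intervals), shallowest first.
LAYERS = ("0-10", "10-20", "20-30", "30-40")

#: Layer thickness in cm (all layers are 10 cm).
LAYER_THICKNESS_CM = 10.0

#: Canonical column names of a sample table, in writing order.
SAMPLE_COLUMNS = (
    "location_id",
    "x",
    "y",
    "layer",
    "soc",
    "stones",
    "sand",
    "silt",
    "clay",
    "bd",
)

_NUMERIC_COLUMNS = ("x", "y", "soc", "stones", "sand", "silt", "clay", "bd")

#: Tolerance on sand+silt+clay exceeding 100 % (rounding slack).
TEXTURE_SUM_TOL = 0.5


@dataclass(frozen=True)
class LocationGrid:
    """A regular sampling lattice with closed (boundary-inclusive) extents.

    The default is the survey design used throughout the package: a
    5 km x 8 km area sampled every 500 m, which yields an 11 x 17
    lattice of 187 locations.
    """

    width_m: float = 5000.0
    height_m: float = 8000.0
    spacing_m: float = 500.0

    def __post_init__(self):
        if self.width_m <= 0 or self.height_m <= 0 or self.spacing_m <= 0:
            raise DimensionError("grid extents and spacing must be positive")

    @property
    def nx(self) -> int:
        return int(np.floor(self.width_m / self.spacing_m + 1e-9)) + 1

    @property
    def ny(self) -> int:
        return int(np.floor(self.height_m / self.spacing_m + 1e-9)) + 1

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def coords(self) -> np.ndarray:
        """(n, 2) array of node coordinates, row-by-row from south to north."""
        xs = np.arange(self.nx) * self.spacing_m
        ys = np.arange(self.ny) * self.spacing_m
        xx, yy = np.meshgrid(xs, ys)  # yy varies along rows (south -> north)
        return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    def location_ids(self) -> list[str]:
        width = max(3, len(str(self.n_nodes)))
        return [f"L{i + 1:0{width}d}" for i in range(self.n_nodes)]


def read_samples(
    path,
    schema: dict[str, str] | None = None,
    *,
    on_invalid: str = "raise",
    extent: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Read a long-format sample table from CSV.

    Parameters
    ----------
    path : str, Path or file-like
        CSV file with a header row.
    schema : dict, optional
        Mapping from canonical column names (:data:`SAMPLE_COLUMNS`) to
        the names used in the file.  Columns not mentioned are assumed
        to carry their canonical name.
    on_invalid : {"raise", "warn"}
        Whether out-of-range values abort reading or only emit a warning.
    extent : (width_m, height_m), optional
        If given, coordinates are validated against the closed extent.

    Returns
    -------
    pandas.DataFrame with the canonical columns, row order preserved.
    Empty cells become NaN and are excluded pairwise downstream.
    """
    schema = schema or {}
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in SAMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(missing)}"
        )

    out = raw.loc[:, list(SAMPLE_COLUMNS)].copy()
    for col in _NUMERIC_COLUMNS:
        text = out[col].astype("string")
        parsed = pd.to_numeric(text, errors="coerce")
        bad = parsed.isna() & text.notna() & (text.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {text.iloc[row]!r} in column {col!r} "
                f"at data row {row + 1}"
            )
        out[col] = parsed.astype(float)

    _validate_samples(out, on_invalid=on_invalid, extent=extent)
    return out


def _validate_samples(df: pd.DataFrame, *, on_invalid: str, extent=None) -> None:
    import warnings

    problems = []
    def check(mask, msg):
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        if np.asarray(mask).any():
            rows = np.flatnonzero(np.asarray(mask))[:5] + 1
            problems.append(f"{msg} (data rows {list(rows)})")

    check(df["soc"] <= 0, "SOC must be positive")
    check((df["stones"] < 0) | (df["stones"] > 100), "stones outside [0, 100] %")
    for col in ("sand", "silt", "clay"):
        check(df[col] < 0, f"{col} negative")
    tex = df[["sand", "silt", "clay"]].sum(axis=1, min_count=3)
    check(tex > 100 + TEXTURE_SUM_TOL, "sand+silt+clay exceeds 100 %")
    check(df["bd"] <= 0, "bulk density must be positive")
    unknown = ~df["layer"].isin(LAYERS) & df["layer"].notna()
    check(unknown, f"unknown layer label (expected one of {LAYERS})")
    if extent is not None:
        w, h = extent
        check((df["x"] < 0) | (df["x"] > w), f"x outside [0, {w}] m")
        check((df["y"] < 0) | (df["y"] > h), f"y outside [0, {h}] m")

    if problems:
        msg = "; ".join(problems)
        if on_invalid == "warn":
            warnings.warn(msg, stacklevel=3)
        else:
            raise ValidationError(msg)


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a sample table as canonical CSV (UTF-8, '.' decimal)."""
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write table lacking column(s): {missing}")
    df.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII rasters


def write_raster(
    values,
    cell_size: float,
    origin: tuple[float, float],
    path,
    *,
    nodata: float = -9999.0,
    fmt: str = "%.8g",
) -> None:
    """Write a 2-D grid as an ESRI ASCII raster (.asc).

    ``values`` is indexed ``[row, col]`` with row 0 the *southernmost*
    row (y increases with the row index, matching the package's map
    orientation); the file itself is written north-to-south as the
    format requires.  NaN cells become the declared no-data sentinel.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise DimensionError(
            f"raster values must be a non-empty 2-D grid, got shape {arr.shape}"
        )
    nrows, ncols = arr.shape
    xll, yll = origin
    body = np.where(np.isnan(arr), nodata, arr)[::-1]  # flip to north-first
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.8g}\n")
        fh.write(f"yllcorner {yll:.8g}\n")
        fh.write(f"cellsize {cell_size:.8g}\n")
        fh.write(f"NODATA_value {nodata:.8g}\n")
        for row in body:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_raster(path):
    """Read an ESRI ASCII raster written by :func:`write_raster`.

    Returns ``(values, cell_size, (xll, yll), nodata)`` with values in
    south-to-north row order and no-data cells as NaN.
    """
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"raster header missing {key}")
    body = np.loadtxt(io.StringIO("".join(lines[i:])))
    body = np.atleast_2d(body)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if body.shape != (nrows, ncols):
        raise DimensionError(
            f"raster body shape {body.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", -9999.0)
    values = body[::-1].copy()  # back to south-first
    values[values == nodata] = np.nan
    return values, header["cellsize"], (header["xllcorner"], header["yllcorner"]), nodata
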