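"""Orte-matrix and binary-mask I/O plus the two masking operations.

The orte matrix is the central currency of the pipeline: one row per
localized blink event with signal amplitude, lateral x/y coordinates in
nanometres and the localization error.  Coordinates are absolute nm in the
image frame with the origin at the top-left corner and y increasing
downward.  Masks are binary rasters (nucleus outline or damage-focus
regions) with a known pixel size and origin offset, applied to orte tables
by point-in-pixel membership.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Normative column order of the orte dialect; ``frame`` is optional.
ORTE_COLUMNS = ("amplitude", "x_nm", "y_nm", "loc_error_nm")

#: Accepted aliases for each mandatory column (case-insensitive).
_COLUMN_ALIASES = {
    "amplitude": {"amplitude", "amp", "intensity"},
    "x_nm": {"x_nm", "x"},
    "y_nm": {"y_nm", "y"},
    "loc_error_nm": {"loc_error_nm", "loc_error", "locerror", "error_nm"},
    "frame": {"frame", "frame_index", "t"},
}


class OrteSchemaError(ValueError):
    """Raised when an orte file lacks a mandatory column."""


class OrteParseError(ValueError):
    """Raised when an orte file contains non-numeric cells."""


@dataclass
class OrteMatrix:
    """Table of localized blink events for one channel.

    Parameters
    ----------
    data
        DataFrame with columns ``amplitude, x_nm, y_nm, loc_error_nm``
        and optionally ``frame``.
    channel
        Free-form channel label (e.g. dye or protein name).
    source
        Identifier of where the table came from (file path, scene id).
    """

    data: pd.DataFrame
    channel: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in ORTE_COLUMNS if c not in self.data.columns]
        if missing:
            raise OrteSchemaError(f"orte matrix missing column(s): {missing}")
        if len(self.data):
            xy = self.data[["x_nm", "y_nm"]].to_numpy(float)
            if not np.all(np.isfinite(xy)):
                raise ValueError("orte coordinates must be finite")
            if (self.data["loc_error_nm"].to_numpy(float) < 0).any():
                raise ValueError("loc_error_nm must be >= 0")
            if (self.data["amplitude"].to_numpy(float) <= 0).any():
                raise ValueError("amplitude must be > 0")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of x/y coordinates in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    def select(self, indices) -> "OrteMatrix":
        """Row subset (order preserved) as a new OrteMatrix."""
        sub = self.data.iloc[np.asarray(indices, dtype=int)].reset_index(drop=True)
        return OrteMatrix(sub, channel=self.channel, source=self.source)


@dataclass
class BinaryMask:
    """Binary raster with metric pixel size, in the orte coordinate frame.

    ``grid[i, j]`` covers the half-open square
    ``[origin_x + j*p, origin_x + (j+1)*p) x [origin_y + i*p, origin_y + (i+1)*p)``
    so every point belongs to exactly one pixel.
    """

    grid: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    kind: str = "nucleus"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-mask test; points off the grid are outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.floor((x - self.origin_nm[0]) / self.pixel_size_nm).astype(int)
        i = np.floor((y - self.origin_nm[1]) / self.pixel_size_nm).astype(int)
        ok = (i >= 0) & (i < self.grid.shape[0]) & (j >= 0) & (j < self.grid.shape[1])
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        out[ok] = self.grid[i[ok], j[ok]]
        return out


def mask_area(mask: BinaryMask) -> float:
    """Area of the inside region in square micrometres."""
    return float(mask.grid.sum()) * mask.pixel_size_nm**2 / 1e6


def apply_mask(orte: OrteMatrix, mask: BinaryMask) -> OrteMatrix:
    """Keep exactly the rows whose (x, y) falls in an inside pixel.

    Row order is preserved.  Points falling off the mask grid count as
    outside; the excluded count is logged.
    """
    if len(orte) == 0:
        return orte.select([])
    inside = mask.contains(orte.data["x_nm"], orte.data["y_nm"])
    n_out = int((~inside).sum())
    if n_out:
        logger.info("apply_mask(%s): excluded %d of %d events", mask.kind, n_out, len(orte))
    return orte.select(np.flatnonzero(inside))


def _detect_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get)


def read_orte(path, dialect: str | None = None, channel: str = "") -> OrteMatrix:
    """Read a delimited orte file.

    The delimiter is auto-detected among comma/tab/semicolon unless given.
    The header must name at least amplitude, x, y and loc_error columns
    (aliases accepted); ``frame`` is optional.  Non-numeric cells raise an
    :class:`OrteParseError` naming the first offending row.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = dialect or _detect_delimiter(header)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    rename = {}
    lower = {c.lower(): c for c in raw.columns}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
    raw = raw.rename(columns=rename)
    missing = [c for c in ORTE_COLUMNS if c not in raw.columns]
    if missing:
        raise OrteSchemaError(f"{path.name}: missing mandatory column(s) {missing}")

    keep = [c for c in (*ORTE_COLUMNS, "frame") if c in raw.columns]
    table = raw[keep]
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table.notna()
    if bad.to_numpy().any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        col = bad.columns[int(np.flatnonzero(bad.iloc[row])[0])]
        raise OrteParseError(
            f"{path.name}: non-numeric value {table.iloc[row][col]!r} "
            f"in column {col!r}, data row {row + 1}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1))[0])
        raise OrteParseError(f"{path.name}: empty cell in data row {row + 1}")
    if "frame" in numeric.columns:
        numeric["frame"] = numeric["frame"].astype(int)
    return OrteMatrix(numeric, channel=channel, source=str(path))


def write_orte(orte: OrteMatrix, path, sep: str = ",", header_comment: str | None = None) -> None:
    """Write an orte matrix in the normative CSV dialect (full precision)."""
    path = Path(path)
    cols = [c for c in (*ORTE_COLUMNS, "frame") if c in orte.data.columns]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        orte.data[cols].to_csv(fh, sep=sep, index=False, float_format="%.17g")


def write_mask(mask: BinaryMask, path) -> None:
    """Write mask as single-page TIFF (0/255) + sidecar JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255))
    meta = {
        "pixel_size_nm": mask.pixel_size_nm,
        "origin_x_nm": mask.origin_nm[0],
        "origin_y_nm": mask.origin_nm[1],
        "kind": mask.kind,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_mask(path) -> BinaryMask:
    """Read a mask TIFF (nonzero = inside) and its sidecar JSON."""
    path = Path(path)
    grid = tifffile.imread(path) != 0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    else:
        logger.warning("mask %s has no sidecar JSON; assuming 1 nm pixels", path.name)
        meta = {}
    return BinaryMask(
        grid,
        pixel_size_nm=float(meta.get("pixel_size_nm", 1.0)),
        origin_nm=(float(meta.get("origin_x_nm", 0.0)), float(meta.get("origin_y_nm", 0.0))),
        kind=str(meta.get("kind", "nucleus")),
    )
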