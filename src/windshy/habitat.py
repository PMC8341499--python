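"""Habitat-preference (GET score) raster extraction.

The Golden Eagle Topography (GET) surface scores every 50-m pixel 1-10 for
intrinsic eagle habitat preference derived from topography (6 and above is
increasingly preferred).  This module consumes such a surface — it never
derives one — and extracts:

* a single-pixel score under any planar point (tag fix or closest-pass
  location of a flight line), and
* a turbine-location score as the mode of the pixel containing the tower
  plus its four rook (edge-adjacent) neighbours, with modal ties broken
  toward the *highest* tied score (precautionary toward "preferred").

Raster I/O uses the ESRI ASCII grid format (plain text ``.asc``), which is
integer-exact and diff-friendly.  Pixels are half-open: a point on a shared
vertical edge belongs to the pixel to its east (west edge inclusive), and a
point on a shared horizontal edge to the pixel below (north edge
inclusive), so every in-extent point maps to exactly one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class GETRaster:
    """Integer habitat-score grid on a square metric lattice.

    ``data`` is row-major with row 0 at the *north* edge (the ASCII-grid
    convention).  ``xll``/``yll`` locate the south-west corner.
    """

    data: np.ndarray  # int array (nrows, ncols); nodata as NODATA value
    xll: float
    yll: float
    cellsize: float = 50.0
    nodata: int = -9999

    def __post_init__(self):
        self.data = np.asarray(self.data)
        valid = self.data[self.data != self.nodata]
        if valid.size and (valid.min() < 1 or valid.max() > 10):
            raise ValueError("GET scores must lie in 1..10 (or nodata)")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    # -- indexing ---------------------------------------------------------
    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) owning planar point (x, y); half-open cells."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x < xmax and ymin < y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = int(np.floor((x - self.xll) / self.cellsize))
        # north-edge-inclusive: a boundary y belongs to the cell whose top it is
        row_from_bottom = int(np.ceil((y - self.yll) / self.cellsize)) - 1
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def value_at(self, x: float, y: float) -> int | None:
        """Score of the containing pixel; None for nodata."""
        r, c = self.rowcol(x, y)
        v = int(self.data[r, c])
        return None if v == self.nodata else v

    def values_at(self, xs, ys) -> np.ndarray:
        """Vectorised extraction; nodata/out-of-extent come back as -1."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        xmin, ymin, xmax, ymax = self.extent
        inside = (xs >= xmin) & (xs < xmax) & (ys > ymin) & (ys <= ymax)
        col = np.floor((xs - self.xll) / self.cellsize).astype(int)
        rfb = np.ceil((ys - self.yll) / self.cellsize).astype(int) - 1
        row = self.nrows - 1 - rfb
        out = np.full(xs.shape, -1, dtype=int)
        r = np.clip(row, 0, self.nrows - 1)
        c = np.clip(col, 0, self.ncols - 1)
        vals = self.data[r, c]
        ok = inside & (vals != self.nodata)
        out[ok] = vals[ok]
        return out


def point_get_score(raster: GETRaster, x: float, y: float) -> int | None:
    """GET score of the 50-m pixel under a planar point (None for nodata)."""
    return raster.value_at(x, y)


def turbine_get_score(raster: GETRaster, turbine) -> int:
    """Modal GET score of the tower pixel and its four rook neighbours.

    Ties among equally frequent scores resolve to the highest tied score.
    Raises if any of the five pixels is outside the raster or nodata.
    """
    r, c = raster.rowcol(turbine.easting, turbine.northing)
    cells = [(r, c), (r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    vals = []
    for rr, cc in cells:
        if not (0 <= rr < raster.nrows and 0 <= cc < raster.ncols):
            raise ValueError(
                f"turbine {turbine.turbine_id}: 5-pixel neighbourhood leaves the raster"
            )
        v = int(raster.data[rr, cc])
        if v == raster.nodata:
            raise ValueError(
                f"turbine {turbine.turbine_id}: nodata in 5-pixel neighbourhood"
            )
        vals.append(v)
    return mode_highest_tie(vals)


def mode_highest_tie(values) -> int:
    """Mode of an integer multiset; ties broken by the highest tied value."""
    vals = np.asarray(values, dtype=int)
    counts = np.bincount(vals)
    best = counts.max()
    return int(np.flatnonzero(counts == best).max())


# -- ESRI ASCII grid I/O -------------------------------------------------

def read_ascii_grid(path: str | Path) -> GETRaster:
    """Read an integer ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req!r}")
    data = np.loadtxt(lines[n_header:], dtype=int)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    return GETRaster(
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=int(header.get("nodata_value", -9999)),
    )


def write_ascii_grid(raster: GETRaster, path: str | Path) -> None:
    """Write an integer ESRI ASCII grid (.asc)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:g}\n")
        fh.write(f"yllcorner {raster.yll:g}\n")
        fh.write(f"cellsize {raster.cellsize:g}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
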