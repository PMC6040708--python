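"""Resistance rasters for linear-landscape-element (LLE) networks.

A landscape is modelled as a 1-m grid of cell resistances: cells on an LLE
(field margin, ditch, hedge) get a low resistance ``R_LLE = 0.01``, a 5-m halo
around the LLE gets doubled resistance ``R_BUFFER = 0.02`` (so that gaps
shorter than 10 m between elements remain traversable at a penalty), and the
agricultural matrix is impassable (infinite resistance).  The halo rule and
the two resistance values follow the standard corridor parameterisation for
multi-generational plant migration along LLE.

Grids use the ESRI ASCII convention: x to the right, y up, origin at the
lower-left cell corner, row 0 the northernmost row.  Infinite resistance is
serialised as the NODATA value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

R_LLE = 0.01
R_BUFFER = 0.02
GAP_BUFFER_M = 5.0

#: columns of the segment-geometry table produced by :mod:`llecorridor.synth`
SEGMENT_COLUMNS = ["area_id", "x1", "y1", "x2", "y2", "width_m", "lle_type"]


@dataclass
class ResistanceRaster:
    """Grid of cell resistances; ``np.inf`` marks impassable matrix cells.

    Internal indexing is (row, col) with row 0 the northernmost row; cell
    centres are at half-cell offsets from the lower-left ``origin``.
    """

    values: np.ndarray  # (nrows, ncols) float
    cell_m: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """(x, y) of cell centres for (row, col) indices."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_m
        y = self.origin_y + (self.n_rows - np.asarray(row) - 0.5) * self.cell_m
        return x, y

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.cell_m))
        row = self.n_rows - 1 - int(np.floor((y - self.origin_y) / self.cell_m))
        return row, col

    def copy(self) -> "ResistanceRaster":
        return ResistanceRaster(
            self.values.copy(), self.cell_m, self.origin_x, self.origin_y, self.nodata
        )


def _segment_mask(raster: ResistanceRaster, x1, y1, x2, y2, width_m,
                  r_lle: float = R_LLE) -> None:
    """Mark cells whose centre is within width/2 of the segment as LLE.

    Operates in place on ``raster.values``; vectorised over the segment's
    bounding box only.
    """
    half = width_m / 2.0
    cell = raster.cell_m
    xmin, xmax = min(x1, x2) - half, max(x1, x2) + half
    ymin, ymax = min(y1, y2) - half, max(y1, y2) + half
    c0 = max(0, int(np.floor((xmin - raster.origin_x) / cell)))
    c1 = min(raster.n_cols - 1, int(np.ceil((xmax - raster.origin_x) / cell)))
    r0 = max(0, raster.n_rows - 1 - int(np.ceil((ymax - raster.origin_y) / cell)))
    r1 = min(
        raster.n_rows - 1, raster.n_rows - 1 - int(np.floor((ymin - raster.origin_y) / cell))
    )
    if c1 < c0 or r1 < r0:
        return
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cx = raster.origin_x + (cols + 0.5) * cell
    cy = raster.origin_y + (raster.n_rows - rows - 0.5) * cell
    px, py = np.meshgrid(cx, cy)
    # flat-capped rectangle: perpendicular distance <= width/2 within the
    # segment's axial span (keeps inserted gap lengths exact)
    dx, dy = x2 - x1, y2 - y1
    seg_len2 = dx * dx + dy * dy
    if seg_len2 == 0.0:
        inside = np.hypot(px - x1, py - y1) <= half
    else:
        t = ((px - x1) * dx + (py - y1) * dy) / seg_len2
        perp = np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))
        inside = (t >= 0.0) & (t <= 1.0) & (perp <= half)
    block = raster.values[r0 : r1 + 1, c0 : c1 + 1]
    block[inside] = r_lle


def rasterize_lle(
    segments: pd.DataFrame,
    cell_m: float = 1.0,
    extent: tuple[float, float, float, float] | None = None,
    buffer_m: float = 500.0,
    r_lle: float = R_LLE,
) -> ResistanceRaster:
    """Rasterise LLE segment geometry onto a resistance grid.

    Parameters
    ----------
    segments
        Table with columns ``x1, y1, x2, y2, width_m`` (one row per LLE
        centreline segment).  A cell becomes LLE (resistance 0.01) iff its
        centre lies within ``width_m / 2`` of the centreline.
    extent
        ``(xmin, ymin, xmax, ymax)`` of the grid.  If omitted, the segment
        bounding box extended by ``buffer_m`` on all sides is used, which
        guarantees the 500-m analysis frame around the mapped elements.
    """
    if extent is None:
        if len(segments) == 0:
            extent = (0.0, 0.0, cell_m, cell_m)
        else:
            xs = np.r_[segments["x1"].to_numpy(), segments["x2"].to_numpy()]
            ys = np.r_[segments["y1"].to_numpy(), segments["y2"].to_numpy()]
            extent = (
                xs.min() - buffer_m,
                ys.min() - buffer_m,
                xs.max() + buffer_m,
                ys.max() + buffer_m,
            )
    xmin, ymin, xmax, ymax = extent
    n_cols = max(1, int(np.ceil((xmax - xmin) / cell_m)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cell_m)))
    values = np.full((n_rows, n_cols), np.inf)
    raster = ResistanceRaster(values, cell_m=cell_m, origin_x=xmin, origin_y=ymin)
    if len(segments) == 0:
        warnings.warn("empty LLE geometry: all-infinite resistance raster")
        return raster
    if (segments["width_m"] <= 0).any():
        raise ValueError("LLE widths must be positive")
    for seg in segments.itertuples(index=False):
        _segment_mask(raster, seg.x1, seg.y1, seg.x2, seg.y2, seg.width_m, r_lle)
    return raster


def apply_gap_buffers(
    raster: ResistanceRaster,
    buffer_m: float = GAP_BUFFER_M,
    r_buffer: float = R_BUFFER,
    r_lle: float = R_LLE,
) -> ResistanceRaster:
    """Add the doubled-resistance halo around all LLE cells.

    Every matrix cell whose centre lies within ``buffer_m`` of the nearest
    LLE cell centre becomes ``r_buffer``; LLE cells are never overwritten.
    Two elements separated by a gap shorter than ``2 * buffer_m`` therefore
    become connected through the halo.  Idempotent: the halo is always
    recomputed from the LLE cells only.
    """
    out = raster.copy()
    lle = raster.values == r_lle
    if not lle.any():
        return out
    dist = ndimage.distance_transform_edt(~lle, sampling=raster.cell_m)
    halo = (dist <= buffer_m) & ~lle
    out.values[halo] = r_buffer
    out.values[lle] = r_lle
    return out


def write_ascii_grid(raster: ResistanceRaster, path) -> None:
    """Write an ESRI ASCII grid (.asc); infinite resistance becomes NODATA."""
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = raster.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin_x:.6f}\n")
        fh.write(f"yllcorner {raster.origin_y:.6f}\n")
        fh.write(f"cellsize {raster.cell_m:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        np.savetxt(fh, vals, fmt="%.6g")


def read_ascii_grid(path) -> ResistanceRaster:
    """Read an ESRI ASCII grid; NODATA cells become infinite resistance."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed ASCII grid header line: {line!r}")
            header[parts[0].lower()] = float(parts[1])
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"ASCII grid header missing {key}")
        nodata = header.get("nodata_value", -9999.0)
        n_cols = int(header["ncols"])
        n_rows = int(header["nrows"])
        rows = []
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            row = np.array(line.split(), dtype=float)
            if row.size != n_cols:
                raise ValueError(
                    f"row {len(rows)} has {row.size} values, expected {n_cols}"
                )
            rows.append(row)
        if len(rows) != n_rows:
            raise ValueError(f"expected {n_rows} rows, found {len(rows)}")
    values = np.vstack(rows)
    values[values == nodata] = np.inf
    return ResistanceRaster(
        values,
        cell_m=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=nodata,
    )
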