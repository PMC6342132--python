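"""Habitat-mask geometry: RPSV buffers, mask gridding, covariate
extraction, opportunistic-sample gridding, and MCP availability domains.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Polygon

from .containers import CaptureHistory, DetectorArray, MaskGrid


def compute_rpsv(history: CaptureHistory, detectors: DetectorArray) -> float:
    """Root pooled spatial variance of detections about individual centroids.

    RPSV = sqrt( sum_i sum_j ((x_ij - xbar_i)^2 + (y_ij - ybar_i)^2)
                 / (2 * (sum_i n_i - m)) )
    pooled over the m individuals with n_i >= 2 detections; individuals
    detected once carry no information about movement and are excluded.
    Three times this value is the conventional mask buffer.
    """
    dev = 0.0
    n_tot = 0
    m = 0
    for i in range(history.n_individuals):
        k_idx, s_idx = np.nonzero(history.detections[i])
        if k_idx.size < 2:
            continue
        xs = detectors.x[k_idx]
        ys = detectors.y[k_idx]
        dev += ((xs - xs.mean()) ** 2 + (ys - ys.mean()) ** 2).sum()
        n_tot += k_idx.size
        m += 1
    if m == 0:
        raise ValueError(
            "RPSV undefined: no individual has >= 2 detections; "
            "supply a mask buffer explicitly"
        )
    return float(np.sqrt(dev / (2.0 * (n_tot - m))))


def build_mask(
    detectors: DetectorArray,
    buffer: float,
    spacing: float,
    clip_bounds: tuple | None = None,
) -> MaskGrid:
    """Grid of cells whose centroids lie within `buffer` of any detector.

    The lattice is anchored at the detector bounding-box minimum, so a
    detector coordinate is itself a lattice point. ``clip_bounds``
    (xmin, ymin, xmax, ymax) optionally restricts the mask, e.g. to the
    mapped landscape.
    """
    if detectors.n_detectors == 0:
        raise ValueError("cannot build a mask around an empty detector set")
    if buffer <= 0 or spacing <= 0:
        raise ValueError("buffer and spacing must be positive")
    x0, y0 = detectors.x.min(), detectors.y.min()
    nx_lo = int(np.floor(-buffer / spacing))
    nx_hi = int(np.ceil((detectors.x.max() - x0 + buffer) / spacing))
    ny_lo = int(np.floor(-buffer / spacing))
    ny_hi = int(np.ceil((detectors.y.max() - y0 + buffer) / spacing))
    gx, gy = np.meshgrid(
        x0 + np.arange(nx_lo, nx_hi + 1) * spacing,
        y0 + np.arange(ny_lo, ny_hi + 1) * spacing,
        indexing="ij",
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(detectors.coords)
    d, _ = tree.query(pts)
    keep = d <= buffer + 1e-12
    if clip_bounds is not None:
        xmin, ymin, xmax, ymax = clip_bounds
        keep &= (
            (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
        )
    pts = pts[keep]
    return MaskGrid(pts[:, 0], pts[:, 1], spacing)


# ---------------------------------------------------------------------------
# rasters


@dataclass
class Raster:
    """Minimal in-memory grid matching the ESRI ASCII (.asc) layout.

    ``data`` is (nrows, ncols) with row 0 the *northern* row, as in the
    file format. Categorical layers may hold object dtype.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def value_at(self, x: float, y: float):
        """Nearest-cell lookup; raises if (x, y) is outside the extent."""
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = self.nrows - 1 - int(np.floor((y - self.yll) / self.cellsize))
        if not (0 <= col < self.ncols and 0 <= row < self.nrows):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return self.data[row, col]

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        header = {}
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            key, val = lines[i].split()[:2]
            header[key.lower()] = float(val)
            i += 1
        data = np.loadtxt(lines[i:])
        data = np.atleast_2d(data)
        return cls(
            data,
            header["xllcorner"],
            header["yllcorner"],
            header["cellsize"],
            header.get("nodata_value", -9999.0),
        )

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"ncols {self.ncols}\nnrows {self.nrows}\n"
                f"xllcorner {self.xll:.10g}\nyllcorner {self.yll:.10g}\n"
                f"cellsize {self.cellsize:.10g}\n"
                f"NODATA_value {self.nodata:.10g}\n"
            )
            for row in self.data:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def attach_covariates(mask: MaskGrid, source) -> MaskGrid:
    """Attach covariates to mask cells by point extraction at centroids.

    ``source`` is either a mapping of name -> `Raster`, or a grid-like
    object (a `MaskGrid`, e.g. the synthetic landscape) whose covariate
    values are looked up at the nearest cell. A centroid farther than
    one source cell from any source point is an error naming the cell,
    never a silent missing value.
    """
    out = {}
    if isinstance(source, dict):
        for name, rast in source.items():
            vals = []
            for i, (x, y) in enumerate(mask.coords):
                try:
                    vals.append(rast.value_at(x, y))
                except ValueError as exc:
                    raise ValueError(
                        f"mask cell {i} at ({x:.3f}, {y:.3f}) outside "
                        f"raster {name!r}"
                    ) from exc
            out[name] = np.asarray(vals)
    elif isinstance(source, MaskGrid):
        tree = cKDTree(source.coords)
        d, idx = tree.query(mask.coords)
        tol = source.spacing * np.sqrt(2) / 2 + 1e-9
        bad = np.nonzero(d > tol)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"mask cell {i} at ({mask.x[i]:.3f}, {mask.y[i]:.3f}) "
                f"outside the covariate grid"
            )
        for name in source.covariates.columns:
            out[name] = source.covariates[name].to_numpy()[idx]
    else:
        raise TypeError("source must be a dict of Raster or a MaskGrid")
    return mask.with_covariates(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# opportunistic gridding


def grid_opportunistic(
    samples: pd.DataFrame,
    cell_size: float,
    origin: tuple = (0.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Snap point detections onto a square grid of trap cells.

    ``samples`` needs columns ``individual, x, y`` (and optionally
    ``occasion``). Cells are half-open squares
    [origin + k*c, origin + (k+1)*c); each sample maps to its cell
    centroid and duplicate (individual, cell, occasion) records
    collapse to one detection.

    Returns ``(cells, records)``: unique cells (cell_id, x, y) and the
    deduplicated detections (individual, occasion, cell_id).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    cols = {"individual", "x", "y"}
    if samples.empty:
        return (
            pd.DataFrame(columns=["cell_id", "x", "y"]),
            pd.DataFrame(columns=["individual", "occasion", "cell_id"]),
        )
    if not cols <= set(samples.columns):
        raise ValueError(f"samples must have columns {sorted(cols)}")
    ox, oy = origin
    kx = np.floor((samples["x"].to_numpy(float) - ox) / cell_size).astype(int)
    ky = np.floor((samples["y"].to_numpy(float) - oy) / cell_size).astype(int)
    rec = pd.DataFrame(
        {
            "individual": samples["individual"].to_numpy(),
            "occasion": samples.get(
                "occasion", pd.Series(1, index=samples.index)
            ).to_numpy(),
            "kx": kx,
            "ky": ky,
        }
    ).drop_duplicates()
    rec["cell_id"] = [f"opp_{a}_{b}" for a, b in zip(rec.kx, rec.ky)]
    cells = (
        rec[["cell_id", "kx", "ky"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    cells["x"] = ox + (cells.pop("kx") + 0.5) * cell_size
    cells["y"] = oy + (cells.pop("ky") + 0.5) * cell_size
    records = rec[["individual", "occasion", "cell_id"]].reset_index(drop=True)
    return cells, records


def opportunistic_detectors(
    cells: pd.DataFrame, n_occasions: int, occasion: int | None = None
) -> DetectorArray:
    """Wrap gridded opportunistic cells as an opp-type DetectorArray
    active on a single occasion (default: the last)."""
    if occasion is None:
        occasion = n_occasions - 1
    K = len(cells)
    usage = np.zeros((K, n_occasions), dtype=np.int8)
    usage[:, occasion] = 1
    return DetectorArray(
        cells["cell_id"].to_numpy(),
        cells["x"].to_numpy(float),
        cells["y"].to_numpy(float),
        np.full(K, "opp"),
        usage,
    )


# ---------------------------------------------------------------------------
# MCP


def mcp_buffer(points: np.ndarray, buffer: float, quad_segs: int = 64) -> Polygon:
    """Minimum convex polygon around `points`, dilated by `buffer` km.

    Needs at least three non-collinear points. ``quad_segs`` controls
    the circular-arc approximation of the dilation.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("need >= 3 (x, y) points for an MCP")
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear; MCP is degenerate")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    if buffer == 0:
        return hull
    return hull.buffer(buffer, quad_segs=quad_segs)
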