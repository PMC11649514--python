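"""Ki67 heatmap and fixed-area square hotspot search.

The hotspot is the axis-aligned square of predefined area (default
0.5 mm², side √0.5·1000 ≈ 707.107 µm) that maximizes the Ki67-positive
ratio among candidate windows containing at least ``min_cells`` masked
tumour nuclei. Candidate origins lie on a lattice of pitch ``stride_um``
with the window fully inside the slide. The proliferation index of the
winning window is computed over ALL its cells, not the first 500. Ties
(equal positive ratio, compared exactly as integer fractions) are broken
by higher cell count, then smaller y0, then smaller x0.

``brute_force_hotspot`` re-derives the same answer by direct enumeration
and serves as the definitional oracle for the lattice search.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import CellTable
from .errors import NoHotspotError

__all__ = ["SearchParams", "HeatmapGrid", "Hotspot", "build_heatmap",
           "find_hotspot", "brute_force_hotspot", "compute_pi"]


@dataclass(frozen=True)
class SearchParams:
    hotspot_area_mm2: float = 0.5
    min_cells: int = 500
    stride_um: float = 25.0
    heatmap_bin_um: float = 50.0

    def __post_init__(self) -> None:
        if self.hotspot_area_mm2 <= 0 or self.stride_um <= 0 or self.heatmap_bin_um <= 0:
            raise ValueError("sizes must be positive")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")

    @property
    def window_side_um(self) -> float:
        return math.sqrt(self.hotspot_area_mm2) * 1000.0


@dataclass
class HeatmapGrid:
    """Per-bin tallies of masked cells; ratio is NaN (undefined) for empty
    bins — stroma never dilutes the display."""

    bin_um: float
    total: np.ndarray      # (ny, nx) int
    positive: np.ndarray   # (ny, nx) int
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.positive / self.total.astype(float)
        return np.where(self.total > 0, r, np.nan)

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.total.shape
        by, bx = np.mgrid[0:ny, 0:nx]
        return pd.DataFrame({
            "bin_x": bx.ravel(), "bin_y": by.ravel(),
            "total": self.total.ravel(), "positive": self.positive.ravel(),
            "ratio": self.ratio.ravel(),
        })


@dataclass
class Hotspot:
    origin_um: tuple[float, float]
    side_um: float
    n_cells: int
    n_positive: int
    pi_percent: float
    method: str = ""

    @property
    def center_um(self) -> tuple[float, float]:
        return (self.origin_um[0] + self.side_um / 2, self.origin_um[1] + self.side_um / 2)

    def as_dict(self) -> dict:
        return {"x0_um": self.origin_um[0], "y0_um": self.origin_um[1],
                "side_um": self.side_um, "n_cells": self.n_cells,
                "n_positive": self.n_positive, "pi_percent": self.pi_percent,
                "method": self.method}

    def to_geojson(self) -> dict:
        x0, y0 = self.origin_um
        s = self.side_um
        ring = [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0]]
        return {"type": "Feature", "properties": self.as_dict(),
                "geometry": {"type": "Polygon", "coordinates": [ring]}}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def compute_pi(n_positive: int, n_total: int) -> float:
    """Proliferation index in percent, reported to one decimal."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_positive <= n_total):
        raise ValueError("need 0 <= n_positive <= n_total")
    return round(100.0 * n_positive / n_total, 1)


def _cells_xy(cells) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = cells.df if isinstance(cells, CellTable) else cells
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    pos = (df["ki67_class"].to_numpy() == "positive")
    return x, y, pos


def _extent(extent_um, mask) -> tuple[float, float]:
    if extent_um is not None:
        return float(extent_um[0]), float(extent_um[1])
    if mask is not None:
        h, w = mask.mask.shape
        res = mask.resolution_um_per_px
        return w * res, h * res
    raise ValueError("supply extent_um or a mask to bound the search")


def build_heatmap(cells, mask=None, params: SearchParams | None = None,
                  extent_um=None) -> HeatmapGrid:
    """Bin mask-filtered cells into half-open square bins."""
    params = params or SearchParams()
    width, height = _extent(extent_um, mask)
    x, y, pos = _cells_xy(cells)
    b = params.heatmap_bin_um
    nx = max(1, int(math.ceil(width / b)))
    ny = max(1, int(math.ceil(height / b)))
    ix = np.floor(x / b).astype(int)
    iy = np.floor(y / b).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    total = np.zeros((ny, nx), dtype=int)
    positive = np.zeros((ny, nx), dtype=int)
    np.add.at(total, (iy[ok], ix[ok]), 1)
    np.add.at(positive, (iy[ok][pos[ok]], ix[ok][pos[ok]]), 1)
    return HeatmapGrid(b, total, positive)


def _candidate_origins(extent: float, side: float, stride: float) -> np.ndarray:
    n = int(math.floor((extent - side) / stride + 1e-9)) + 1
    if n <= 0:
        return np.empty(0)
    return np.arange(n) * stride


def _select_best(x0s, y0s, ns, ps) -> int:
    """Index of the best window: max exact ratio, then max n, min y0, min x0."""
    ns = np.asarray(ns)
    ps = np.asarray(ps)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = ps / ns.astype(float)
    best_f = np.nanmax(ratio)
    near = np.flatnonzero(ratio >= best_f - 1e-12)
    best = None
    for i in near:
        if best is None:
            best = i
            continue
        # exact fraction comparison: p_i/n_i vs p_b/n_b
        lhs = int(ps[i]) * int(ns[best])
        rhs = int(ps[best]) * int(ns[i])
        if lhs > rhs:
            best = i
        elif lhs == rhs:
            if (int(ns[i]), -float(y0s[i]), -float(x0s[i])) > \
               (int(ns[best]), -float(y0s[best]), -float(x0s[best])):
                best = i
    return int(best)


def find_hotspot(cells, mask=None, params: SearchParams | None = None,
                 extent_um=None, method: str = "") -> Hotspot:
    """Lattice search for the maximal-ratio eligible window.

    ``cells`` must already be mask-filtered. Raises :class:`NoHotspotError`
    when no candidate window holds ``min_cells`` cells (the case is
    reported unscorable).
    """
    params = params or SearchParams()
    width, height = _extent(extent_um, mask)
    side = params.window_side_um
    x, y, pos = _cells_xy(cells)
    xs0 = _candidate_origins(width, side, params.stride_um)
    ys0 = _candidate_origins(height, side, params.stride_um)
    if len(xs0) == 0 or len(ys0) == 0:
        raise NoHotspotError("window larger than slide")

    order = np.argsort(x, kind="stable")
    x_sorted = x[order]
    y_by_x = y[order]
    pos_by_x = pos[order]

    cand_x, cand_y, cand_n, cand_p = [], [], [], []
    for x0 in xs0:
        i0 = np.searchsorted(x_sorted, x0, side="left")
        i1 = np.searchsorted(x_sorted, x0 + side, side="left")
        if i1 - i0 < params.min_cells:
            continue
        ys = y_by_x[i0:i1]
        ps = pos_by_x[i0:i1]
        yorder = np.argsort(ys, kind="stable")
        ys = ys[yorder]
        cum_pos = np.concatenate([[0], np.cumsum(ps[yorder])])
        j0 = np.searchsorted(ys, ys0, side="left")
        j1 = np.searchsorted(ys, ys0 + side, side="left")
        n_win = j1 - j0
        ok = n_win >= params.min_cells
        if not ok.any():
            continue
        cand_x.append(np.full(ok.sum(), x0))
        cand_y.append(ys0[ok])
        cand_n.append(n_win[ok])
        cand_p.append(cum_pos[j1[ok]] - cum_pos[j0[ok]])

    if not cand_x:
        raise NoHotspotError(
            f"no {side:.0f} µm window holds >= {params.min_cells} masked cells")
    cand_x = np.concatenate(cand_x)
    cand_y = np.concatenate(cand_y)
    cand_n = np.concatenate(cand_n)
    cand_p = np.concatenate(cand_p)
    i = _select_best(cand_x, cand_y, cand_n, cand_p)
    n, p = int(cand_n[i]), int(cand_p[i])
    return Hotspot((float(cand_x[i]), float(cand_y[i])), side, n, p,
                   compute_pi(p, n), method)


def brute_force_hotspot(cells, mask=None, params: SearchParams | None = None,
                        extent_um=None, method: str = "") -> Hotspot:
    """O(candidates × cells) enumeration with identical eligibility and
    tie-break rules; the test oracle for :func:`find_hotspot`."""
    params = params or SearchParams()
    width, height = _extent(extent_um, mask)
    side = params.window_side_um
    x, y, pos = _cells_xy(cells)
    xs0 = _candidate_origins(width, side, params.stride_um)
    ys0 = _candidate_origins(height, side, params.stride_um)

    best = None  # (x0, y0, n, p)
    for y0 in ys0:
        in_y = (y >= y0) & (y < y0 + side)
        for x0 in xs0:
            in_win = in_y & (x >= x0) & (x < x0 + side)
            n = int(in_win.sum())
            if n < params.min_cells:
                continue
            p = int(pos[in_win].sum())
            if best is None:
                best = (x0, y0, n, p)
                continue
            lhs = p * best[2]
            rhs = best[3] * n
            better = lhs > rhs or (
                lhs == rhs and (n, -y0, -x0) > (best[2], -best[1], -best[0]))
            if better:
                best = (x0, y0, n, p)
    if best is None:
        raise NoHotspotError(
            f"no {side:.0f} µm window holds >= {params.min_cells} masked cells")
    x0, y0, n, p = best
    return Hotspot((float(x0), float(y0)), side, n, p, compute_pi(p, n), method)
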