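"""Simulated manual hotspot scoring by human observers.

An observer looks at the real slide (ground-truth cells, not the
detector's output — human perception does not share the algorithm's
segmentation errors), perceives Ki67 positivity on a coarse grid with
additive noise, centres a fixed-size ROI on the apparently hottest bin,
and counts 500 tumour cells in a typewriter pattern: fields of view
visited in raster order (left→right within a row of fields, rows
top→bottom), stopping at the end of the field in which the 500th cell is
reached — hence counts slightly above 500, as standardized manual scoring
produces in practice. Each counted cell's class may be misread with a
small flip probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GenerationError
from .hotspot import compute_pi
from .simgen import HOTSPOT_WINDOW_SIDE_UM, RegionPolygon, SyntheticCase

__all__ = ["ObserverProfile", "ObserverScore", "perceive_hotspot",
           "typewriter_count", "score_manual"]

TARGET_COUNT = 500


@dataclass(frozen=True)
class ObserverProfile:
    """Perceptual and procedural parameters of one simulated observer."""

    perception_bin_um: float = 250.0
    perception_noise_sd: float = 0.05
    classification_flip_prob: float = 0.03
    roi_side_um: float = HOTSPOT_WINDOW_SIDE_UM
    row_height_um: float = 50.0
    field_width_um: float = 100.0
    observer_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.classification_flip_prob <= 1):
            raise ValueError("flip probability outside [0, 1]")
        if min(self.perception_bin_um, self.roi_side_um, self.row_height_um,
               self.field_width_um) <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.perception_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class ObserverScore:
    roi_origin_um: tuple[float, float]
    roi_side_um: float
    n_counted: int
    n_positive_counted: int
    pi_percent: float
    observer_id: int
    seed: int


def _invasive_frame(cells: pd.DataFrame) -> pd.DataFrame:
    return cells[cells["region_class"] == "invasive_tumour"]


def perceive_hotspot(truth_cells: pd.DataFrame, regions: list[RegionPolygon],
                     profile: ObserverProfile, rng: np.random.Generator,
                     extent_um: tuple[float, float]) -> tuple[float, float]:
    """Pick the ROI origin: noisy argmax over the coarse perception grid.

    Bins holding fewer cells than the hotspot-window density equivalent
    (min 500 scaled by bin/window area) are down-weighted — observers
    favour dense regions inside the tumour over sparse margins. Ties break
    deterministically (smaller bin y, then x). The ROI is centred on the
    winning bin and clipped into the slide and the invasive region's
    bounding box.
    """
    inv = _invasive_frame(truth_cells)
    if not len(inv):
        raise GenerationError("no invasive cells to perceive")
    b = profile.perception_bin_um
    width, height = extent_um
    nx = max(1, int(math.ceil(width / b)))
    ny = max(1, int(math.ceil(height / b)))
    ix = np.clip(np.floor(inv["x_um"].to_numpy() / b).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(inv["y_um"].to_numpy() / b).astype(int), 0, ny - 1)
    total = np.zeros((ny, nx))
    positive = np.zeros((ny, nx))
    np.add.at(total, (iy, ix), 1)
    pos = inv["ki67_class"].to_numpy() == "positive"
    np.add.at(positive, (iy[pos], ix[pos]), 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, positive / total, -np.inf)
    dense_min = TARGET_COUNT * (b * b) / (HOTSPOT_WINDOW_SIDE_UM ** 2)
    weight = np.where(total >= dense_min, 1.0, 0.5)
    score = np.where(total > 0,
                     ratio * weight + profile.perception_noise_sd * rng.standard_normal(
                         (ny, nx)),
                     -np.inf)
    flat = np.argmax(score)  # row-major: smaller y first, then smaller x
    by, bx = np.unravel_index(flat, score.shape)

    cx, cy = (bx + 0.5) * b, (by + 0.5) * b
    s = profile.roi_side_um
    x0, y0 = cx - s / 2, cy - s / 2
    invasive = next(r for r in regions if r.region_class == "invasive_tumour")
    minx, miny, maxx, maxy = invasive.polygon.bounds
    if maxx - minx >= s:
        x0 = min(max(x0, minx), maxx - s)
    if maxy - miny >= s:
        y0 = min(max(y0, miny), maxy - s)
    x0 = min(max(x0, 0.0), max(0.0, width - s))
    y0 = min(max(y0, 0.0), max(0.0, height - s))
    return (x0, y0)


def typewriter_count(truth_cells: pd.DataFrame, roi: tuple[float, float],
                     profile: ObserverProfile, rng: np.random.Generator
                     ) -> tuple[int, int]:
    """Count invasive cells in the ROI in typewriter order.

    The ROI grows by 10% steps about its centre until it holds at least
    500 invasive cells (error if the whole slide has fewer). Returns
    (n_counted, n_positive_counted) after per-cell misreads.
    """
    inv = _invasive_frame(truth_cells)
    if len(inv) < TARGET_COUNT:
        raise GenerationError("fewer than 500 invasive cells on the slide")
    x = inv["x_um"].to_numpy(dtype=float)
    y = inv["y_um"].to_numpy(dtype=float)
    positive = inv["ki67_class"].to_numpy() == "positive"

    x0, y0 = roi
    side = profile.roi_side_um
    cx, cy = x0 + side / 2, y0 + side / 2
    for _ in range(200):
        half = side / 2
        sel = (x >= cx - half) & (x < cx + half) & (y >= cy - half) & (y < cy + half)
        if sel.sum() >= TARGET_COUNT:
            break
        side *= 1.1
    else:
        raise GenerationError("ROI could not be grown to 500 cells")

    rx = x[sel] - (cx - side / 2)
    ry = y[sel] - (cy - side / 2)
    rpos = positive[sel]
    row = np.floor(ry / profile.row_height_um).astype(int)
    col = np.floor(rx / profile.field_width_um).astype(int)
    order = np.lexsort((ry, rx, col, row))
    row_o = row[order]
    col_o = col[order]
    rpos_o = rpos[order]

    k = TARGET_COUNT - 1
    stop_row, stop_col = row_o[k], col_o[k]
    in_stop_field = (row_o == stop_row) & (col_o == stop_col)
    last = np.flatnonzero(in_stop_field)[-1]
    n_counted = int(last + 1)
    counted_pos = rpos_o[:n_counted].copy()
    if profile.classification_flip_prob > 0:
        flips = rng.random(n_counted) < profile.classification_flip_prob
        counted_pos ^= flips
    return n_counted, int(counted_pos.sum())


def score_manual(case: SyntheticCase, profile: ObserverProfile,
                 rng: np.random.Generator | None = None) -> ObserverScore:
    """Full manual protocol: perceive a hotspot, then typewriter-count it."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.seed, profile.observer_id,
                                    int(case.spec.seed)]))
    extent = (case.spec.width_um, case.spec.height_um)
    roi = perceive_hotspot(case.cells, case.regions, profile, rng, extent)
    n_counted, n_pos = typewriter_count(case.cells, roi, profile, rng)
    return ObserverScore(roi, profile.roi_side_um, n_counted, n_pos,
                         compute_pi(n_pos, n_counted), profile.observer_id,
                         profile.seed)
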