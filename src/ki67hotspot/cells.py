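"""Nucleus detection and Ki67 classification on the Ki67 section.

The detector is a classical colour-deconvolution pipeline: the RGB image is
inverted to haematoxylin/DAB concentration maps, the total nuclear optical
density is smoothed at nucleus scale and thresholded, touching blobs are
split by a distance-transform watershed, and components are filtered by
area and circularity ("shape and size"). Each surviving nucleus carries
its mean stain ODs; it is Ki67-positive when its mean DAB OD reaches the
(deliberately low) positive threshold — any intensity of brown nuclear
staining counts as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stains import StainMatrix, deconvolve, rgb_to_od

__all__ = ["DetectionParams", "CellTable", "detect_nuclei", "classify_nuclei",
           "match_to_ground_truth", "MatchReport"]

CSV_COLUMNS = ["id", "x_um", "y_um", "area_um2", "mean_dab_od", "mean_h_od", "ki67_class"]


@dataclass(frozen=True)
class DetectionParams:
    """Shape/size and staining thresholds of the nucleus detector."""

    min_diameter_um: float = 5.0
    max_diameter_um: float = 13.0
    nuclear_od_threshold: float = 0.25
    dab_positive_threshold: float = 0.15
    min_circularity: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter_um < self.max_diameter_um):
            raise ValueError("need 0 < min_diameter < max_diameter")
        if self.nuclear_od_threshold <= 0 or self.dab_positive_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.min_circularity <= 1):
            raise ValueError("circularity must be in (0, 1]")

    @property
    def min_area_um2(self) -> float:
        return np.pi * (self.min_diameter_um / 2) ** 2

    @property
    def max_area_um2(self) -> float:
        return np.pi * (self.max_diameter_um / 2) ** 2


@dataclass
class CellTable:
    """Detected (or ground-truth-derived) nuclei plus provenance.

    ``df`` columns: id, x_um, y_um, area_um2, equivalent_diameter_um,
    mean_dab_od, mean_h_od, ki67_class.
    """

    df: pd.DataFrame
    resolution_um_per_px: float = 1.0
    source: str = ""
    params: DetectionParams | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_positive(self) -> int:
        return int((self.df["ki67_class"] == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.df["ki67_class"] == "negative").sum())

    def to_csv(self, path) -> None:
        out = self.df.copy()
        for col in CSV_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan
        out.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def from_csv(cls, path, resolution_um_per_px: float = 1.0) -> "CellTable":
        return cls(pd.read_csv(path), resolution_um_per_px, source=str(path))


def detect_nuclei(ki67_image: np.ndarray, resolution_um_per_px: float,
                  params: DetectionParams | None = None,
                  stains: StainMatrix | None = None) -> CellTable:
    """Detect and classify nuclei in an RGB Ki67 image.

    Raises ``ValueError`` when the resolution is missing or non-positive.
    """
    from skimage.feature import peak_local_max
    from skimage.measure import regionprops
    from skimage.segmentation import watershed

    if resolution_um_per_px is None or resolution_um_per_px <= 0:
        raise ValueError("resolution metadata required (µm/px)")
    if params is None:
        params = DetectionParams()
    res = resolution_um_per_px

    conc = deconvolve(rgb_to_od(ki67_image), stains, res)
    h_map = np.clip(conc.haematoxylin, 0, None)
    dab_map = np.clip(conc.dab, 0, None)
    total = h_map + dab_map

    sigma = max(0.5, 0.25 * params.min_diameter_um / res)
    smoothed = ndi.gaussian_filter(total, sigma=sigma)
    fg = smoothed > params.nuclear_od_threshold
    if not fg.any():
        return CellTable(_empty_frame(), res, params=params)

    dist = ndi.distance_transform_edt(fg)
    labels0, _ = ndi.label(fg)
    min_sep_px = max(1, int(round(0.5 * params.min_diameter_um / res)))
    coords = peak_local_max(dist, min_distance=min_sep_px, labels=labels0,
                            exclude_border=False)
    markers = np.zeros_like(labels0)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-dist, markers, mask=fg)

    rows = []
    for prop in regionprops(labels):
        area_um2 = prop.area * res * res
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        perimeter = prop.perimeter
        circularity = 4 * np.pi * prop.area / (perimeter ** 2) if perimeter > 0 else 1.0
        if circularity < params.min_circularity:
            continue
        cy, cx = prop.centroid
        sl = prop.slice
        component = labels[sl] == prop.label
        rows.append({
            "x_um": (cx + 0.5) * res,
            "y_um": (cy + 0.5) * res,
            "area_um2": area_um2,
            "equivalent_diameter_um": 2 * np.sqrt(area_um2 / np.pi),
            "mean_dab_od": float(dab_map[sl][component].mean()),
            "mean_h_od": float(h_map[sl][component].mean()),
        })
    if not rows:
        return CellTable(_empty_frame(), res, params=params)
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(len(df)))
    table = CellTable(df, res, params=params)
    return classify_nuclei(table, params)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["id", "x_um", "y_um", "area_um2",
                                 "equivalent_diameter_um", "mean_dab_od",
                                 "mean_h_od", "ki67_class"])


def classify_nuclei(table: CellTable, params: DetectionParams | None = None) -> CellTable:
    """Assign ki67_class from mean DAB OD: positive iff >= threshold
    (inclusive boundary — any intensity of brown staining is positive)."""
    if params is None:
        params = table.params or DetectionParams()
    df = table.df.copy()
    df["ki67_class"] = np.where(df["mean_dab_od"] >= params.dab_positive_threshold,
                                "positive", "negative")
    return CellTable(df, table.resolution_um_per_px, table.source, params)


@dataclass
class MatchReport:
    """Greedy one-to-one matching of detections against ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int
    precision: float
    recall: float
    f1: float
    class_accuracy: float
    confusion: pd.DataFrame
    pairs: np.ndarray  # (n_matched, 2): truth index, detected index


def match_to_ground_truth(detected: CellTable | pd.DataFrame,
                          truth_cells: pd.DataFrame,
                          match_radius_um: float = 5.0) -> MatchReport:
    """Match detections to truth centroids greedily by increasing distance.

    One-to-one within ``match_radius_um``; the confusion matrix and class
    accuracy are computed over matched pairs only.
    """
    from scipy.spatial import cKDTree

    det_df = detected.df if isinstance(detected, CellTable) else detected
    t_xy = truth_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    d_xy = det_df[["x_um", "y_um"]].to_numpy(dtype=float)
    n_t, n_d = len(t_xy), len(d_xy)

    pairs = []
    if n_t and n_d:
        tree = cKDTree(t_xy)
        cand = tree.query_ball_point(d_xy, match_radius_um)
        edges = [(np.hypot(*(t_xy[ti] - d_xy[di])), ti, di)
                 for di, tis in enumerate(cand) for ti in tis]
        edges.sort()
        used_t = np.zeros(n_t, dtype=bool)
        used_d = np.zeros(n_d, dtype=bool)
        for _, ti, di in edges:
            if not used_t[ti] and not used_d[di]:
                used_t[ti] = used_d[di] = True
                pairs.append((ti, di))
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    n_m = len(pairs)
    precision = n_m / n_d if n_d else 0.0
    recall = n_m / n_t if n_t else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    classes = ("positive", "negative")
    conf = pd.DataFrame(0, index=classes, columns=classes)
    if n_m:
        t_cls = truth_cells["ki67_class"].to_numpy()[pairs[:, 0]]
        d_cls = det_df["ki67_class"].to_numpy()[pairs[:, 1]]
        for tc in classes:
            for dc in classes:
                conf.loc[tc, dc] = int(np.sum((t_cls == tc) & (d_cls == dc)))
        class_accuracy = float(np.mean(t_cls == d_cls))
    else:
        class_accuracy = float("nan")
    return MatchReport(n_t, n_d, n_m, precision, recall, f1, class_accuracy, conf, pairs)
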