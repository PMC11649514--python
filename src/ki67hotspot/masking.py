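"""Invasive-tumour masks restricting the hotspot search.

Two arms mirror the study design. The VDS arm registers the serial CK8/18
section to the Ki67 section (rigid, coarse exhaustive search + fine
refinement on epithelial foreground overlap), thresholds the CK stain into
an epithelial mask, transfers it into the Ki67 frame, and removes
operator-supplied exclusion polygons (benign / in-situ) — the human
"manual discard" step. Registration whose foreground IoU falls below the
failure threshold marks the case VDS-excluded, reproducing the failure
pathway of sections that are misaligned or not cut in serial order. The
rule arm stands in for the trained tumour-detection model: it rasterizes
invasive-tumour polygons (or delegates to any pluggable detector) and never
touches the CK section, so it cannot fail for alignment reasons.

Cell membership is centroid-in-mask: a nucleus belongs to the mask iff the
pixel under its centroid is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cells import CellTable
from .errors import RegistrationFailedError
from .stains import StainMatrix, deconvolve, rgb_to_od
from .transforms import RigidTransform

__all__ = ["RigidTransform", "RegistrationResult", "TumourMask",
           "register_serial", "build_mask_vds", "build_mask_rule",
           "filter_cells_by_mask", "DEFAULT_FAILURE_THRESHOLD"]

#: Registration is declared failed below this epithelial-overlap IoU.
DEFAULT_FAILURE_THRESHOLD = 0.6

#: Stain-concentration threshold for epithelial / nuclear foreground.
FOREGROUND_OD_THRESHOLD = 0.15


@dataclass
class RegistrationResult:
    """Estimated CK→Ki67 rigid correction and its quality."""

    transform: RigidTransform
    alignment_score: float
    status: str  # "success" | "failed"
    failure_threshold: float = DEFAULT_FAILURE_THRESHOLD

    def as_dict(self) -> dict:
        d = self.transform.as_dict()
        d.update(score=self.alignment_score, status=self.status,
                 failure_threshold=self.failure_threshold)
        return d


@dataclass
class TumourMask:
    """Binary invasive-tumour raster aligned to the Ki67 image."""

    mask: np.ndarray
    resolution_um_per_px: float
    mode: str  # "vds" | "rule" | "ground_truth"
    excluded_classes: tuple[str, ...] = ("benign_epithelium", "carcinoma_in_situ")

    def __post_init__(self) -> None:
        if self.mode not in ("vds", "rule", "ground_truth"):
            raise ValueError(f"unknown mask mode {self.mode!r}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.resolution_um_per_px ** 2 / 1e6

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, (self.mask.astype(np.uint8)) * 255)


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr.astype(np.float32)
    h, w = arr.shape
    h2, w2 = h // factor, w // factor
    return arr[:h2 * factor, :w2 * factor].astype(np.float32).reshape(
        h2, factor, w2, factor).mean(axis=(1, 3))


def _registration_channels(rgb: np.ndarray, resolution_um_per_px: float,
                           stains: StainMatrix | None = None,
                           close_um: float = 25.0,
                           working_um_per_px: float = 2.0
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Foreground mask and haematoxylin map at the registration scale.

    Returns (epithelial/tissue foreground, nuclear H-concentration map,
    working resolution). The foreground is the any-stain threshold pooled
    to the working scale and closed (distance-transform morphology) so
    nuclei merge into contiguous tissue; the H map keeps per-nucleus
    detail, which carries the sharp rotation information.
    """
    res = resolution_um_per_px
    conc = deconvolve(rgb_to_od(rgb), stains, res)
    fg_native = (np.clip(conc.haematoxylin, 0, None) + np.clip(conc.dab, 0, None)
                 ) > FOREGROUND_OD_THRESHOLD
    factor = max(1, int(round(working_um_per_px / res)))
    work_res = res * factor
    fg = _block_mean(fg_native, factor) > 0.2
    fg = _close_disk(fg, close_um / work_res)
    fg = ndi.binary_fill_holes(fg)
    h_map = _block_mean(np.clip(conc.haematoxylin, 0, None), factor)
    return fg, h_map, work_res


def _epithelial_foreground(rgb: np.ndarray, resolution_um_per_px: float,
                           stains: StainMatrix | None = None,
                           close_um: float = 25.0,
                           working_um_per_px: float = 2.0) -> tuple[np.ndarray, float]:
    """Tissue/epithelium foreground at a working scale (mask, µm/px)."""
    fg, _, work_res = _registration_channels(rgb, resolution_um_per_px, stains,
                                             close_um, working_um_per_px)
    return fg, work_res


def _close_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological closing with a Euclidean disk via distance transforms."""
    if radius_px <= 0 or not mask.any():
        return mask
    dilated = ndi.distance_transform_edt(~mask) <= radius_px + 0.5
    return ndi.distance_transform_edt(dilated) > radius_px


def _downsample_bool(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    h, w = mask.shape
    h2, w2 = h // factor, w // factor
    trimmed = mask[:h2 * factor, :w2 * factor].astype(np.float32)
    pooled = trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))
    return pooled > 0.5


def _rotate_bool(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0:
        return mask
    rot = ndi.rotate(mask.astype(np.float32), -angle_deg, reshape=False, order=1)
    return rot > 0.5


def _best_shift(fixed: np.ndarray, moving: np.ndarray, max_shift_px: float
                ) -> tuple[float, float, float]:
    """Translation (dy, dx) maximizing overlap count, by FFT correlation,
    restricted to |shift| components <= max_shift_px; parabolic subpixel."""
    f = np.fft.rfft2(fixed.astype(np.float32))
    m = np.fft.rfft2(moving.astype(np.float32))
    corr = np.fft.irfft2(f * np.conj(m), s=fixed.shape)
    # shift index k means moving displaced by +k (wrapped)
    h, w = fixed.shape
    ky = np.fft.fftfreq(h, 1 / h).astype(int)
    kx = np.fft.fftfreq(w, 1 / w).astype(int)
    allowed = (np.abs(ky)[:, None] <= max_shift_px) & (np.abs(kx)[None, :] <= max_shift_px)
    corr_masked = np.where(allowed, corr, -np.inf)
    iy, ix = np.unravel_index(np.argmax(corr_masked), corr.shape)

    def parabolic(c_m, c_0, c_p):
        denom = c_m - 2 * c_0 + c_p
        if denom >= 0:
            return 0.0
        return 0.5 * (c_m - c_p) / denom

    dy = float(ky[iy]) + parabolic(corr[(iy - 1) % h, ix], corr[iy, ix],
                                   corr[(iy + 1) % h, ix])
    dx = float(kx[ix]) + parabolic(corr[iy, (ix - 1) % w], corr[iy, ix],
                                   corr[iy, (ix + 1) % w])
    return dy, dx, float(corr[iy, ix])


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union) if union else 0.0


def _apply_transform_mask(mask: np.ndarray, transform: RigidTransform,
                          resolution_um_per_px: float) -> np.ndarray:
    """Warp a boolean raster by a µm-space rigid transform (about centre)."""
    res = resolution_um_per_px
    h, w = mask.shape
    centre = np.array([(w / 2), (h / 2)])  # px, (x, y)
    theta = np.deg2rad(transform.theta_deg)
    c, s = np.cos(theta), np.sin(theta)
    # output pixel (x', y') pulls from input (x, y) = R^-1 ((x' - t) - c) + c
    rot_inv = np.array([[c, s], [-s, c]])
    t_px = np.array([transform.dx_um, transform.dy_um]) / res
    offset_xy = centre - rot_inv @ (centre + t_px)
    # ndi.affine_transform works in (row, col) = (y, x) order
    matrix = rot_inv[::-1, ::-1]
    offset = offset_xy[::-1]
    out = ndi.affine_transform(mask.astype(np.float32), matrix, offset=offset, order=1)
    return out > 0.5


def register_serial(ck_image: np.ndarray, ki67_image: np.ndarray,
                    resolution_um_per_px: float,
                    stains: StainMatrix | None = None,
                    max_shift_um: float = 500.0,
                    coarse_rotation_deg: float = 5.0,
                    coarse_rotation_step_deg: float = 1.0,
                    fine_rotation_step_deg: float = 0.1,
                    failure_threshold: float = DEFAULT_FAILURE_THRESHOLD
                    ) -> RegistrationResult:
    """Estimate the rigid CK→Ki67 correction by foreground overlap.

    Coarse stage: exhaustive rotation grid (±``coarse_rotation_deg``) at
    ~8 µm/px with FFT translation search within ±``max_shift_um``. Fine
    stage: 0.1° rotation grid around the coarse optimum at ~2 µm/px with
    subpixel translation. The alignment score is the foreground IoU after
    applying the estimate; below ``failure_threshold`` the status is
    ``failed`` and the case drops out of the VDS arm.
    """
    res = resolution_um_per_px
    fg_ki, h_ki, work_res = _registration_channels(ki67_image, res, stains)
    fg_ck, h_ck, _ = _registration_channels(ck_image, res, stains)
    if not fg_ki.any() or not fg_ck.any():
        return RegistrationResult(RigidTransform.identity(), 0.0, "failed",
                                  failure_threshold)

    def search(moving, fixed, angles, scale_um, order):
        best = None
        for ang in angles:
            if ang == 0:
                rotated = moving
            else:
                rotated = ndi.rotate(moving, -ang, reshape=False, order=order)
            dy, dx, score = _best_shift(fixed, rotated, max_shift_um / scale_um)
            if best is None or score > best[0]:
                best = (score, ang, dx * scale_um, dy * scale_um)
        return best

    coarse_factor = max(1, int(round(8.0 / work_res)))
    fg_ki_c = _downsample_bool(fg_ki, coarse_factor).astype(np.float32)
    fg_ck_c = _downsample_bool(fg_ck, coarse_factor).astype(np.float32)
    angles = np.arange(-coarse_rotation_deg, coarse_rotation_deg + 1e-9,
                       coarse_rotation_step_deg)
    coarse_best = search(fg_ck_c, fg_ki_c, angles, coarse_factor * work_res,
                         order=0)

    # refinement on the nuclear H maps: tissue outlines are nearly
    # rotation-blind for roundish lesions, while the shared nuclei (same
    # cells, <=5 µm section jitter) lock both angle and subpixel shift.
    # The medium sweep re-covers the full rotation range because the
    # outline-based coarse angle can be degrees off.
    med_factor = max(1, int(round(4.0 / work_res)))
    h_ki_m = ndi.gaussian_filter(_block_mean(h_ki, med_factor), 1.0)
    h_ck_m = ndi.gaussian_filter(_block_mean(h_ck, med_factor), 1.0)
    med_angles = np.arange(-coarse_rotation_deg, coarse_rotation_deg + 1e-9, 0.3)
    med_best = search(h_ck_m, h_ki_m, med_angles, med_factor * work_res, order=1)
    ang_m = med_best[1] if med_best[0] > 0 else coarse_best[1]

    h_ki_s = ndi.gaussian_filter(h_ki, 1.0)
    h_ck_s = ndi.gaussian_filter(h_ck, 1.0)
    fine_angles = np.arange(ang_m - 0.3, ang_m + 0.3 + 1e-9, fine_rotation_step_deg)
    _, ang, dx, dy = search(h_ck_s, h_ki_s, fine_angles, work_res, order=1)

    estimate = RigidTransform(float(dx), float(dy), float(ang))
    warped = _apply_transform_mask(fg_ck, estimate, work_res)
    score = _iou(warped, fg_ki)
    status = "success" if score >= failure_threshold else "failed"
    return RegistrationResult(estimate, score, status, failure_threshold)


def build_mask_vds(ck_image: np.ndarray, registration: RegistrationResult,
                   exclusion_regions=(), resolution_um_per_px: float = 1.0,
                   stains: StainMatrix | None = None,
                   closing_um: float = 10.0) -> TumourMask:
    """Epithelial mask from the CK section, transferred into the Ki67 frame,
    with the supplied exclusion polygons (benign / in-situ) discarded.

    Refuses (``RegistrationFailedError``) when registration failed; the
    caller records the case as VDS-excluded.
    """
    if registration.status != "success":
        raise RegistrationFailedError(
            f"registration failed (IoU {registration.alignment_score:.3f} < "
            f"{registration.failure_threshold})")
    res = resolution_um_per_px
    conc = deconvolve(rgb_to_od(ck_image), stains, res)
    epi = np.clip(conc.dab, 0, None) > FOREGROUND_OD_THRESHOLD
    mask = _apply_transform_mask(epi, registration.transform, res)
    mask = _close_disk(mask, closing_um / res)
    mask = _remove_exclusions(mask, exclusion_regions, res)
    return TumourMask(mask, res, "vds")


def _remove_exclusions(mask: np.ndarray, exclusion_regions, res: float) -> np.ndarray:
    from .simgen import RegionPolygon, rasterize_polygons

    geoms = []
    for reg in exclusion_regions:
        geoms.append(reg.polygon if isinstance(reg, RegionPolygon) else reg)
    if not geoms:
        return mask
    excl = rasterize_polygons(geoms, mask.shape, res)
    return mask & ~excl


def build_mask_rule(ki67_image: np.ndarray | tuple[int, int] | None = None,
                    regions=None, detector=None,
                    resolution_um_per_px: float = 1.0,
                    mode: str = "rule") -> TumourMask:
    """Invasive-tumour mask without the CK section.

    Ground-truth mode (``regions`` given): rasterize the invasive_tumour
    polygons — benign and in-situ are excluded by construction. Detector
    mode: ``detector(ki67_image)`` must return a boolean raster. Runs on
    every case; there is no alignment failure pathway.
    """
    from .simgen import RegionPolygon, rasterize_polygons

    if regions is None and detector is None:
        raise ValueError("supply ground-truth regions or a detector")
    if regions is not None:
        invasive = [r.polygon for r in regions
                    if isinstance(r, RegionPolygon) and r.region_class == "invasive_tumour"]
        if ki67_image is None:
            raise ValueError("need the Ki67 image or its shape to size the mask")
        shape = (ki67_image.shape[:2] if isinstance(ki67_image, np.ndarray)
                 else tuple(ki67_image))
        mask = rasterize_polygons(invasive, shape, resolution_um_per_px)
    else:
        mask = np.asarray(detector(ki67_image), dtype=bool)
    return TumourMask(mask, resolution_um_per_px, mode)


def filter_cells_by_mask(table: CellTable | pd.DataFrame, mask: TumourMask):
    """Keep nuclei whose centroid pixel lies inside the mask.

    Accepts a CellTable (resolutions must match) or a bare DataFrame with
    x_um/y_um columns; returns the same type with all columns preserved.
    """
    if isinstance(table, CellTable):
        if not np.isclose(table.resolution_um_per_px, mask.resolution_um_per_px):
            raise ValueError("cell table and mask resolution mismatch")
        df = table.df
    else:
        df = table
    res = mask.resolution_um_per_px
    h, w = mask.mask.shape
    px = np.floor(df["x_um"].to_numpy(dtype=float) / res).astype(int)
    py = np.floor(df["y_um"].to_numpy(dtype=float) / res).astype(int)
    inside = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    keep = np.zeros(len(df), dtype=bool)
    keep[inside] = mask.mask[py[inside], px[inside]]
    out = df.loc[keep].reset_index(drop=True)
    if isinstance(table, CellTable):
        return CellTable(out, table.resolution_um_per_px, table.source, table.params)
    return out
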