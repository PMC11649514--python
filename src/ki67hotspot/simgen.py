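"""Synthetic IHC slide-pair generator with vector ground truth.

Each case emulates the material the hotspot study assumes: a Ki67-stained
section of invasive breast carcinoma whose positive fraction varies
smoothly in space (a Gaussian bump planted on a baseline), plus distractor
epithelium (benign structures and carcinoma in situ, the latter allowed to
be highly Ki67-positive so that only correct masking excludes it), and a
serial CK8/18 section related to the Ki67 section by a small rigid
transform. A ``non_serial`` corruption mode replaces the CK section's
layout with an unrelated one, emulating sections not cut in serial order.

Coordinates are µm with the origin at the top-left pixel corner, x
rightward and y downward. All square windows are half-open
``[x0, x0+s) × [y0, y0+s)``. Everything is deterministic given the spec's
seed: the same seed reproduces bit-identical images and tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from PIL import Image, ImageDraw
from shapely.geometry import Polygon, box, mapping, shape as geo_shape

from .errors import ConfigurationError, GenerationError
from .stains import StainMatrix, forward_render
from .transforms import RigidTransform

__all__ = [
    "SlideSpec",
    "RegionPolygon",
    "SyntheticCase",
    "HOTSPOT_WINDOW_SIDE_UM",
    "generate_regions",
    "sample_cells",
    "render_ki67_image",
    "render_ck_serial",
    "generate_case",
    "write_case",
    "read_case",
    "planted_window_positivity",
    "positivity_field",
    "rasterize_polygons",
]

#: Side of the 0.5 mm² hotspot window in µm.
HOTSPOT_WINDOW_SIDE_UM = math.sqrt(0.5) * 1000.0

#: Render optical densities (haematoxylin nucleus, DAB in positive nuclei,
#: CK epithelial blush, background texture ceiling).
NUCLEUS_H_OD = 0.8
POSITIVE_DAB_OD = 0.6
CK_DAB_OD = 0.35
CK_NUCLEUS_H_OD = 0.5
BACKGROUND_OD_MAX = 0.02

#: Fixed low positivity of benign epithelium.
BENIGN_POSITIVITY = 0.05

REGION_CLASSES = ("invasive_tumour", "benign_epithelium", "carcinoma_in_situ", "stroma")


@dataclass
class SlideSpec:
    """Data-generating parameters for one synthetic case.

    Defaults give a 4×4 mm slide at 1 µm/px with ~3000 invasive-tumour
    nuclei per mm², a baseline Ki67 positive fraction of 0.15 rising to
    0.6 at the planted hotspot, two benign distractors and one
    high-positivity in-situ distractor, and a small serial offset.
    """

    width_um: float = 4000.0
    height_um: float = 4000.0
    resolution_um_per_px: float = 1.0
    tumour_density_per_mm2: float = 3000.0
    baseline_positivity: float = 0.15
    hotspot_center_um: tuple[float, float] | None = None
    hotspot_peak_positivity: float = 0.6
    hotspot_radius_um: float = 400.0
    benign_region_count: int = 2
    insitu_region_count: int = 1
    insitu_positivity: float = 0.7
    nucleus_diameter_range_um: tuple[float, float] = (6.0, 10.0)
    serial_shift_um: tuple[float, float] = (60.0, -40.0)
    serial_rotation_deg: float = 1.0
    serial_mode: str = "serial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hotspot_center_um is None:
            self.hotspot_center_um = (0.4 * self.width_um, 0.4 * self.height_um)
        self.validate()

    def validate(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise ConfigurationError("resolution must be positive")
        if not (0 <= self.baseline_positivity <= self.hotspot_peak_positivity <= 1):
            raise ConfigurationError(
                "need 0 <= baseline_positivity <= hotspot_peak_positivity <= 1"
            )
        if not (0 <= self.insitu_positivity <= 1):
            raise ConfigurationError("insitu_positivity outside [0, 1]")
        side = HOTSPOT_WINDOW_SIDE_UM
        if self.width_um < side or self.height_um < side:
            raise ConfigurationError("slide smaller than one hotspot window")
        cx, cy = self.hotspot_center_um
        if not (side / 2 <= cx <= self.width_um - side / 2
                and side / 2 <= cy <= self.height_um - side / 2):
            raise ConfigurationError(
                "hotspot window centred at hotspot_center_um exceeds the slide extent"
            )
        if self.serial_mode not in ("serial", "non_serial"):
            raise ConfigurationError("serial_mode must be 'serial' or 'non_serial'")
        if self.benign_region_count < 0 or self.insitu_region_count < 0:
            raise ConfigurationError("region counts must be non-negative")
        lo, hi = self.nucleus_diameter_range_um
        if not (0 < lo <= hi):
            raise ConfigurationError("bad nucleus diameter range")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.height_um / self.resolution_um_per_px)),
            int(round(self.width_um / self.resolution_um_per_px)),
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hotspot_center_um"] = list(self.hotspot_center_um)
        d["serial_shift_um"] = list(self.serial_shift_um)
        d["nucleus_diameter_range_um"] = list(self.nucleus_diameter_range_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SlideSpec":
        d = dict(d)
        for key in ("hotspot_center_um", "serial_shift_um", "nucleus_diameter_range_um"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RegionPolygon:
    """A tissue region: a valid polygon (µm) tagged with its class."""

    polygon: shapely.Geometry
    region_class: str

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("region polygon must be valid with positive area")


@dataclass
class SyntheticCase:
    """One simulated slide pair plus its vector ground truth."""

    ki67_image: np.ndarray
    ck_image: np.ndarray
    cells: pd.DataFrame
    regions: list[RegionPolygon]
    true_serial_transform: RigidTransform
    spec: SlideSpec

    @property
    def resolution_um_per_px(self) -> float:
        return self.spec.resolution_um_per_px

    def invasive_region(self) -> RegionPolygon:
        return next(r for r in self.regions if r.region_class == "invasive_tumour")


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _lobed_blob(centre, base_radius, rng, lobe_amplitude=0.18, n_vertices=180) -> Polygon:
    """Star-convex blob: radius modulated by a few random harmonics."""
    phases = rng.uniform(0, 2 * np.pi, size=4)
    amps = rng.uniform(0.2, 1.0, size=4) * lobe_amplitude
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = base_radius * (1 + sum(a * np.cos((k + 2) * phi + p)
                               for k, (a, p) in enumerate(zip(amps, phases))))
    r = np.maximum(r, 0.2 * base_radius)
    xy = np.column_stack([centre[0] + r * np.cos(phi), centre[1] + r * np.sin(phi)])
    return Polygon(xy)


def generate_regions(spec: SlideSpec, rng: np.random.Generator) -> list[RegionPolygon]:
    """Lay out the tissue regions of the Ki67 section.

    Exactly one invasive-tumour blob covering at least 30% of the slide and
    fully containing the hotspot window, the requested numbers of benign
    and in-situ distractor blobs placed in the surrounding stroma, and a
    stroma region making up the remainder.
    """
    spec.validate()
    slide = box(0, 0, spec.width_um, spec.height_um)
    cx, cy = spec.hotspot_center_um
    half = HOTSPOT_WINDOW_SIDE_UM / 2
    window = box(cx - half, cy - half, cx + half, cy + half)

    centre = (spec.width_um / 2, spec.height_um / 2)
    base_r = 0.40 * min(spec.width_um, spec.height_um)
    invasive = None
    for _ in range(40):
        blob = _lobed_blob(centre, base_r, rng)
        blob = blob.union(window.buffer(40, join_style="mitre")).intersection(
            slide.buffer(-1, join_style="mitre"))
        blob = shapely.make_valid(blob)
        if blob.geom_type == "MultiPolygon":
            blob = max(blob.geoms, key=lambda g: g.area)
        if blob.area >= 0.30 * slide.area and blob.contains(window):
            invasive = blob
            break
        base_r *= 1.05
    if invasive is None:
        raise GenerationError("could not build an invasive region containing the hotspot window")

    regions = [RegionPolygon(invasive, "invasive_tumour")]
    placed: list[Polygon] = []
    forbidden = invasive.buffer(30)
    counts = [("benign_epithelium", spec.benign_region_count),
              ("carcinoma_in_situ", spec.insitu_region_count)]
    for cls_name, count in counts:
        for _ in range(count):
            blob = None
            for _attempt in range(400):
                r = rng.uniform(80, 150)
                px = rng.uniform(r + 5, spec.width_um - r - 5)
                py = rng.uniform(r + 5, spec.height_um - r - 5)
                cand = _lobed_blob((px, py), r, rng, lobe_amplitude=0.12, n_vertices=60)
                cand = cand.intersection(slide.buffer(-1, join_style="mitre"))
                if cand.is_empty or cand.geom_type != "Polygon":
                    continue
                if cand.intersects(forbidden):
                    continue
                if any(cand.buffer(10).intersects(p) for p in placed):
                    continue
                blob = cand
                break
            if blob is None:
                raise GenerationError(f"could not place {cls_name} region off the tumour")
            placed.append(blob)
            regions.append(RegionPolygon(blob, cls_name))

    epithelium = shapely.unary_union([r.polygon for r in regions])
    stroma = slide.difference(epithelium)
    regions.append(RegionPolygon(stroma, "stroma"))
    return regions


def positivity_field(spec: SlideSpec, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
    """Planted Ki67-positive probability p(x, y) for invasive-tumour cells."""
    cx, cy = spec.hotspot_center_um
    d2 = (np.asarray(x_um) - cx) ** 2 + (np.asarray(y_um) - cy) ** 2
    bump = np.exp(-d2 / (2.0 * spec.hotspot_radius_um ** 2))
    return spec.baseline_positivity + (
        spec.hotspot_peak_positivity - spec.baseline_positivity) * bump


def planted_window_positivity(spec: SlideSpec, grid_step_um: float = 5.0) -> float:
    """Analytic mean of p(x, y) over the hotspot window centred on the plant."""
    cx, cy = spec.hotspot_center_um
    half = HOTSPOT_WINDOW_SIDE_UM / 2
    xs = np.arange(cx - half + grid_step_um / 2, cx + half, grid_step_um)
    ys = np.arange(cy - half + grid_step_um / 2, cy + half, grid_step_um)
    gx, gy = np.meshgrid(xs, ys)
    return float(np.mean(positivity_field(spec, gx, gy)))


def _hardcore_sample(polygon, n_target: int, diam_range, rng, max_batches: int = 10):
    """Dart-throwing hard-core process: centre separation >= the larger of
    the two nuclei's diameters. Returns (xy array, diameters array)."""
    if n_target == 0:
        return np.empty((0, 2)), np.empty(0)
    minx, miny, maxx, maxy = polygon.bounds
    cell = diam_range[1]  # grid pitch = max diameter = max interaction range
    grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    xs: list[float] = []
    ys: list[float] = []
    ds: list[float] = []
    for _batch in range(max_batches):
        need = n_target - len(xs)
        if need <= 0:
            break
        m = max(4 * need, 256)
        px = rng.uniform(minx, maxx, size=m)
        py = rng.uniform(miny, maxy, size=m)
        inside = shapely.contains_xy(polygon, px, py)
        pd_ = rng.uniform(diam_range[0], diam_range[1], size=m)
        for x, y, d in zip(px[inside], py[inside], pd_[inside]):
            gi, gj = int(x // cell), int(y // cell)
            ok = True
            for ni in (gi - 1, gi, gi + 1):
                for nj in (gj - 1, gj, gj + 1):
                    for ox, oy, od in grid.get((ni, nj), ()):
                        sep = max(d, od)
                        ddx = x - ox
                        ddy = y - oy
                        if ddx * ddx + ddy * ddy < sep * sep:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gi, gj), []).append((x, y, d))
                xs.append(x)
                ys.append(y)
                ds.append(d)
                if len(xs) >= n_target:
                    break
    if len(xs) < n_target:
        raise GenerationError(
            f"hard-core constraint incompatible with density: placed {len(xs)}/{n_target}"
        )
    return np.column_stack([xs, ys]), np.asarray(ds)


def sample_cells(spec: SlideSpec, regions: list[RegionPolygon],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Sample ground-truth nuclei in every epithelial region.

    Counts are Poisson(density × area); centres follow a hard-core process
    (separation at least one nucleus diameter); Ki67 class is Bernoulli in
    the planted positivity field for invasive cells, a fixed low rate for
    benign epithelium and ``insitu_positivity`` for carcinoma in situ.
    Stroma holds no cells.
    """
    frames = []
    next_id = 0
    for region in regions:
        if region.region_class == "stroma":
            continue
        area_mm2 = region.polygon.area / 1e6
        n = int(rng.poisson(spec.tumour_density_per_mm2 * area_mm2))
        xy, diam = _hardcore_sample(region.polygon, n, spec.nucleus_diameter_range_um, rng)
        if region.region_class == "invasive_tumour":
            p = positivity_field(spec, xy[:, 0], xy[:, 1])
        elif region.region_class == "benign_epithelium":
            p = np.full(n, BENIGN_POSITIVITY)
        else:
            p = np.full(n, spec.insitu_positivity)
        positive = rng.random(n) < p
        frames.append(pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "diameter_um": diam,
            "ki67_class": np.where(positive, "positive", "negative"),
            "region_class": region.region_class,
        }))
        next_id += n
    if not frames:
        return pd.DataFrame(columns=[
            "id", "x_um", "y_um", "diameter_um", "ki67_class", "region_class"])
    return pd.concat(frames, ignore_index=True)


def _paint_discs(h_od: np.ndarray, dab_od: np.ndarray, x_um, y_um, diam_um,
                 dab_flags, res: float, h_value: float, dab_value: float) -> None:
    """Anti-aliased maximum-composited discs on the OD canvases (in place)."""
    height, width = h_od.shape
    for x, y, d, is_dab in zip(np.asarray(x_um), np.asarray(y_um),
                               np.asarray(diam_um), np.asarray(dab_flags)):
        r = d / 2.0 / res
        cx, cy = x / res, y / res
        x0, x1 = int(max(0, cx - r - 2)), int(min(width, cx + r + 3))
        y0, y1 = int(max(0, cy - r - 2)), int(min(height, cy + r + 3))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
        alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
        patch = h_od[y0:y1, x0:x1]
        np.maximum(patch, h_value * alpha, out=patch)
        if is_dab:
            patch = dab_od[y0:y1, x0:x1]
            np.maximum(patch, dab_value * alpha, out=patch)


def _background_texture(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth faint haematoxylin texture, bounded by BACKGROUND_OD_MAX."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.standard_normal(shape), sigma=20, mode="reflect")
    span = np.ptp(noise)
    if span > 0:
        noise = (noise - noise.min()) / span
    else:
        noise = np.zeros(shape)
    return BACKGROUND_OD_MAX * (0.25 + 0.75 * noise)


def render_ki67_image(cells: pd.DataFrame, regions: list[RegionPolygon],
                      spec: SlideSpec, rng: np.random.Generator,
                      stains: StainMatrix | None = None) -> np.ndarray:
    """Render the Ki67 section: blue (haematoxylin) nuclei everywhere, brown
    (DAB) on Ki67-positive nuclei, over a faint background texture."""
    shape = spec.shape_px
    res = spec.resolution_um_per_px
    h_od = _background_texture(shape, rng)
    dab_od = np.zeros(shape)
    if len(cells):
        _paint_discs(h_od, dab_od, cells["x_um"], cells["y_um"], cells["diameter_um"],
                     cells["ki67_class"].to_numpy() == "positive",
                     res, NUCLEUS_H_OD, POSITIVE_DAB_OD)
    return forward_render(h_od, dab_od, stains)


def _alternate_layout(spec: SlideSpec, rng: np.random.Generator) -> list[Polygon]:
    """Unrelated fragmented epithelium for the non-serial corruption mode."""
    slide = box(0, 0, spec.width_um, spec.height_um)
    blobs = []
    n = int(rng.integers(5, 9))
    for _ in range(n):
        r = rng.uniform(0.08, 0.18) * min(spec.width_um, spec.height_um)
        px = rng.uniform(0, spec.width_um)
        py = rng.uniform(0, spec.height_um)
        cand = _lobed_blob((px, py), r, rng, lobe_amplitude=0.25, n_vertices=60)
        cand = cand.intersection(slide.buffer(-1, join_style="mitre"))
        if not cand.is_empty:
            blobs.append(cand)
    return blobs


def render_ck_serial(cells: pd.DataFrame, regions: list[RegionPolygon],
                     spec: SlideSpec, rng: np.random.Generator,
                     stains: StainMatrix | None = None
                     ) -> tuple[np.ndarray, RigidTransform]:
    """Render the serial CK8/18 section and return its true rigid transform.

    Epithelial regions carry a CK (DAB-like) blush; nuclei are re-rendered
    with ≤5 µm per-cell jitter emulating the 3 µm section offset. In
    ``non_serial`` mode the epithelial layout is regenerated from an
    unrelated seed so no rigid transform aligns the pair.
    """
    res = spec.resolution_um_per_px
    shape = spec.shape_px
    centre = (spec.width_um / 2, spec.height_um / 2)
    transform = RigidTransform(spec.serial_shift_um[0], spec.serial_shift_um[1],
                               spec.serial_rotation_deg)

    h_od = _background_texture(shape, rng)
    dab_od = np.zeros(shape)

    if spec.serial_mode == "non_serial":
        geoms = _alternate_layout(spec, rng)
        ck_mask = rasterize_polygons(geoms, shape, res)
        dab_od += CK_DAB_OD * ck_mask
    else:
        epithelial = [r.polygon for r in regions if r.region_class != "stroma"]
        moved = [
            shapely.affinity.translate(
                shapely.affinity.rotate(g, transform.theta_deg, origin=centre),
                transform.dx_um, transform.dy_um)
            for g in epithelial
        ]
        ck_mask = rasterize_polygons(moved, shape, res)
        dab_od += CK_DAB_OD * ck_mask
        if len(cells):
            pts = transform.apply(cells[["x_um", "y_um"]].to_numpy(), centre)
            ang = rng.uniform(0, 2 * np.pi, size=len(pts))
            rad = 5.0 * np.sqrt(rng.random(len(pts)))
            pts = pts + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            _paint_discs(h_od, dab_od, pts[:, 0], pts[:, 1],
                         cells["diameter_um"].to_numpy(),
                         np.zeros(len(pts), dtype=bool),
                         res, CK_NUCLEUS_H_OD, 0.0)
    return forward_render(h_od, np.clip(dab_od, 0, None), stains), transform


def rasterize_polygons(geoms, shape_px, resolution_um_per_px: float) -> np.ndarray:
    """Rasterize µm-space polygons (with holes) into a boolean pixel mask."""
    img = Image.new("1", (shape_px[1], shape_px[0]), 0)
    draw = ImageDraw.Draw(img)
    res = resolution_um_per_px

    def draw_poly(poly, value):
        ext = [(x / res, y / res) for x, y in np.asarray(poly.exterior.coords)]
        draw.polygon(ext, fill=value)

    flat = []
    for g in geoms:
        g = g.polygon if isinstance(g, RegionPolygon) else g
        if g.is_empty:
            continue
        if g.geom_type == "MultiPolygon":
            flat.extend(g.geoms)
        elif g.geom_type == "Polygon":
            flat.append(g)
    for poly in flat:
        draw_poly(poly, 1)
    for poly in flat:
        for hole in poly.interiors:
            pts = [(x / res, y / res) for x, y in np.asarray(hole.coords)]
            draw.polygon(pts, fill=0)
    return np.asarray(img, dtype=bool)


def generate_case(spec: SlideSpec, render: bool = True) -> SyntheticCase:
    """Generate a full case (regions, cells and — optionally — both images).

    With ``render=False`` the images are left as empty arrays; cell-level
    analyses (hotspot search, observer simulation) do not need rasters and
    run orders of magnitude faster without them.
    """
    rng_regions, rng_cells, rng_ki67, rng_ck = _rng_streams(spec.seed, 4)
    regions = generate_regions(spec, rng_regions)
    cells = sample_cells(spec, regions, rng_cells)
    if render:
        ki67 = render_ki67_image(cells, regions, spec, rng_ki67)
        ck, transform = render_ck_serial(cells, regions, spec, rng_ck)
    else:
        ki67 = np.empty((0, 0, 3), dtype=np.uint8)
        ck = np.empty((0, 0, 3), dtype=np.uint8)
        transform = RigidTransform(spec.serial_shift_um[0], spec.serial_shift_um[1],
                                   spec.serial_rotation_deg)
    return SyntheticCase(ki67, ck, cells, regions, transform, spec)


# ---------------------------------------------------------------------------
# Case I/O


def _write_tiff(path: Path, image: np.ndarray, res_um: float) -> None:
    import tifffile

    tifffile.imwrite(
        path, image, photometric="rgb",
        resolution=(1e4 / res_um, 1e4 / res_um), resolutionunit="CENTIMETER",
        description=json.dumps({"resolution_um_per_px": res_um}),
    )


def read_tiff(path) -> tuple[np.ndarray, float]:
    """Read an RGB TIFF and its µm/px resolution (description JSON, falling
    back to the TIFF resolution tags)."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        image = page.asarray()
        res = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                res = float(json.loads(desc.value)["resolution_um_per_px"])
            except (ValueError, KeyError, TypeError):
                res = None
        if res is None:
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                res = 1e4 * den / num
        if res is None:
            raise ValueError(f"{path}: no resolution metadata")
    return image, res


def write_case(case: SyntheticCase, directory) -> dict:
    """Write a case to disk; returns the manifest (file → sha256)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    res = case.resolution_um_per_px

    _write_tiff(directory / "ki67.tif", case.ki67_image, res)
    _write_tiff(directory / "ck.tif", case.ck_image, res)
    case.cells.to_csv(directory / "cells.csv", index=False,
                      columns=["id", "x_um", "y_um", "diameter_um",
                               "ki67_class", "region_class"])
    features = [
        {"type": "Feature",
         "properties": {"region_class": r.region_class},
         "geometry": mapping(r.polygon)}
        for r in case.regions
    ]
    with open(directory / "regions.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    with open(directory / "case.json", "w") as fh:
        json.dump({"spec": case.spec.as_dict(),
                   "true_serial_transform": case.true_serial_transform.as_dict()},
                  fh, indent=2)

    manifest = {}
    for name in ("ki67.tif", "ck.tif", "cells.csv", "regions.geojson", "case.json"):
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_case(directory) -> SyntheticCase:
    """Round-trip reader for :func:`write_case` output."""
    directory = Path(directory)
    with open(directory / "case.json") as fh:
        meta = json.load(fh)
    spec = SlideSpec.from_dict(meta["spec"])
    transform = RigidTransform(**meta["true_serial_transform"])
    ki67, _ = read_tiff(directory / "ki67.tif")
    ck, _ = read_tiff(directory / "ck.tif")
    cells = pd.read_csv(directory / "cells.csv")
    with open(directory / "regions.geojson") as fh:
        fc = json.load(fh)
    regions = [RegionPolygon(geo_shape(f["geometry"]), f["properties"]["region_class"])
               for f in fc["features"]]
    return SyntheticCase(ki67, ck, cells, regions, transform, spec)
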