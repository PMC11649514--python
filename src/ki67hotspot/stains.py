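"""Beer–Lambert two-stain optical model (haematoxylin + DAB).

Both the synthetic-slide generator and the nucleus detector speak this
model: the generator composes per-pixel stain optical densities into an
8-bit RGB raster, and the detector inverts that raster back into per-stain
concentration maps by least-squares colour deconvolution.

Conventions
-----------
* Optical density per channel: ``OD_c = -log10((I_c + 1) / 256)`` so that a
  saturated white pixel maps to exactly zero OD and the guard term never
  produces infinities at ``I = 0``.
* Forward rendering: ``I_c = round(255 * 10**(-OD_c))`` clipped to [0, 255].
* Deconvolution: unweighted least-squares projection of the 3-vector OD
  pixel onto the two stain vectors; the component along the residual
  (cross-product) direction is discarded, so adding any multiple of the
  residual vector to a pixel leaves the output unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StainMatrix", "ODImage", "rgb_to_od", "deconvolve", "forward_render"]

#: Ruifrok–Johnston haematoxylin / DAB optical-density vectors (unnormalized).
RUIFROK_HAEMATOXYLIN = (0.65, 0.70, 0.29)
RUIFROK_DAB = (0.27, 0.57, 0.78)

#: Optical densities are clamped at this value when reading 8-bit images.
OD_CLAMP = 3.0

#: Small negative concentrations from noise are clamped here at read-out.
CONC_FLOOR = -0.05


@dataclass(frozen=True)
class StainMatrix:
    """Pair of unit-norm stain vectors in RGB optical-density space.

    Attributes
    ----------
    vectors : (2, 3) ndarray
        Row 0 haematoxylin, row 1 DAB, each unit norm.
    residual : (3,) ndarray
        Normalized cross product of the two stain vectors; the direction
        carrying no stain information.
    """

    vectors: np.ndarray
    residual: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (2, 3):
            raise ValueError("StainMatrix needs exactly two 3-vectors")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        v = v / norms[:, None]
        cosang = abs(float(v[0] @ v[1]))
        if cosang > np.cos(np.deg2rad(10.0)):
            raise ValueError("stain vectors closer than 10 degrees; matrix ill-conditioned")
        res = np.cross(v[0], v[1])
        res = res / np.linalg.norm(res)
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "residual", res)

    @classmethod
    def ruifrok(cls) -> "StainMatrix":
        """Default haematoxylin/DAB basis (Ruifrok–Johnston, normalized)."""
        return cls(np.array([RUIFROK_HAEMATOXYLIN, RUIFROK_DAB]))

    @classmethod
    def from_json(cls, path) -> "StainMatrix":
        with open(path) as fh:
            data = json.load(fh)
        return cls(np.array([data["haematoxylin"], data["dab"]], dtype=float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"haematoxylin": self.vectors[0].tolist(), "dab": self.vectors[1].tolist()},
                fh,
                indent=2,
            )

    @property
    def matrix(self) -> np.ndarray:
        """(3, 2) matrix with stain vectors as columns."""
        return self.vectors.T

    @property
    def pinv(self) -> np.ndarray:
        """(2, 3) least-squares projector onto the stain basis."""
        return np.linalg.pinv(self.matrix)


@dataclass
class ODImage:
    """Per-pixel haematoxylin / DAB concentration maps.

    ``haematoxylin`` and ``dab`` are float rasters of equal shape in stain
    concentration units (optical density along each unit stain vector).
    """

    haematoxylin: np.ndarray
    dab: np.ndarray
    resolution_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.haematoxylin.shape != self.dab.shape:
            raise ValueError("channel shape mismatch")


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to per-channel optical densities.

    ``OD_c = -log10((I_c + 1) / 256)``, clamped at :data:`OD_CLAMP`.
    White (255) maps to exactly 0; black (0) maps to log10(256) ≈ 2.41.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    od = -np.log10((rgb.astype(np.float64) + 1.0) / 256.0)
    return np.minimum(od, OD_CLAMP)


def deconvolve(od: np.ndarray, stains: StainMatrix | None = None,
               resolution_um_per_px: float = 1.0) -> ODImage:
    """Project a 3-channel OD raster onto the stain basis.

    Least-squares per pixel; small negatives (quantization/noise leakage)
    are clamped at :data:`CONC_FLOOR`.
    """
    if stains is None:
        stains = StainMatrix.ruifrok()
    od = np.asarray(od, dtype=np.float64)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) OD raster")
    conc = od @ stains.pinv.T
    conc = np.maximum(conc, CONC_FLOOR)
    return ODImage(conc[..., 0], conc[..., 1], resolution_um_per_px)


def forward_render(h_od: np.ndarray, dab_od: np.ndarray,
                   stains: StainMatrix | None = None) -> np.ndarray:
    """Compose stain concentration rasters into an 8-bit RGB image.

    ``I_c = round(256 * 10**(-(H*S_H,c + DAB*S_DAB,c))) - 1``, the exact
    quantized inverse of :func:`rgb_to_od`; zero ODs render white (255).
    Raises on negative inputs — the generator must clamp first.
    """
    if stains is None:
        stains = StainMatrix.ruifrok()
    h_od = np.asarray(h_od, dtype=np.float64)
    dab_od = np.asarray(dab_od, dtype=np.float64)
    if h_od.shape != dab_od.shape:
        raise ValueError("OD raster shape mismatch")
    if np.any(h_od < 0) or np.any(dab_od < 0):
        raise ValueError("negative optical densities")
    od = h_od[..., None] * stains.vectors[0] + dab_od[..., None] * stains.vectors[1]
    img = np.round(256.0 * 10.0 ** (-od)) - 1.0
    return np.clip(img, 0, 255).astype(np.uint8)
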