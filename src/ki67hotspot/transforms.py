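"""Rigid in-plane transforms between serial sections.

A transform maps a point ``p`` (µm) in the reference (Ki67-section) frame to
``p' = R(theta) @ (p - c) + c + t`` where ``c`` is the image centre and
``t = (dx, dy)``. Rotation is counter-clockwise in the (x right, y down)
µm coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform"]


@dataclass(frozen=True)
class RigidTransform:
    dx_um: float
    dy_um: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.dx_um, self.dy_um, self.theta_deg])):
            raise ValueError("non-finite transform")
        if abs(self.theta_deg) > 180:
            raise ValueError("|theta| must be <= 180 degrees")

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points_um: np.ndarray, centre_um) -> np.ndarray:
        """Transform an (n, 2) array of µm points about ``centre_um``."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        c = np.asarray(centre_um, dtype=float)
        out = (pts - c) @ self.rotation_matrix.T + c + [self.dx_um, self.dy_um]
        return out

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one (about the same centre)."""
        r_inv = RigidTransform(0.0, 0.0, -self.theta_deg).rotation_matrix
        t_inv = -(r_inv @ [self.dx_um, self.dy_um])
        return RigidTransform(float(t_inv[0]), float(t_inv[1]), -self.theta_deg)

    def as_dict(self) -> dict:
        return {"dx_um": self.dx_um, "dy_um": self.dy_um, "theta_deg": self.theta_deg}

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)
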