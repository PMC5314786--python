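"""Spherocylindrical cell geometry.

An *E. coli* cell is modelled as a cylinder of radius ``r`` capped by two
hemispheres, with tip-to-tip length ``L`` (so the cylindrical part has length
``L - 2r``). Simulations work in the *cell frame*: the long axis is x, the
cell centre is the origin. ``center`` and ``orientation`` place the cell in
the lab frame for rendering and for pooling localizations across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate cell geometries."""


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylinder: tip-to-tip ``length``, cap/cylinder ``radius`` (um)."""

    length: float = 3.0
    radius: float = 0.5
    center: tuple = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("radius must be > 0")
        if self.length < 2 * self.radius:
            raise GeometryError("length must be >= 2*radius (spherocylinder)")

    @property
    def half_axis(self) -> float:
        """Half-length of the cylindrical midsection (distance from the
        centre to either cap centre)."""
        return self.length / 2.0 - self.radius

    def axial_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of cell-frame points (n, 3) from the midline segment."""
        p = np.atleast_2d(points)
        ax = np.clip(p[:, 0], -self.half_axis, self.half_axis)
        d = p.copy()
        d[:, 0] -= ax
        return np.linalg.norm(d, axis=1)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which cell-frame points lie inside the cell."""
        return self.axial_distance(points) <= self.radius + tol

    def local_half_width(self, x: np.ndarray) -> np.ndarray:
        """Half-width of the outline at axial coordinate x (cell frame).

        Equal to the radius along the cylindrical part; follows the
        hemispherical profile sqrt(r^2 - (|x| - h)^2) inside the caps.
        """
        x = np.asarray(x, dtype=float)
        over = np.abs(x) - self.half_axis
        w = np.where(over <= 0, self.radius,
                     np.sqrt(np.maximum(self.radius ** 2 - over ** 2, 0.0)))
        return w

    def to_lab(self, points_xy: np.ndarray) -> np.ndarray:
        """Map cell-frame (n, 2) xy points into the lab frame."""
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return points_xy @ rot.T + np.asarray(self.center)

    def to_cell(self, points_xy: np.ndarray) -> np.ndarray:
        """Map lab-frame (n, 2) xy points into the cell frame."""
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return (np.atleast_2d(points_xy) - np.asarray(self.center)) @ rot

    def to_dict(self) -> dict:
        return {
            "length_um": self.length,
            "radius_um": self.radius,
            "center": list(self.center),
            "orientation": self.orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellGeometry":
        return cls(length=d["length_um"], radius=d["radius_um"],
                   center=tuple(d.get("center", (0.0, 0.0))),
                   orientation=d.get("orientation", 0.0))


def reflect_into(points: np.ndarray, geometry: CellGeometry,
                 max_iter: int = 16) -> np.ndarray:
    """Fold cell-frame points that escaped the spherocylinder back inside.

    Reflection is radial about the nearest midline point: a point at distance
    d > r from the axis segment is mapped to distance 2r - d along the same
    radial direction (specular reflection for small overshoots, applied
    iteratively for rare large ones). This boundary condition preserves the
    uniform equilibrium distribution.
    """
    p = np.array(points, dtype=float, copy=True)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    r = geometry.radius
    for _ in range(max_iter):
        ax = np.clip(p[:, 0], -geometry.half_axis, geometry.half_axis)
        rad = p.copy()
        rad[:, 0] -= ax
        d = np.linalg.norm(rad, axis=1)
        out = d > r
        if not out.any():
            break
        # scale the radial component to the folded distance 2r - d
        scale = np.abs(2.0 * r - d[out]) / np.maximum(d[out], 1e-300)
        p[out] = np.column_stack([ax[out], np.zeros_like(ax[out]),
                                  np.zeros_like(ax[out])]) + rad[out] * scale[:, None]
    return p[0] if single else p
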