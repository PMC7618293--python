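"""Spherocylindrical cell geometry.

Rod-shaped bacteria such as *E. coli* are modelled as spherocylinders: a
cylinder of radius ``radius_um`` capped by two hemispheres, giving a total
pole-to-pole length ``length_um``.  All simulation happens in a local frame
with the long axis along x and the cell centred at the origin; geometries
also carry a position and orientation in the imaging field so that rendered
or tabulated localizations live in field coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CellGeometry:
    """One spherocylindrical cell.

    Parameters
    ----------
    length_um : float
        Pole-to-pole length (cap to cap), micrometers.
    radius_um : float
        Cylinder/cap radius, micrometers.
    nucleoid_fraction : float
        Fraction of the cell length occupied by the centred nucleoid zone.
    center_xy_um : tuple of float
        Cell centre in field coordinates (x, y), micrometers.
    orientation_rad : float
        Angle of the long axis relative to the field x axis.
    cell_id : int
        Identifier used in localization tables and outlines.
    """

    length_um: float
    radius_um: float
    nucleoid_fraction: float = 0.8
    center_xy_um: tuple[float, float] = (0.0, 0.0)
    orientation_rad: float = 0.0
    cell_id: int = 0

    def __post_init__(self) -> None:
        if self.length_um < 2.0 * self.radius_um:
            raise ValueError(
                f"length_um ({self.length_um}) must be >= 2*radius_um "
                f"({2 * self.radius_um})"
            )
        if not 0.0 <= self.nucleoid_fraction <= 1.0:
            raise ValueError("nucleoid_fraction must lie in [0, 1]")

    @property
    def half_axis_um(self) -> float:
        """Half-length of the cylindrical segment of the long axis."""
        return self.length_um / 2.0 - self.radius_um

    # ---- containment -------------------------------------------------

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Vectorized inside test for local-frame points of shape (..., 3)."""
        return self._axis_distance(xyz) <= self.radius_um

    def _axis_distance(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        h = self.half_axis_um
        ax = np.clip(xyz[..., 0], -h, h)
        dx = xyz[..., 0] - ax
        return np.sqrt(dx**2 + xyz[..., 1] ** 2 + xyz[..., 2] ** 2)

    def reflect_inside(self, xyz: np.ndarray, max_iter: int = 8) -> np.ndarray:
        """Mirror points that left the cell back across the local boundary.

        Points are mirrored across the tangent plane at the nearest surface
        point (radial distance rho -> 2R - rho).  For the sub-frame step
        sizes used here a couple of iterations suffice; stragglers are
        clamped just inside the surface.
        """
        out = np.array(xyz, dtype=float)
        h = self.half_axis_um
        R = self.radius_um
        for _ in range(max_iter):
            ax = np.clip(out[..., 0], -h, h)
            rad = out.copy()
            rad[..., 0] -= ax
            rho = np.sqrt(np.sum(rad**2, axis=-1))
            outside = rho > R
            if not np.any(outside):
                return out
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = (2.0 * R - rho) / rho
            scale = np.where(rho > 0, scale, 1.0)
            upd = rad * scale[..., None]
            upd[..., 0] += ax
            out = np.where(outside[..., None], upd, out)
        # clamp whatever still escaped (pathologically long steps)
        ax = np.clip(out[..., 0], -h, h)
        rad = out.copy()
        rad[..., 0] -= ax
        rho = np.sqrt(np.sum(rad**2, axis=-1))
        outside = rho > R
        if np.any(outside):
            scale = (R * (1 - 1e-9)) / np.where(rho > 0, rho, 1.0)
            upd = rad * scale[..., None]
            upd[..., 0] += ax
            out = np.where(outside[..., None], upd, out)
        return out

    # ---- zones -------------------------------------------------------

    def in_nucleoid(self, xyz: np.ndarray) -> np.ndarray:
        """Centred ellipsoid: semi-axis nucleoid_fraction*L/2 along x, R across."""
        xyz = np.asarray(xyz, dtype=float)
        a = max(self.nucleoid_fraction * self.length_um / 2.0, 1e-12)
        q = (
            (xyz[..., 0] / a) ** 2
            + (xyz[..., 1] / self.radius_um) ** 2
            + (xyz[..., 2] / self.radius_um) ** 2
        )
        return q <= 1.0

    def zone_mask(self, xyz: np.ndarray, zone: str) -> np.ndarray:
        inside = self.contains(xyz)
        if zone == "whole_cell":
            return inside
        if zone == "nucleoid":
            return inside & self.in_nucleoid(xyz)
        if zone == "nucleoid_periphery":
            # shell between 70% and 100% of the nucleoid ellipsoid
            a = max(self.nucleoid_fraction * self.length_um / 2.0, 1e-12)
            q = (
                (xyz[..., 0] / a) ** 2
                + (xyz[..., 1] / self.radius_um) ** 2
                + (xyz[..., 2] / self.radius_um) ** 2
            )
            return inside & (q <= 1.0) & (q >= 0.7**2)
        raise ValueError(f"unknown zone {zone!r}")

    def sample_position(self, zone: str, rng: np.random.Generator) -> np.ndarray:
        """Uniform point in the requested zone, by rejection sampling."""
        L2, R = self.length_um / 2.0, self.radius_um
        for _ in range(10_000):
            p = rng.uniform([-L2, -R, -R], [L2, R, R], size=(64, 3))
            ok = self.zone_mask(p, zone)
            if np.any(ok):
                return p[np.argmax(ok)]
        raise RuntimeError(f"failed to sample a point in zone {zone!r}")

    # ---- field <-> local frames -------------------------------------

    def to_field(self, xy_local: np.ndarray) -> np.ndarray:
        """Rotate/translate local (x, y) points into field coordinates."""
        xy_local = np.asarray(xy_local, dtype=float)
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        x = c * xy_local[..., 0] - s * xy_local[..., 1] + self.center_xy_um[0]
        y = s * xy_local[..., 0] + c * xy_local[..., 1] + self.center_xy_um[1]
        return np.stack([x, y], axis=-1)

    def outline_polygon(self, n_arc: int = 16) -> np.ndarray:
        """Closed 2D outline polygon in field coordinates, shape (N, 2)."""
        h, R = self.half_axis_um, self.radius_um
        th = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
        right = np.stack([h + R * np.cos(th), R * np.sin(th)], axis=-1)
        left = np.stack([-h - R * np.cos(th), -R * np.sin(th)], axis=-1)
        local = np.concatenate([right[::-1], left[::-1]])
        return self.to_field(local)


def sample_cells(
    n_cells: int,
    length_range_um: tuple[float, float] = (2.0, 3.0),
    radius_um: float = 0.45,
    seed: int | np.random.Generator | None = None,
    field_um: tuple[float, float] | None = None,
    margin_um: float = 0.5,
    nucleoid_fraction: float = 0.8,
) -> list[CellGeometry]:
    """Place ``n_cells`` non-overlapping cells in a rectangular field.

    Lengths are uniform in ``length_range_um``; orientations are uniform in
    [0, pi).  Overlap is tested conservatively on bounding circles.  If
    ``field_um`` is omitted a field large enough for the requested density
    is chosen automatically.

    Raises
    ------
    RuntimeError
        If the field is too small to place all cells without overlap.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = length_range_um
    if lo <= 0 or hi < lo:
        raise ValueError("length_range_um must be a positive interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if field_um is None:
        # ~4x the summed bounding-circle area keeps rejection cheap
        side = max(4.0, math.sqrt(n_cells) * (hi + 2 * margin_um) * 1.6)
        field_um = (side, side)

    cells: list[CellGeometry] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for cid in range(n_cells):
        length = rng.uniform(lo, hi)
        rad_bound = length / 2.0 + margin_um / 2.0
        placed = False
        for _ in range(20_000):
            cx = rng.uniform(rad_bound, field_um[0] - rad_bound)
            cy = rng.uniform(rad_bound, field_um[1] - rad_bound)
            c = np.array([cx, cy])
            if all(
                np.hypot(*(c - c2)) > rad_bound + r2 for c2, r2 in zip(centers, radii)
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {cid} of {n_cells} in a "
                f"{field_um[0]:.1f}x{field_um[1]:.1f} um field without overlap"
            )
        cells.append(
            CellGeometry(
                length_um=length,
                radius_um=radius_um,
                nucleoid_fraction=nucleoid_fraction,
                center_xy_um=(float(cx), float(cy)),
                orientation_rad=float(rng.uniform(0.0, np.pi)),
                cell_id=cid,
            )
        )
        centers.append(c)
        radii.append(rad_bound)
    return cells
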