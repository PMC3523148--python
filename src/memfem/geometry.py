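"""Thin-ring membrane geometry with ion-channel holes.

A biological cell at low frequency is modelled as a thin insulating
annulus (the membrane) immersed in saline: conductivity drops from the
background value ``sigma0`` to ``sigmaA`` inside the ring.  Ions can
only pass where holes are punched through the ring, so the hole pattern
controls the apparent (macroscopic) conductivity of the tissue.

The anomaly region ``A`` is the union of closed annuli minus open hole
disks.  A hole is the open disk of a given diameter centred on the ring
mid-circle at a stated angle; ring material inside the disk is removed
(replaced by background saline).  The annulus is closed and the holes
are open -- a measure-zero convention fixed so that deterministic point
tests are well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellSpec",
    "MembraneGeometry",
    "make_cell",
    "place_cells",
    "chi_A",
    "exact_membrane_area",
    "DEFAULT_DOMAIN",
]

#: The canonical square domain, side length 0.2 centred at the origin.
DEFAULT_DOMAIN: tuple[float, float, float, float] = (-0.1, 0.1, -0.1, 0.1)


@dataclass(frozen=True)
class CellSpec:
    """One annular cell: a thin ring of membrane with optional holes.

    Parameters
    ----------
    center
        Cell centre in domain coordinates.
    outer_radius
        Outer radius of the ring (default 0.01, i.e. diameter 0.02).
    thickness
        Membrane thickness ``delta`` (default 0.002).
    hole_angles
        Angles of hole centres in degrees, counter-clockwise from +x.
    hole_diameter
        Diameter of the (open) hole disks (default 0.005).
    """

    center: tuple[float, float]
    outer_radius: float = 0.01
    thickness: float = 0.002
    hole_angles: tuple[float, ...] = ()
    hole_diameter: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.thickness < self.outer_radius:
            raise ValueError(
                f"need 0 < thickness < outer_radius, got "
                f"thickness={self.thickness}, outer_radius={self.outer_radius}"
            )
        n_holes = len(self.hole_angles)
        if n_holes > 0:
            max_d = 2.0 * math.pi * self.mid_radius / n_holes
            if self.hole_diameter >= max_d:
                raise ValueError(
                    f"hole_diameter={self.hole_diameter} too large: holes "
                    f"would overlap (limit {max_d:.4g} for {n_holes} holes)"
                )

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.thickness

    @property
    def mid_radius(self) -> float:
        """Radius of the circle on which hole centres sit."""
        return 0.5 * (self.outer_radius + self.inner_radius)

    @property
    def hole_radius(self) -> float:
        return 0.5 * self.hole_diameter

    @property
    def hole_centers(self) -> np.ndarray:
        """(n_holes, 2) array of hole-disk centres on the mid-circle."""
        ang = np.deg2rad(np.asarray(self.hole_angles, dtype=float))
        cx, cy = self.center
        return np.column_stack(
            [cx + self.mid_radius * np.cos(ang), cy + self.mid_radius * np.sin(ang)]
        )


@dataclass(frozen=True)
class MembraneGeometry:
    """The anomaly region ``A``: a collection of ring cells inside a box.

    Validates that every ring lies strictly inside the domain and that
    rings of distinct cells are pairwise disjoint.
    """

    cells: tuple[CellSpec, ...]
    domain: tuple[float, float, float, float] = DEFAULT_DOMAIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        xmin, xmax, ymin, ymax = self.domain
        for c in self.cells:
            cx, cy = c.center
            r = c.outer_radius
            if not (xmin < cx - r and cx + r < xmax and ymin < cy - r and cy + r < ymax):
                raise ValueError(f"cell at {c.center} touches the domain boundary")
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1 :]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.outer_radius + b.outer_radius:
                    raise ValueError(
                        f"cells at {a.center} and {b.center} overlap or touch"
                    )

    def chi(self, points: np.ndarray) -> np.ndarray:
        """Characteristic function of ``A`` evaluated at an (n, 2) array.

        Returns a float array of 0.0 / 1.0.  A point is in ``A`` iff it
        lies in some cell's closed annulus and in none of that cell's
        open hole disks.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(pts.shape[0])
        for c in self.cells:
            d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
            in_ring = (d >= c.inner_radius) & (d <= c.outer_radius)
            if not in_ring.any():
                continue
            for hc in c.hole_centers:
                dh = np.hypot(pts[:, 0] - hc[0], pts[:, 1] - hc[1])
                in_ring &= dh >= c.hole_radius  # open hole: boundary stays membrane
            out[in_ring] = 1.0
        return out


def make_cell(
    center: tuple[float, float],
    n_holes: int = 4,
    orientation: str = "compass",
    *,
    outer_radius: float = 0.01,
    thickness: float = 0.002,
    hole_diameter: float = 0.005,
) -> CellSpec:
    """Build a canonical cell with 0, 2 or 4 holes.

    ``n_holes=4`` places holes at 0/90/180/270 degrees (orthogonal to
    each other); ``n_holes=2`` with ``orientation='horizontal'`` puts
    them at the left and right end points of the circle (0/180), with
    ``'vertical'`` at top and bottom (90/270); ``n_holes=0`` is a closed
    insulating ring.
    """
    if n_holes == 0:
        angles: tuple[float, ...] = ()
    elif n_holes == 2:
        if orientation == "horizontal":
            angles = (0.0, 180.0)
        elif orientation == "vertical":
            angles = (90.0, 270.0)
        else:
            raise ValueError(
                f"n_holes=2 requires orientation 'horizontal' or 'vertical', "
                f"got {orientation!r}"
            )
    elif n_holes == 4:
        angles = (0.0, 90.0, 180.0, 270.0)
    else:
        raise ValueError(f"unsupported n_holes={n_holes}; expected 0, 2 or 4")
    return CellSpec(
        center=tuple(center),
        outer_radius=outer_radius,
        thickness=thickness,
        hole_angles=angles,
        hole_diameter=hole_diameter,
    )


def place_cells(
    n_cells: int,
    cell_template: CellSpec,
    *,
    spacing: float = 0.04,
    domain: tuple[float, float, float, float] = DEFAULT_DOMAIN,
) -> MembraneGeometry:
    """Place 1, 9 or 25 copies of a cell on a grid centred at the origin.

    One cell sits at the origin; 9 cells form a 3x3 grid and 25 cells a
    5x5 grid with the given centre-to-centre spacing (default 0.04).
    """
    side = {1: 1, 9: 3, 25: 5}.get(n_cells)
    if side is None:
        raise ValueError(f"n_cells must be one of 1, 9, 25; got {n_cells}")
    offs = (np.arange(side) - (side - 1) / 2.0) * spacing
    cells = []
    for oy in offs:
        for ox in offs:
            cells.append(
                CellSpec(
                    center=(float(ox), float(oy)),
                    outer_radius=cell_template.outer_radius,
                    thickness=cell_template.thickness,
                    hole_angles=cell_template.hole_angles,
                    hole_diameter=cell_template.hole_diameter,
                )
            )
    return MembraneGeometry(cells=tuple(cells), domain=domain)


def chi_A(p, geom: MembraneGeometry) -> np.ndarray | float:
    """Characteristic function of the membrane region at point(s) ``p``.

    Accepts a single (x, y) pair or an (n, 2) array; returns a scalar or
    an array of 0.0 / 1.0 accordingly.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    out = geom.chi(p)
    return float(out[0]) if single else out


def _cell_polygon(cell: CellSpec, quad_segs: int):
    """Shapely polygon of one cell's membrane: annulus minus hole disks."""
    from shapely.geometry import Point

    ring = Point(cell.center).buffer(cell.outer_radius, quad_segs=quad_segs).difference(
        Point(cell.center).buffer(cell.inner_radius, quad_segs=quad_segs)
    )
    for hc in cell.hole_centers:
        ring = ring.difference(Point(hc).buffer(cell.hole_radius, quad_segs=quad_segs))
    return ring


def membrane_polygon(geom: MembraneGeometry, quad_segs: int = 256):
    """Polygonal approximation of ``A`` (e.g. for WKT export or clipping)."""
    from shapely.ops import unary_union

    return unary_union([_cell_polygon(c, quad_segs) for c in geom.cells])


def exact_membrane_area(geom: MembraneGeometry, rtol: float = 1e-6) -> float:
    """Area of ``A`` by polygon clipping, refined to relative ``rtol``.

    Circles are approximated by polygons whose resolution is doubled
    until the clipped area changes by less than ``rtol`` relatively.
    Serves as the independent oracle for quadrature-based area sums.
    """
    if not geom.cells:
        return 0.0
    quad_segs = 64
    prev = sum(_cell_polygon(c, quad_segs).area for c in geom.cells)
    for _ in range(12):
        quad_segs *= 2
        cur = sum(_cell_polygon(c, quad_segs).area for c in geom.cells)
        if abs(cur - prev) <= rtol * abs(cur):
            return cur
        prev = cur
    return prev
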