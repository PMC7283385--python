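"""Vessel cross-section metrics.

A cross-section is described either by a closed planar contour (mm) or
directly by its area and perimeter.  The derived quantity used throughout
is the hydraulic diameter D_h = 4A/P, which equals the geometric diameter
for a circle and degrades gracefully for the irregular lumen shapes seen at
a coarctation.  The severity index is the coarctation ratio: coarctation
D_h divided by the descending-aorta D_h at the level of the diaphragm.
Outlet patches of a CFD model are extruded by a multiple (default 10×) of
their hydraulic diameter to keep recirculation away from the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import InvalidGeometryError, InvalidParameterError

__all__ = [
    "CrossSection",
    "PatchGeometry",
    "polygon_metrics",
    "hydraulic_diameter",
    "coarctation_ratio",
    "extension_length",
    "plane_cut_contour",
    "min_hydraulic_diameter",
    "read_contour",
    "geometry_report",
]


def polygon_metrics(contour: np.ndarray) -> Tuple[float, float]:
    """Area (mm²) and perimeter (mm) of a closed planar contour.

    ``contour`` is an (N, 2) array of points in mm; the closing segment from
    last to first point is implicit (a repeated closing point is accepted).
    Area is the absolute shoelace value, perimeter the summed segment
    lengths; the result is independent of vertex orientation.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidGeometryError("contour must be an (N, 2) point array")
    if np.allclose(pts[0], pts[-1]) and len(pts) > 3:
        pts = pts[:-1]
    if len(pts) < 3:
        raise InvalidGeometryError("contour needs at least 3 distinct points")
    poly = Polygon(pts)
    if not poly.is_valid or poly.area == 0:
        raise InvalidGeometryError("contour is self-intersecting or degenerate")
    return float(poly.area), float(poly.exterior.length)


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """D_h = 4·area/perimeter (mm for mm²/mm inputs)."""
    if area <= 0 or perimeter <= 0:
        raise InvalidParameterError("area and perimeter must be positive")
    return 4.0 * area / perimeter


@dataclass(frozen=True)
class CrossSection:
    """A vessel cross-section: area (mm²), perimeter (mm) and a label.

    Build from a contour with :meth:`from_contour` or directly from
    measured (area, perimeter) pairs.
    """

    area: float
    perimeter: float
    label: str = ""
    contour: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise InvalidParameterError("area and perimeter must be positive")

    @classmethod
    def from_contour(cls, contour: np.ndarray, label: str = "") -> "CrossSection":
        area, perimeter = polygon_metrics(contour)
        return cls(area=area, perimeter=perimeter, label=label,
                   contour=np.asarray(contour, dtype=float))


@dataclass(frozen=True)
class PatchGeometry:
    """A cross-section together with its derived hydraulic diameter."""

    section: CrossSection

    @property
    def hydraulic_diameter(self) -> float:
        return hydraulic_diameter(self.section.area, self.section.perimeter)

    @property
    def label(self) -> str:
        return self.section.label


def coarctation_ratio(coarct: PatchGeometry, dao: PatchGeometry) -> float:
    """Coarctation severity: coarctation D_h over descending-aorta D_h.

    Below 1 indicates residual narrowing; clinically, small values (≲0.5)
    mark a severe stenosis.
    """
    return coarct.hydraulic_diameter / dao.hydraulic_diameter


def extension_length(patch: PatchGeometry, multiple: float = 10.0) -> float:
    """Outlet extrusion length, ``multiple`` × hydraulic diameter (mm)."""
    if multiple <= 0:
        raise InvalidParameterError("multiple must be positive")
    return multiple * patch.hydraulic_diameter


# ---------------------------------------------------------------------------
# optional 3-D helpers (STL plane cuts)
# ---------------------------------------------------------------------------

def plane_cut_contour(
    mesh: Union[str, Path, "object"],
    plane_origin: Sequence[float],
    plane_normal: Sequence[float],
) -> np.ndarray:
    """Cut a surface mesh with a plane and return the largest resulting
    closed contour as an (N, 2) array in the plane's coordinates (mm).

    ``mesh`` may be a path to an STL file (ASCII or binary) or a loaded
    ``trimesh.Trimesh``.  Plane-polygon intersection is delegated to
    trimesh; the contour is then suitable for :func:`polygon_metrics`.
    """
    import trimesh  # heavyweight; imported only when 3-D input is used

    if isinstance(mesh, (str, Path)):
        mesh = trimesh.load_mesh(str(mesh))
    section = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if section is None:
        raise InvalidGeometryError("plane does not intersect the mesh")
    planar, _ = section.to_2D()
    polygons = planar.polygons_full
    if not polygons:
        raise InvalidGeometryError("plane cut produced no closed contour")
    largest = max(polygons, key=lambda p: p.area)
    return np.asarray(largest.exterior.coords, dtype=float)


def min_hydraulic_diameter(
    mesh: Union[str, Path, "object"],
    planes: Iterable[Tuple[Sequence[float], Sequence[float]]],
    label: str = "coarctation",
) -> PatchGeometry:
    """Sweep user-supplied (origin, normal) planes along a vessel and return
    the section with the minimum hydraulic diameter."""
    best: Optional[PatchGeometry] = None
    for origin, normal in planes:
        try:
            contour = plane_cut_contour(mesh, origin, normal)
        except InvalidGeometryError:
            continue
        patch = PatchGeometry(CrossSection.from_contour(contour, label=label))
        if best is None or patch.hydraulic_diameter < best.hydraulic_diameter:
            best = patch
    if best is None:
        raise InvalidGeometryError("no plane produced a valid cross-section")
    return best


# ---------------------------------------------------------------------------
# I/O and reporting
# ---------------------------------------------------------------------------

def read_contour(path: Union[str, Path]) -> np.ndarray:
    """Read a delimited x,y point list (mm); comma or whitespace separated,
    ``#`` comment lines ignored."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        rows.append([float(p) for p in parts[:2]])
    return np.asarray(rows, dtype=float)


def geometry_report(
    sections: Sequence[PatchGeometry], dao: PatchGeometry
) -> pd.DataFrame:
    """Tabulate area, perimeter, hydraulic diameter and coarctation ratio
    for a set of candidate coarctation sections against a reference
    descending-aorta section."""
    rows = []
    for patch in list(sections) + [dao]:
        ratio = (
            coarctation_ratio(patch, dao) if patch is not dao else np.nan
        )
        rows.append(
            {
                "label": patch.label,
                "area_mm2": patch.section.area,
                "perimeter_mm": patch.section.perimeter,
                "hydraulic_diameter_mm": patch.hydraulic_diameter,
                "coarct_to_dao_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
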