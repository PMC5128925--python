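"""Target regions in template space and point-membership queries.

A region is a binary labelmap, either native (e.g. a voxelized nucleus)
or rasterized from per-coronal-slice 2D contours, the form in which
printed atlas nuclei are available.  Contour stacks are sparse along AP;
membership on an un-contoured plane is borrowed from the nearest
contoured plane when within a gap tolerance, and reported as
*indeterminate* otherwise — silent interpolation across missing slices
would hide exactly the discontinuity that makes small thalamic nuclei
hard to represent in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError
from .volume_io import Modality, Volume3D

__all__ = ["TargetRegion", "rasterize_contours", "region_from_labelmap", "in_target"]

INSIDE = "inside"
OUTSIDE = "outside"
INDETERMINATE = "indeterminate"


@dataclass
class TargetRegion:
    """Named binary labelmap, possibly built from a coronal contour stack."""

    name: str
    labelmap: Volume3D
    provenance: str = "native"  # native | contours
    slice_spacing_mm: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.labelmap.data)
        if not np.isin(np.unique(data), [0, 1]).all():
            raise GeometryError("region labelmap must be binary {0, 1}")
        if not data.any():
            raise GeometryError(f"region {self.name!r} is empty")

    @property
    def default_gap_tolerance(self) -> float:
        """Half the contour slice spacing (0 for native labelmaps)."""
        return 0.5 * self.slice_spacing_mm


def region_from_labelmap(name: str, labelmap: Volume3D) -> TargetRegion:
    data = (np.asarray(labelmap.data) > 0).astype(np.uint8)
    return TargetRegion(name, Volume3D(data, labelmap.affine.copy(), Modality.LABEL))


def rasterize_contours(name: str, contours: list[dict], template: Volume3D,
                       interpolate: bool = False) -> TargetRegion:
    """Rasterize closed (ML, DV) polygons at stated AP positions.

    ``contours`` is a list of ``{"ap": float, "vertices": [(ml, dv), ...]}``
    in world mm.  Each polygon is filled (even-odd rule; for the required
    simple polygons this equals ordinary containment) on its nearest
    coronal voxel plane; planes between contoured slices stay empty
    unless ``interpolate`` is set, in which case they copy the nearest
    contoured plane.
    """
    if not contours:
        raise GeometryError("no contours given")
    aff = template.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off, 0, atol=1e-9):
        raise GeometryError("contour rasterization requires an axis-aligned grid")
    nx, ny, nz = template.shape
    data = np.zeros(template.shape, dtype=np.uint8)
    # voxel-center world coordinates of one coronal plane
    xs = aff[0, 0] * np.arange(nx) + aff[0, 3]
    zs = aff[2, 2] * np.arange(nz) + aff[2, 3]
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    planes: list[int] = []
    ap_positions: list[float] = []
    for contour in contours:
        ap = float(contour["ap"])
        verts = np.asarray(contour["vertices"], float)
        if len(verts) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        poly = Polygon(verts)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError(f"self-intersecting polygon at AP={ap}")
        j = int(round((ap - aff[1, 3]) / aff[1, 1]))
        if not 0 <= j < ny:
            raise GeometryError(f"contour AP={ap} outside the template grid")
        inside = shapely.contains_xy(poly, gx.ravel(), gz.ravel()).reshape(nx, nz)
        data[:, j, :] |= inside.astype(np.uint8)
        planes.append(j)
        ap_positions.append(ap)
    spacing = (float(np.diff(np.sort(np.unique(ap_positions))).min())
               if len(set(planes)) > 1 else abs(aff[1, 1]))
    if interpolate and len(planes) > 1:
        order = np.argsort(planes)
        sorted_planes = [planes[i] for i in order]
        for a, b in zip(sorted_planes[:-1], sorted_planes[1:]):
            for j in range(a + 1, b):
                src = a if (j - a) <= (b - j) else b
                data[:, j, :] |= data[:, src, :]
    labelmap = Volume3D(data, aff.copy(), Modality.LABEL)
    return TargetRegion(name, labelmap, provenance="contours",
                        slice_spacing_mm=spacing)


def in_target(point: np.ndarray, region: TargetRegion,
              gap_tolerance_mm: float | None = None) -> str:
    """Membership of a world point: inside / outside / indeterminate.

    Inside iff the containing voxel is labeled.  For contour-stack
    regions, a point on an un-contoured coronal plane borrows the label
    of the nearest contoured plane when within the gap tolerance
    (default: half the slice spacing); beyond it the answer is
    indeterminate rather than a silent guess.
    """
    point = np.asarray(point, float)
    if not np.all(np.isfinite(point)):
        raise GeometryError("membership query requires a finite point")
    if gap_tolerance_mm is None:
        gap_tolerance_mm = region.default_gap_tolerance
    lm = region.labelmap
    vox = lm.world_to_voxel(point)
    # containing voxel: floor(v + 0.5) is consistent under whole-voxel
    # shifts, unlike round-half-to-even
    idx = np.floor(vox + 0.5).astype(int)
    shape = np.array(lm.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        return OUTSIDE
    data = np.asarray(lm.data)
    if data[tuple(idx)] > 0:
        return INSIDE
    if region.provenance != "contours":
        return OUTSIDE
    plane_filled = data.any(axis=(0, 2))
    if plane_filled[idx[1]]:
        return OUTSIDE
    filled_j = np.nonzero(plane_filled)[0]
    if len(filled_j) == 0:
        return INDETERMINATE
    dj = np.abs(filled_j - vox[1])
    nearest = filled_j[int(np.argmin(dj))]
    ap_dist = float(np.min(dj)) * abs(lm.affine[1, 1])
    if ap_dist > gap_tolerance_mm:
        return INDETERMINATE
    return INSIDE if data[idx[0], nearest, idx[2]] > 0 else OUTSIDE
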