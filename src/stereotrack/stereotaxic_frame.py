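"""Bregma-anchored stereotaxic coordinates and planned-trajectory geometry.

Stereotaxic coordinates are offsets relative to bregma along the
anterior-posterior (AP), medio-lateral (ML) and dorso-ventral (DV) axes;
component triples are ordered (AP, ML, DV) throughout.  The AP axis is
the *template's* AP axis, not the animal's bregma-lambda line — the
deviation of the latter from horizontal is reported separately as the
skull-flat angle gamma.

Trajectory inclinations alpha (coronal-plane, from the DV axis) and
beta (sagittal-plane) are independent projection angles with a tangent
parameterization: the direction from entry to tip is proportional to
``(s_hemi * tan(alpha), tan(beta), -1)`` on the (ML, AP, DV) axes, where
``s_hemi`` is +1 for the right and -1 for the left hemisphere so that a
negative alpha always means the entry is lateral to the tip on the
implanted side.  Positive beta tilts the trajectory posterior-to-anterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .volume_io import Volume3D

__all__ = [
    "StereotaxicFrame",
    "PlannedTrajectory",
    "DuralSurface",
    "build_frame",
    "skull_flat_angle",
    "bl_distance",
    "landmark_offsets",
    "direction_from_angles",
    "angles_from_direction",
    "derive_planned",
]

_HEMI_SIGN = {"right": 1.0, "left": -1.0}


@dataclass(frozen=True)
class StereotaxicFrame:
    """Origin at bregma plus orthonormal ML/AP/DV world directions."""

    bregma: np.ndarray
    ml_axis: np.ndarray
    ap_axis: np.ndarray
    dv_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bregma", "ml_axis", "ap_axis", "dv_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        axes = np.column_stack([self.ml_axis, self.ap_axis, self.dv_axis])
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes must be orthonormal")
        if self.dv_axis[2] <= 0:
            raise GeometryError("DV axis must have a positive dorsal component")

    def to_stereo(self, points: np.ndarray) -> np.ndarray:
        """World mm -> (AP, ML, DV) offsets relative to bregma."""
        pts = np.atleast_2d(np.asarray(points, float)) - self.bregma
        out = np.column_stack(
            [pts @ self.ap_axis, pts @ self.ml_axis, pts @ self.dv_axis]
        )
        return out[0] if np.asarray(points).ndim == 1 else out

    def from_stereo(self, apmldv: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(apmldv, float))
        out = (self.bregma + np.outer(s[:, 0], self.ap_axis)
               + np.outer(s[:, 1], self.ml_axis) + np.outer(s[:, 2], self.dv_axis))
        return out[0] if np.asarray(apmldv).ndim == 1 else out

    def direction_to_world(self, ml_ap_dv: np.ndarray) -> np.ndarray:
        v = np.asarray(ml_ap_dv, float)
        return v[0] * self.ml_axis + v[1] * self.ap_axis + v[2] * self.dv_axis


def build_frame(bregma: np.ndarray, lambda_pt: np.ndarray,
                axes: np.ndarray | None = None) -> StereotaxicFrame:
    """Frame with origin at bregma and the template's canonical axes.

    ``axes`` is a 3x3 matrix with columns (ML, AP, DV); the default is
    the world identity (x=ML, y=AP, z=DV).  The bregma-lambda line is
    deliberately *not* used to orient the frame; pass the landmarks so
    degenerate input is caught early.
    """
    bregma = np.asarray(bregma, float)
    lambda_pt = np.asarray(lambda_pt, float)
    if np.allclose(bregma, lambda_pt, atol=1e-12):
        raise GeometryError("bregma and lambda coincide")
    if axes is None:
        axes = np.eye(3)
    axes = np.asarray(axes, float)
    return StereotaxicFrame(bregma, axes[:, 0], axes[:, 1], axes[:, 2])


def skull_flat_angle(bregma: np.ndarray, lambda_pt: np.ndarray) -> float:
    """Signed angle gamma (deg) of the B->L segment to the horizontal plane.

    Positive when lambda is ventral to bregma; 0 in skull-flat position.
    """
    b = np.asarray(bregma, float)
    lam = np.asarray(lambda_pt, float)
    d = np.linalg.norm(b - lam)
    if d <= 0:
        raise GeometryError("bregma and lambda coincide")
    return float(np.degrees(np.arcsin((b[2] - lam[2]) / d)))


def bl_distance(bregma: np.ndarray, lambda_pt: np.ndarray) -> float:
    """Euclidean bregma-lambda distance in mm."""
    return float(np.linalg.norm(np.asarray(bregma, float) - np.asarray(lambda_pt, float)))


def landmark_offsets(animal: pd.DataFrame, template: pd.DataFrame,
                     frame: StereotaxicFrame) -> pd.DataFrame:
    """Per-landmark (animal - template) offsets on the stereotaxic axes.

    Both tables must be point tables in the same (template) space with
    matching ids; returns columns id, dAP, dML, dDV, ED.
    """
    merged = animal.merge(template, on="id", suffixes=("_a", "_t"))
    if merged.empty:
        raise GeometryError("no matching landmark ids between tables")
    pa = merged[["x_a", "y_a", "z_a"]].to_numpy(float)
    pt = merged[["x_t", "y_t", "z_t"]].to_numpy(float)
    delta = pa - pt
    comps = np.column_stack(
        [delta @ frame.ap_axis, delta @ frame.ml_axis, delta @ frame.dv_axis]
    )
    return pd.DataFrame(
        {"id": merged["id"], "dAP": comps[:, 0], "dML": comps[:, 1],
         "dDV": comps[:, 2], "ED": np.linalg.norm(delta, axis=1)}
    )


def direction_from_angles(alpha: float, beta: float, hemisphere: str = "left") -> np.ndarray:
    """Unit entry->tip direction (world x=ML, y=AP, z=DV) from the
    projection angles, pointing ventral."""
    if hemisphere not in _HEMI_SIGN:
        raise GeometryError(f"unknown hemisphere: {hemisphere!r}")
    if abs(alpha) >= 90 or abs(beta) >= 90:
        raise GeometryError("trajectory angles must satisfy |alpha|, |beta| < 90 deg")
    s = _HEMI_SIGN[hemisphere]
    v = np.array([s * np.tan(np.radians(alpha)), np.tan(np.radians(beta)), -1.0])
    return v / np.linalg.norm(v)


def angles_from_direction(direction: np.ndarray, hemisphere: str = "left") -> tuple[float, float]:
    """Inverse of :func:`direction_from_angles`; requires a ventral direction."""
    if hemisphere not in _HEMI_SIGN:
        raise GeometryError(f"unknown hemisphere: {hemisphere!r}")
    d = np.asarray(direction, float)
    if d[2] >= 0:
        raise GeometryError("direction must point ventral (DV component < 0)")
    s = _HEMI_SIGN[hemisphere]
    alpha = np.degrees(np.arctan(s * d[0] / -d[2]))
    beta = np.degrees(np.arctan(d[1] / -d[2]))
    return float(alpha), float(beta)


# -- dural surface --------------------------------------------------------

class DuralSurface:
    """DV height field of the dorsal brain surface on a template grid.

    ``height[i, j]`` is the world z of the dorsal-most brain-mask voxel in
    the (x, y) column; NaN where the mask has no support.  Queries use
    bilinear interpolation, so line intersections are sub-voxel.
    """

    def __init__(self, height: np.ndarray, x0: float, y0: float,
                 dx: float, dy: float) -> None:
        self.height = np.asarray(height, float)
        self.x0, self.y0, self.dx, self.dy = float(x0), float(y0), float(dx), float(dy)

    @classmethod
    def from_mask(cls, mask: Volume3D) -> "DuralSurface":
        aff = mask.affine
        off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
        if not np.allclose(off, 0, atol=1e-9) or np.any(np.diag(aff[:3, :3]) <= 0):
            raise GeometryError("dural height field requires an axis-aligned grid")
        data = np.asarray(mask.data) > 0
        if not data.any():
            raise GeometryError("empty brain mask")
        nz = data.shape[2]
        any_col = data.any(axis=2)
        top_k = np.where(any_col, nz - 1 - np.argmax(data[:, :, ::-1], axis=2), -1)
        height = np.where(any_col, aff[2, 2] * top_k + aff[2, 3], np.nan)
        return cls(height, aff[0, 3], aff[1, 3], aff[0, 0], aff[1, 1])

    @classmethod
    def flat(cls, z: float, x_range: tuple[float, float] = (-50.0, 50.0),
             y_range: tuple[float, float] = (-50.0, 50.0),
             spacing: float = 1.0) -> "DuralSurface":
        """Analytic flat surface (for tests and closed-form geometry)."""
        nx = int(round((x_range[1] - x_range[0]) / spacing)) + 1
        ny = int(round((y_range[1] - y_range[0]) / spacing)) + 1
        return cls(np.full((nx, ny), float(z)), x_range[0], y_range[0], spacing, spacing)

    @property
    def min_spacing(self) -> float:
        return min(self.dx, self.dy)

    def height_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear height lookup; NaN outside support."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        fi = (x - self.x0) / self.dx
        fj = (y - self.y0) / self.dy
        nx, ny = self.height.shape
        i0 = np.floor(fi).astype(int)
        j0 = np.floor(fj).astype(int)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        ok = (i0 >= 0) & (i0 < nx - 1) & (j0 >= 0) & (j0 < ny - 1)
        if np.any(ok):
            i0o, j0o = i0[ok], j0[ok]
            wi = fi[ok] - i0o
            wj = fj[ok] - j0o
            h00 = self.height[i0o, j0o]
            h10 = self.height[i0o + 1, j0o]
            h01 = self.height[i0o, j0o + 1]
            h11 = self.height[i0o + 1, j0o + 1]
            val = ((1 - wi) * (1 - wj) * h00 + wi * (1 - wj) * h10
                   + (1 - wi) * wj * h01 + wi * wj * h11)
            out[ok] = val
        return out

    def intersect(self, point: np.ndarray, direction: np.ndarray,
                  step_fraction: float = 0.1, max_length: float = 200.0) -> np.ndarray:
        """First crossing of the line through ``point`` along ventral
        ``direction`` with the surface, by ray-marching at
        ``step_fraction`` of the column spacing with bilinear height
        interpolation and a bisection refinement of the bracketing step.
        """
        p = np.asarray(point, float)
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        if d[2] >= 0:
            raise GeometryError("intersection requires a ventral direction")
        step = step_fraction * self.min_spacing

        def gap(s: float) -> float:
            q = p + s * d
            h = self.height_at(q[0], q[1])
            if np.isnan(h):
                raise GeometryError("trajectory leaves the dural height field support")
            return float(q[2] - h)

        # walk dorsally until above the surface
        s = 0.0
        guard = 0
        try:
            while gap(s) <= 0:
                s -= step
                guard += 1
                if guard * step > max_length:
                    raise GeometryError("no dorsal start above the dural surface")
        except GeometryError:
            raise
        # march ventrally to bracket the crossing
        s_lo = s
        while True:
            s_hi = s_lo + step
            if s_hi - s > max_length:
                raise GeometryError("no dural crossing within the height field")
            if gap(s_hi) <= 0:
                break
            s_lo = s_hi
        for _ in range(60):
            mid = 0.5 * (s_lo + s_hi)
            if gap(mid) > 0:
                s_lo = mid
            else:
                s_hi = mid
        return p + 0.5 * (s_lo + s_hi) * d


@dataclass(frozen=True)
class PlannedTrajectory:
    """Planned entry/target geometry derived from stereotaxic coordinates."""

    target_stereo: np.ndarray  # (AP, ML, DV depth below dura at entry column)
    alpha: float
    beta: float
    hemisphere: str
    entry: np.ndarray          # world mm, on the dural surface
    target: np.ndarray         # world mm
    direction: np.ndarray      # unit entry->tip
    d_plan: float              # mm along trajectory

    def __post_init__(self) -> None:
        for name in ("target_stereo", "entry", "target", "direction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))


def derive_planned(target_stereo: np.ndarray, alpha: float, beta: float,
                   hemisphere: str, dura: DuralSurface,
                   frame: StereotaxicFrame, max_iter: int = 20) -> PlannedTrajectory:
    """Derive the dural entry point and trajectory length of a plan.

    The planned DV coordinate is a *depth below the dural surface at the
    entry column*, so for inclined trajectories the target's world
    position and the entry column are coupled; they are resolved by a
    fixed-point iteration (initialized at the target column) that
    converges in a few steps for smooth dural surfaces.  Requires the
    frame DV axis to coincide with the height-field z axis.
    """
    if not np.allclose(frame.dv_axis, [0, 0, 1], atol=1e-9):
        raise GeometryError("derive_planned requires a canonical (template) frame")
    ap, ml, depth = np.asarray(target_stereo, float)
    if depth <= 0:
        raise GeometryError("planned DV depth must be positive")
    d_world = frame.direction_to_world(direction_from_angles(alpha, beta, hemisphere))
    col = frame.from_stereo([ap, ml, 0.0])  # target column at DV=0
    h0 = float(dura.height_at(col[0], col[1]))
    if np.isnan(h0):
        raise GeometryError("target column outside the dural height field")
    target = np.array([col[0], col[1], h0 - depth])
    entry = None
    for _ in range(max_iter):
        new_entry = dura.intersect(target, d_world)
        target = np.array([col[0], col[1], new_entry[2] - depth])
        if entry is not None and np.linalg.norm(new_entry - entry) < 1e-9:
            entry = new_entry
            break
        entry = new_entry
    entry = dura.intersect(target, d_world)
    if target[2] >= entry[2]:
        raise GeometryError("planned target is not below the dura")
    d_plan = float(np.linalg.norm(target - entry))
    return PlannedTrajectory(
        target_stereo=np.array([ap, ml, depth]), alpha=float(alpha),
        beta=float(beta), hemisphere=hemisphere, entry=entry, target=target,
        direction=d_world, d_plan=d_plan,
    )
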