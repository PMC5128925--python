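"""Trajectory fitting from electrode masks and dural-surface reconstruction.

The 3D orientation of the electrode is the principal axis (dominant PCA
eigenvector) of the segmented voxel centers, sign-fixed to point
ventral.  Entry and tip are read either directly from the extents of the
mask projected onto the axis (sources ``mri``/``ct``) or reconstructed
by intersecting the axis with the template's dural surface and placing
the tip at the planned distance ``D_plan`` from that entry (sources
``rec-mri``/``rec-ct``) — the latter assumes no inaccuracy in insertion
depth and therefore carries zero depth error by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AmbiguousAxisError, GeometryError, InputError
from .registration import AffineTransform
from .segmentation import ElectrodeMask
from .stereotaxic_frame import DuralSurface, angles_from_direction

__all__ = [
    "Trajectory",
    "SOURCES",
    "principal_axis",
    "extents_entry_tip",
    "trajectory_from_mask",
    "reconstruct_from_axis",
    "to_template",
    "ingest_observer",
    "trajectories_to_table",
    "table_to_trajectories",
]

SOURCES = ("plan", "mri", "rec-mri", "ct", "rec-ct", "obs-ct", "hist", "truth")


@dataclass(frozen=True)
class Trajectory:
    """A straight electrode trajectory: entry, tip, direction, angles, depth."""

    entry: np.ndarray
    tip: np.ndarray
    direction: np.ndarray
    alpha: float
    beta: float
    depth: float
    source: str
    space: str = "native"
    hemisphere: str = "left"
    traj_id: str = ""

    def __post_init__(self) -> None:
        for name in ("entry", "tip", "direction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.source not in SOURCES:
            raise InputError(f"unknown trajectory source: {self.source!r}")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise GeometryError("direction must be a unit vector")
        if self.direction[2] >= 0:
            raise GeometryError("direction must point ventral (DV component < 0)")
        if not np.allclose(self.tip, self.entry + self.depth * self.direction,
                           atol=1e-6):
            raise GeometryError("tip must equal entry + depth * direction")

    @classmethod
    def from_points(cls, entry: np.ndarray, tip: np.ndarray, source: str,
                    space: str = "native", hemisphere: str = "left",
                    traj_id: str = "") -> "Trajectory":
        entry = np.asarray(entry, float)
        tip = np.asarray(tip, float)
        delta = tip - entry
        depth = float(np.linalg.norm(delta))
        if depth <= 0:
            raise GeometryError("entry and tip coincide")
        d = delta / depth
        if d[2] >= 0:
            raise GeometryError("tip must be ventral to entry")
        alpha, beta = angles_from_direction(d, hemisphere)
        return cls(entry, tip, d, alpha, beta, depth, source, space,
                   hemisphere, traj_id)


def principal_axis(mask: ElectrodeMask) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal axis of the mask's voxel centers (unweighted PCA).

    Returns (centroid, unit direction pointing ventral, explained-variance
    ratio of the dominant eigenvalue).  Raises
    :class:`AmbiguousAxisError` for near-isotropic clouds (top two
    eigenvalues within 5%) and :class:`GeometryError` when the axis is
    orthogonal to DV (no ventral sign fix possible).
    """
    pts = mask.world_points()
    if len(pts) < 3:
        raise AmbiguousAxisError("need at least 3 voxels for an axis fit")
    extent_vox = np.ptp(np.argwhere(np.asarray(mask.mask.data) > 0), axis=0)
    if extent_vox.max() < 5:
        raise AmbiguousAxisError(
            "mask spatial extent below 5 voxels along its longest dimension"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[0] <= 0:
        raise AmbiguousAxisError("degenerate voxel cloud")
    if evals[1] / evals[0] > 0.95:
        raise AmbiguousAxisError(
            f"ambiguous axis: top eigenvalues within 5% ({evals[0]:.4g} vs {evals[1]:.4g})"
        )
    direction = evecs[:, 0]
    if abs(direction[2]) < 1e-12:
        raise GeometryError("principal axis orthogonal to DV; cannot fix sign")
    if direction[2] > 0:
        direction = -direction
    explained = float(evals[0] / evals.sum())
    return centroid, direction, explained


def extents_entry_tip(mask: ElectrodeMask, centroid: np.ndarray,
                      direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """On-axis entry/tip from the extents of the mask along the axis.

    Voxel centers are projected onto the fitted axis; the returned points
    lie on the axis (dorsal-most projection = entry, ventral-most = tip),
    not on raw voxels, which removes single-voxel jitter.
    """
    pts = mask.world_points()
    t = (pts - centroid) @ direction
    entry = centroid + t.min() * direction
    tip = centroid + t.max() * direction
    return entry, tip


def trajectory_from_mask(mask: ElectrodeMask, source: str,
                         space: str = "native", hemisphere: str = "left",
                         traj_id: str = "") -> Trajectory:
    """Direct trajectory (``mri``/``ct``): PCA axis plus mask extents."""
    centroid, direction, _ = principal_axis(mask)
    entry, tip = extents_entry_tip(mask, centroid, direction)
    return Trajectory.from_points(entry, tip, source, space, hemisphere, traj_id)


def reconstruct_from_axis(centroid: np.ndarray, direction: np.ndarray,
                          dura: DuralSurface, d_plan: float, source: str,
                          space: str = "template", hemisphere: str = "left",
                          traj_id: str = "") -> Trajectory:
    """Reconstructed trajectory (``rec-*``): entry at the dural-surface
    intersection of the axis, tip at exactly ``d_plan`` along it."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    entry = dura.intersect(np.asarray(centroid, float), direction)
    tip = entry + d_plan * direction
    alpha, beta = angles_from_direction(direction, hemisphere)
    return Trajectory(entry, tip, direction, alpha, beta, float(d_plan),
                      source, space, hemisphere, traj_id)


def to_template(traj: Trajectory, chain: list[AffineTransform] | AffineTransform,
                space: str = "template") -> Trajectory:
    """Map a trajectory through a chain of transforms (applied first-to-last).

    Entry and tip are mapped; direction, depth and angles are recomputed
    from the mapped points (an affine link may change the depth).
    """
    if isinstance(chain, AffineTransform):
        chain = [chain]
    entry = np.asarray(traj.entry, float)
    tip = np.asarray(traj.tip, float)
    for t in chain:
        entry = t.apply(entry)
        tip = t.apply(tip)
    return Trajectory.from_points(entry, tip, traj.source, space,
                                  traj.hemisphere, traj.traj_id)


def ingest_observer(points: pd.DataFrame, space: str = "native",
                    hemisphere: str = "left") -> list[Trajectory]:
    """Build ``obs-ct`` trajectories from manually picked entry/tip pairs.

    The point table must contain, for every trajectory id ``X``, rows with
    ids ``X:entry`` and ``X:tip``.
    """
    bases: dict[str, dict[str, np.ndarray]] = {}
    for _, row in points.iterrows():
        pid = str(row["id"])
        if ":" not in pid:
            raise InputError(f"observer point id {pid!r} lacks an ':entry'/' :tip' suffix")
        base, role = pid.rsplit(":", 1)
        if role not in ("entry", "tip"):
            raise InputError(f"observer point id {pid!r} must end in ':entry' or ':tip'")
        bases.setdefault(base, {})[role] = np.array([row["x"], row["y"], row["z"]], float)
    out = []
    for base, roles in sorted(bases.items()):
        if set(roles) != {"entry", "tip"}:
            raise InputError(f"trajectory {base!r}: missing entry/tip pair")
        out.append(Trajectory.from_points(roles["entry"], roles["tip"], "obs-ct",
                                          space, hemisphere, base))
    return out


# -- tabular round trip ---------------------------------------------------

_TRAJ_COLS = ["id", "source", "space", "hemisphere", "Ex", "Ey", "Ez",
              "Tx", "Ty", "Tz", "alpha_deg", "beta_deg", "D_mm"]


def trajectories_to_table(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = [
        {"id": t.traj_id, "source": t.source, "space": t.space,
         "hemisphere": t.hemisphere,
         "Ex": t.entry[0], "Ey": t.entry[1], "Ez": t.entry[2],
         "Tx": t.tip[0], "Ty": t.tip[1], "Tz": t.tip[2],
         "alpha_deg": t.alpha, "beta_deg": t.beta, "D_mm": t.depth}
        for t in trajs
    ]
    return pd.DataFrame(rows, columns=_TRAJ_COLS)


def table_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for _, r in df.iterrows():
        out.append(Trajectory.from_points(
            np.array([r["Ex"], r["Ey"], r["Ez"]], float),
            np.array([r["Tx"], r["Ty"], r["Tz"]], float),
            str(r["source"]), str(r["space"]), str(r["hemisphere"]),
            str(r["id"]),
        ))
    return out
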