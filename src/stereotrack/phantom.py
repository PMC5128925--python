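"""Synthetic multimodal head phantoms with known ground truth.

The phantom emulates the imaging setup of a stereotactic targeting
study in rat: an ellipsoidal brain inside an ellipsoidal skull shell,
bregma/lambda landmarks on the outer skull at equal height (skull-flat
template by construction), a 200 µm electrode along a known trajectory,
and per-modality contrasts — the electrode trace is hypo-intense in
post-operative MRI, the electrode itself hyper-intense in post-operative
CT.  Every generated modality records its true rigid transform to
template space, so registration, segmentation, trajectory fitting and
the error statistics can each be validated against a known answer.

The electrode is rasterized with 3x supersampling (partial volume);
hard rasterization at near-voxel diameter would alias the axis fit.
Gaussian additive noise is the default; Rician magnitude noise is
available behind a flag.  The dura is the dorsal surface of the brain
mask — no separate membrane is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import atlas_regions
from .errors import GeometryError
from .registration import AffineTransform, identity_transform, rigid_from_params
from .stereotaxic_frame import (
    DuralSurface, PlannedTrajectory, StereotaxicFrame, build_frame,
    derive_planned, direction_from_angles,
)
from .trajectory import Trajectory
from .volume_io import Modality, Volume3D, make_point_table

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomBundle",
    "CohortBundle",
    "generate_phantom",
    "generate_cohort",
    "rasterize_cylinder",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic animal.

    Defaults describe a scaled rat head at 0.15 mm isotropic resolution:
    brain semi-axes 5 x 7 x 4.5 mm, a 0.7 mm skull shell, bregma/lambda
    8.31 mm apart (the cohort-mean bregma-lambda distance of adult
    Wistar rats), and a 0.2 mm diameter electrode planned at an
    SNCD-like target 6 mm below the dura.
    """

    shape: tuple[int, int, int] = (88, 112, 88)
    voxel_size: float = 0.15
    brain_semiaxes: tuple[float, float, float] = (5.0, 7.0, 4.5)
    skull_thickness: float = 0.7
    bl_half_separation: float = 4.155  # |B-L| = 8.31 mm

    # surgical plan (stereotaxic: AP, ML, DV depth below dura) and the
    # true deviation of this animal from it
    target_stereo: tuple[float, float, float] = (-5.3, -2.4, 6.0)
    alpha_plan: float = 0.0
    beta_plan: float = 0.0
    hemisphere: str = "left"
    angle_offset: tuple[float, float] = (0.0, 0.0)   # true (dAlpha, dBeta) deg
    entry_offset: tuple[float, float] = (0.0, 0.0)   # true (dML, dAP) mm

    electrode_diameter: float = 0.2
    ct_overshoot: float = 2.0  # electrode visible above the dura in CT, mm

    # contrast levels (arbitrary units)
    mri_levels: dict = field(default_factory=lambda: {
        "background": 0.0, "brain": 1000.0, "skull": 150.0, "trace": 300.0})
    ct_levels: dict = field(default_factory=lambda: {
        "background": 0.0, "brain": 200.0, "skull": 800.0, "electrode": 3000.0})
    noise_sd_mri: float = 25.0
    noise_sd_ct: float = 30.0
    noise_model: str = "gaussian"  # gaussian | rician

    region_semiaxes: tuple[float, float, float] = (0.75, 1.0, 0.6)  # ML, AP, DV mm

    # true modality -> template rigid misalignments (deg, deg, deg, mm, mm, mm)
    misalignments: dict = field(default_factory=lambda: {
        "MRIpre": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        "CTpre": (2.0, -1.0, 1.5, 0.8, -0.5, 0.4),
        "MRIpost": (-1.5, 1.0, -1.0, -0.6, 0.4, 0.7),
        "CTpost": (1.0, 2.0, -1.0, 0.5, 0.6, -0.3),
    })
    modalities: tuple[str, ...] = ("MRIpre", "CTpre", "MRIpost", "CTpost")
    seed: int = 0

    def validate(self) -> None:
        if self.electrode_diameter <= 0:
            raise GeometryError("electrode diameter must be positive")
        if self.target_stereo[2] <= 0:
            raise GeometryError("planned depth must be positive")
        if min(self.noise_sd_mri, self.noise_sd_ct) < 0:
            raise GeometryError("noise sd must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise GeometryError(f"unknown noise model: {self.noise_model!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -0.5 * self.voxel_size * (np.array(self.shape) - 1)
        return aff


@dataclass
class PhantomTruth:
    """Everything the generator knows that the pipeline must recover."""

    trajectory: Trajectory            # true trajectory, template space
    plan: PlannedTrajectory
    transforms: dict                  # modality -> AffineTransform (to template)
    landmarks: pd.DataFrame           # bregma/lambda, template space
    region: atlas_regions.TargetRegion
    frame: StereotaxicFrame
    dura: DuralSurface
    in_target: str


@dataclass
class PhantomBundle:
    template: Volume3D
    brain_mask: Volume3D
    modalities: dict
    truth: PhantomTruth
    spec: PhantomSpec


@dataclass
class CohortBundle:
    template: Volume3D
    brain_mask: Volume3D
    animals: list            # list of PhantomBundle
    truth_table: pd.DataFrame
    plan: PlannedTrajectory
    frame: StereotaxicFrame
    dura: DuralSurface
    region: atlas_regions.TargetRegion


# -- geometry helpers -----------------------------------------------------

def _ellipsoid(points: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    return ((points / semiaxes) ** 2).sum(axis=-1) <= 1.0


def _grid_world(shape, affine) -> np.ndarray:
    """(N, 3) world coordinates of all voxel centers."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip((points - p0) @ d / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def rasterize_cylinder(shape, affine, p0: np.ndarray, p1: np.ndarray,
                       radius: float, supersample: int = 4,
                       world_map: np.ndarray | None = None) -> np.ndarray:
    """Partial-volume occupancy of a finite cylinder on a voxel grid.

    Each voxel near the axis is subdivided ``supersample``^3 times and
    the in-cylinder fraction averaged (an even factor avoids subcell
    centers coinciding with voxel centers, which biases grid-aligned
    cylinders).  ``world_map`` optionally maps
    this grid's world coordinates into the space where the cylinder is
    defined (used to pose misaligned modalities without resampling).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    affine = np.asarray(affine, float)
    pts = _grid_world(shape, affine)
    if world_map is not None:
        pts = pts @ world_map[:3, :3].T + world_map[:3, 3]
    vox_diag = np.linalg.norm(affine[:3, :3] @ np.ones(3))
    cand = _segment_distance(pts, p0, p1) <= radius + 0.75 * vox_diag
    occ = np.zeros(len(pts), dtype=np.float32)
    if cand.any():
        ss = supersample
        offs_vox = (np.indices((ss, ss, ss)).reshape(3, -1).T + 0.5) / ss - 0.5
        offs = offs_vox @ affine[:3, :3].T
        if world_map is not None:
            offs = offs @ world_map[:3, :3].T
        centers = pts[cand]
        hits = np.zeros(len(centers), dtype=np.int32)
        for off in offs:
            hits += (_segment_distance(centers + off, p0, p1) <= radius)
        occ[cand] = hits / float(ss ** 3)
    return occ.reshape(shape)


# -- scene ----------------------------------------------------------------

# Internal brain structures (center, semi-axes, MRI level factor, CT level
# factor): a ventricle-like CSF space, a white-matter-like nucleus and a
# cerebellum-like posterior lobe.  They are deliberately asymmetric about
# every axis — a featureless ellipsoid head is almost rotationally
# degenerate and would make intensity-based registration ill-posed in a
# way real rodent anatomy is not.
_STRUCTURES = (
    ((0.7, 1.6, 0.8), (0.9, 2.2, 0.7), 0.45, 0.85),
    ((-1.6, -1.2, -1.2), (1.4, 1.2, 1.0), 1.25, 1.10),
    ((0.3, -5.2, -0.6), (2.4, 1.5, 2.0), 0.78, 0.95),
    ((2.2, 3.1, -0.4), (1.0, 1.6, 0.9), 0.60, 1.20),
)


def _base_scene(points: np.ndarray, spec: PhantomSpec, levels: dict,
                tissue_key: str) -> np.ndarray:
    brain_ax = np.asarray(spec.brain_semiaxes, float)
    skull_ax = brain_ax + spec.skull_thickness
    vals = np.full(len(points), levels["background"], dtype=np.float32)
    in_skull = _ellipsoid(points, skull_ax)
    in_brain = _ellipsoid(points, brain_ax)
    vals[in_skull] = levels["skull"]
    vals[in_brain] = levels["brain"]
    mri_like = tissue_key == "mri"
    for center, ax, f_mri, f_ct in _STRUCTURES:
        inside = in_brain & _ellipsoid(points - np.asarray(center), np.asarray(ax))
        vals[inside] = levels["brain"] * (f_mri if mri_like else f_ct)
    return vals


def _check_inside(points: list[np.ndarray], template: Volume3D) -> None:
    lo, hi = template.world_bounds()
    for p in points:
        if np.any(p < lo) or np.any(p > hi):
            raise GeometryError("electrode exits the phantom grid")


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Generate one animal: template, brain mask, modality volumes, truth."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    shape = spec.shape

    # template (MRI-like, no electrode) and brain mask
    pts = _grid_world(shape, affine)
    template_data = _base_scene(pts, spec, spec.mri_levels, "mri").reshape(shape)
    brain = _ellipsoid(pts, np.asarray(spec.brain_semiaxes, float)).reshape(shape)
    template = Volume3D(template_data, affine.copy(), Modality.MRI)
    brain_mask = Volume3D(brain.astype(np.uint8), affine.copy(), Modality.MASK)

    # landmarks on the outer skull surface, symmetric about the origin
    skull_ax = np.asarray(spec.brain_semiaxes, float) + spec.skull_thickness
    y_bl = spec.bl_half_separation
    z_bl = skull_ax[2] * np.sqrt(max(1.0 - (y_bl / skull_ax[1]) ** 2, 0.0))
    bregma = np.array([0.0, y_bl, z_bl])
    lam = np.array([0.0, -y_bl, z_bl])
    frame = build_frame(bregma, lam)
    landmarks = make_point_table(["bregma", "lambda"], np.vstack([bregma, lam]),
                                 source="template")

    dura = DuralSurface.from_mask(brain_mask)
    plan = derive_planned(spec.target_stereo, spec.alpha_plan, spec.beta_plan,
                          spec.hemisphere, dura, frame)

    # true trajectory = plan perturbed by the stated angle/entry offsets
    alpha = spec.alpha_plan + spec.angle_offset[0]
    beta = spec.beta_plan + spec.angle_offset[1]
    d_true = frame.direction_to_world(
        direction_from_angles(alpha, beta, spec.hemisphere))
    probe = plan.entry + np.array([spec.entry_offset[0], spec.entry_offset[1], 0.0])
    entry = dura.intersect(probe, d_true)
    tip = entry + plan.d_plan * d_true
    truth_traj = Trajectory(entry, tip, d_true, alpha, beta, plan.d_plan,
                            "truth", "template", spec.hemisphere, "truth")
    _check_inside([entry, tip, entry - spec.ct_overshoot * d_true], template)

    # target region labelmap centered on the planned target
    reg_ax = np.asarray(spec.region_semiaxes, float)
    reg_data = _ellipsoid(pts - plan.target, reg_ax).reshape(shape)
    region = atlas_regions.TargetRegion(
        "target", Volume3D(reg_data.astype(np.uint8), affine.copy(), Modality.LABEL))

    transforms: dict[str, AffineTransform] = {}
    volumes: dict[str, Volume3D] = {}
    for name in spec.modalities:
        params = spec.misalignments.get(name, (0.0,) * 6)
        t = (identity_transform(provenance=f"{name}->template")
             if not any(params)
             else rigid_from_params(np.asarray(params, float),
                                    provenance=f"{name}->template"))
        transforms[name] = t
        volumes[name] = _render_modality(name, spec, t, rng, (entry, tip, d_true))

    in_tgt = atlas_regions.in_target(tip, region)
    truth = PhantomTruth(truth_traj, plan, transforms, landmarks, region,
                         frame, dura, in_tgt)
    return PhantomBundle(template, brain_mask, volumes, truth, spec)


def _render_modality(name: str, spec: PhantomSpec, to_template: AffineTransform,
                     rng: np.random.Generator,
                     truth_geom: tuple[np.ndarray, np.ndarray, np.ndarray]) -> Volume3D:
    """Analytically render a modality on its own (misaligned) grid.

    A point at modality-world coordinate x holds the scene intensity at
    template location T(x), so registering the modality to the template
    recovers exactly the recorded transform T.
    """
    affine = spec.affine
    shape = spec.shape
    world_map = to_template.matrix
    pts = _grid_world(shape, affine)
    pts_t = pts @ world_map[:3, :3].T + world_map[:3, 3]

    is_ct = name.startswith("CT")
    levels = spec.ct_levels if is_ct else spec.mri_levels
    vals = _base_scene(pts_t, spec, levels, "ct" if is_ct else "mri").reshape(shape)

    if name.endswith("post"):
        entry, tip, d_true = truth_geom
        radius = 0.5 * spec.electrode_diameter
        if is_ct:
            p_top = entry - spec.ct_overshoot * d_true
            occ = rasterize_cylinder(shape, affine, p_top, tip, radius,
                                     world_map=world_map)
            vals = vals * (1 - occ) + levels["electrode"] * occ
        else:
            occ = rasterize_cylinder(shape, affine, entry, tip, radius,
                                     world_map=world_map)
            vals = vals * (1 - occ) + levels["trace"] * occ

    sd = spec.noise_sd_ct if is_ct else spec.noise_sd_mri
    if sd > 0:
        if spec.noise_model == "gaussian":
            vals = vals + rng.normal(0.0, sd, size=shape)
        else:  # rician magnitude noise
            vals = np.hypot(vals + rng.normal(0.0, sd, size=shape),
                            rng.normal(0.0, sd, size=shape))
    return Volume3D(vals.astype(np.float32), affine.copy(),
                    Modality.CT if is_ct else Modality.MRI)


def generate_cohort(n: int, angular_sd: float = 2.0, entry_sd: float = 0.4,
                    seed: int = 0, spec: PhantomSpec | None = None,
                    modalities: tuple[str, ...] = ("MRIpost",),
                    max_angle: float | None = None) -> CohortBundle:
    """Generate a cohort of animals with seeded trajectory perturbations.

    Each animal's true trajectory is the shared plan perturbed by
    normal draws: angles (alpha, beta) with sd ``angular_sd`` degrees
    (optionally truncated at ``max_angle``) and the entry column by sd
    ``entry_sd`` mm per axis.  Cohort animals are generated in template
    space with identity inter-image transforms — the error model
    describes surgical deviation, not scanner repositioning, which is
    exercised separately for single animals.
    """
    if n < 1:
        raise GeometryError("cohort size must be >= 1")
    base = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    d_angles = rng.normal(0.0, angular_sd, size=(n, 2))
    if max_angle is not None:
        d_angles = np.clip(d_angles, -max_angle, max_angle)
    d_entry = rng.normal(0.0, entry_sd, size=(n, 2))  # (dML, dAP)

    animals: list[PhantomBundle] = []
    rows = []
    shared = None
    for i in range(n):
        s = replace(
            base,
            angle_offset=(float(d_angles[i, 0]), float(d_angles[i, 1])),
            entry_offset=(float(d_entry[i, 0]), float(d_entry[i, 1])),
            modalities=modalities,
            misalignments={m: (0.0,) * 6 for m in modalities},
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        bundle = generate_phantom(s)
        if shared is None:
            shared = bundle
        t = bundle.truth.trajectory
        rows.append({
            "animal": f"A{i + 1:03d}", "d_alpha": d_angles[i, 0],
            "d_beta": d_angles[i, 1], "d_ml": d_entry[i, 0],
            "d_ap": d_entry[i, 1], "alpha_true": t.alpha, "beta_true": t.beta,
            "Ex": t.entry[0], "Ey": t.entry[1], "Ez": t.entry[2],
            "Tx": t.tip[0], "Ty": t.tip[1], "Tz": t.tip[2],
            "in_target": bundle.truth.in_target,
        })
        animals.append(bundle)
    truth_table = pd.DataFrame(rows)
    assert shared is not None
    return CohortBundle(shared.template, shared.brain_mask, animals, truth_table,
                        shared.truth.plan, shared.truth.frame, shared.truth.dura,
                        shared.truth.region)
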