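"""Pipeline orchestration: phantom -> register -> segment -> reconstruct ->
quantify, with QC projections and a reproducible output bundle.

Two registration chains mirror the two study designs:

* ``exp1`` (electrode retracted, trace imaged): CTpre -> MRIpre rigid,
  MRIpost -> MRIpre affine, MRIpre -> template rigid; the trajectory is
  read from the MRIpost trace.
* ``exp2`` (electrode in place for CT): CTpost -> MRIpost rigid,
  MRIpost -> template rigid; trajectories from both the CT electrode
  and the MRI trace.

The in-memory entry points (:func:`process_bundle`, :func:`run_cohort`)
operate on phantom bundles and are what the statistics and the tests
drive; :func:`run_pipeline` wraps them with file I/O, a manifest and a
run log for shell use.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .metrics import TargetingErrors, cohort_table, targeting_errors
from .phantom import CohortBundle, PhantomBundle
from .registration import (AffineTransform, compose, identity_transform,
                           invert, register_mi)
from .segmentation import segment_electrode_ct, segment_trace_mri
from .stereotaxic_frame import DuralSurface, build_frame, derive_planned
from .trajectory import (Trajectory, principal_axis, reconstruct_from_axis,
                         to_template, trajectories_to_table,
                         trajectory_from_mask)
from .volume_io import (Volume3D, read_point_table, read_volume, write_point_table,
                        write_volume)

__all__ = [
    "PipelineConfig",
    "SegmentationSettings",
    "process_bundle",
    "run_cohort",
    "run_pipeline",
    "render_projection",
    "write_phantom",
]


@dataclass(frozen=True)
class SegmentationSettings:
    """Per-modality segmentation parameters.

    The ROI cuboid is placed around the planned trajectory with a world
    margin; thresholds are per-study values (the CT threshold has no
    universal default and must be configured per image set).
    """

    mri_mode: str = "absolute"
    # the 0.2 mm electrode is near voxel scale, so track voxels are
    # partial-volume mixtures; cutoffs sit at ~25% track occupancy,
    # beyond the noise range of the surrounding tissue level
    mri_value: float = 825.0          # brain 1000 / trace 300 mixture
    ct_threshold: float = 950.0       # skull 800 < threshold < electrode 3000
    ct_erosion_mm: float = 0.7
    roi_margin_mm: float = 1.2


def _plan_roi(plan, margin: float, dorsal_extra: float = 2.5) -> np.ndarray:
    """Cuboid ROI around the planned trajectory (world mm)."""
    pts = np.vstack([plan.entry, plan.target])
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    hi[2] += dorsal_extra  # include protruding electrode / cement end
    return np.vstack([lo, hi])


def process_bundle(bundle: PhantomBundle, registration: str = "truth",
                   sources: tuple[str, ...] = ("mri", "rec-mri"),
                   settings: SegmentationSettings | None = None,
                   dura: DuralSurface | None = None) -> dict[str, Trajectory]:
    """Segment, fit and reconstruct the requested trajectory sources.

    ``registration`` selects how modality volumes reach template space:
    ``"truth"`` uses the generator's recorded transforms, ``"identity"``
    assumes volumes are already in template space, ``"estimate"`` runs
    mutual-information registration against the template.
    """
    settings = settings or SegmentationSettings()
    truth = bundle.truth
    dura = dura or truth.dura
    plan = truth.plan
    roi = _plan_roi(plan, settings.roi_margin_mm)
    hemi = truth.trajectory.hemisphere
    tid = truth.trajectory.traj_id

    def chain_for(name: str) -> list[AffineTransform]:
        if registration == "identity":
            return [identity_transform()]
        if registration == "truth":
            return [truth.transforms[name]]
        if registration == "estimate":
            return [_estimate_chain(bundle, name)]
        raise ConfigurationError(f"unknown registration mode: {registration!r}")

    out: dict[str, Trajectory] = {}
    if any(s in sources for s in ("mri", "rec-mri")):
        vol = bundle.modalities["MRIpost"]
        chain = chain_for("MRIpost")
        roi_native = _map_roi(roi, invert(chain[0]))
        brain_native = _native_mask(bundle.brain_mask, chain[0], vol)
        mask = segment_trace_mri(vol, roi_native, settings.mri_mode,
                                 settings.mri_value, within=brain_native)
        if "mri" in sources:
            direct = trajectory_from_mask(mask, "mri", "native", hemi, tid)
            out["mri"] = to_template(direct, chain)
        if "rec-mri" in sources:
            centroid, direction, _ = principal_axis(mask)
            c_t, d_t = _map_axis(centroid, direction, chain)
            out["rec-mri"] = reconstruct_from_axis(
                c_t, d_t, dura, plan.d_plan, "rec-mri", "template", hemi, tid)
    if any(s in sources for s in ("ct", "rec-ct")):
        vol = bundle.modalities["CTpost"]
        chain = chain_for("CTpost")
        roi_native = _map_roi(roi, invert(chain[0]))
        mask = segment_electrode_ct(vol, roi_native, settings.ct_threshold,
                                    settings.ct_erosion_mm)
        if "ct" in sources:
            direct = trajectory_from_mask(mask, "ct", "native", hemi, tid)
            out["ct"] = to_template(direct, chain)
        if "rec-ct" in sources:
            centroid, direction, _ = principal_axis(mask)
            c_t, d_t = _map_axis(centroid, direction, chain)
            out["rec-ct"] = reconstruct_from_axis(
                c_t, d_t, dura, plan.d_plan, "rec-ct", "template", hemi, tid)
    return out


def _native_mask(template_mask: Volume3D, to_template: AffineTransform,
                 reference: Volume3D) -> Volume3D:
    """Brain mask in a modality's native space (nearest-neighbour pull)."""
    if np.allclose(to_template.matrix, np.eye(4), atol=1e-12):
        return template_mask
    from .registration import resample
    return resample(template_mask, invert(to_template), reference, "nearest")


def _map_roi(roi: np.ndarray, t: AffineTransform) -> np.ndarray:
    """Axis-aligned bounding cuboid of a transformed ROI."""
    lo, hi = roi
    corners = np.array([[lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
                        [lo[0], hi[1], lo[2]], [lo[0], lo[1], hi[2]],
                        [hi[0], hi[1], lo[2]], [hi[0], lo[1], hi[2]],
                        [lo[0], hi[1], hi[2]], [hi[0], hi[1], hi[2]]])
    mapped = t.apply(corners)
    return np.vstack([mapped.min(axis=0), mapped.max(axis=0)])


def _map_axis(centroid: np.ndarray, direction: np.ndarray,
              chain: list[AffineTransform]) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(centroid, float)
    q = c + direction
    for t in chain:
        c = t.apply(c)
        q = t.apply(q)
    d = q - c
    return c, d / np.linalg.norm(d)


def _estimate_chain(bundle: PhantomBundle, name: str) -> AffineTransform:
    dof = "affine12" if name == "MRIpost" else "rigid6"
    # direct to-template registration (single-link chain)
    return register_mi(bundle.modalities[name], bundle.template, dof="rigid6"
                       if dof == "rigid6" else "affine12")


def run_cohort(cohort: CohortBundle, registration: str = "identity",
               sources: tuple[str, ...] = ("mri", "rec-mri"),
               settings: SegmentationSettings | None = None,
               ) -> tuple[pd.DataFrame, list[TargetingErrors], pd.DataFrame]:
    """Process every cohort animal and quantify against the shared plan.

    Returns (trajectory table, per-trajectory errors, cohort summary).
    """
    all_trajs: list[Trajectory] = []
    errors: list[TargetingErrors] = []
    for i, bundle in enumerate(cohort.animals):
        trajs = process_bundle(bundle, registration, sources, settings,
                               dura=cohort.dura)
        for src in sources:
            t = trajs[src]
            t = Trajectory(t.entry, t.tip, t.direction, t.alpha, t.beta,
                           t.depth, t.source, t.space, t.hemisphere,
                           cohort.truth_table["animal"].iloc[i])
            all_trajs.append(t)
            errors.append(targeting_errors(t, cohort.plan, cohort.frame,
                                           cohort.region))
    table = trajectories_to_table(all_trajs)
    summary = cohort_table(errors)
    return table, errors, summary


# -- projections ----------------------------------------------------------

def render_projection(v: Volume3D, kind: str = "mIP", axis: int = 1,
                      slab: tuple[float, float] | None = None) -> np.ndarray:
    """Minimum (mIP) or maximum (MIP) intensity projection over a slab.

    ``slab`` is a world-coordinate interval along the projection axis;
    the default projects the whole volume.  MRI trajectories are
    visualized with mIP (hypo-intense trace), CT with MIP (hyper-intense
    electrode).
    """
    if kind not in ("mIP", "MIP"):
        raise ConfigurationError("projection kind must be 'mIP' or 'MIP'")
    if axis not in (0, 1, 2):
        raise ConfigurationError("axis must be 0, 1 or 2")
    data = np.asarray(v.data, float)
    if slab is not None:
        lo, hi = sorted(slab)
        # world coordinate of each slice center along the axis
        n = v.shape[axis]
        idx = np.zeros((n, 3))
        idx[:, axis] = np.arange(n)
        w = v.voxel_to_world(idx)[:, axis]
        sel = (w >= lo) & (w <= hi)
        if not sel.any():
            raise ConfigurationError("slab outside the volume grid")
        data = np.take(data, np.nonzero(sel)[0], axis=axis)
    return data.min(axis=axis) if kind == "mIP" else data.max(axis=axis)


def save_projection_png(proj: np.ndarray, path: str | Path, title: str = "",
                        overlay_points: np.ndarray | None = None) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(proj.T, origin="lower", cmap="gray")
    if overlay_points is not None:
        ax.plot(overlay_points[:, 0], overlay_points[:, 1], "r-", lw=1)
    ax.set_title(title)
    ax.axis("off")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return path


# -- file-based pipeline --------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of a file-based run (typically loaded from YAML)."""

    input_dir: str
    output_dir: str
    route: str = "exp2"                      # exp1 | exp2
    registration: str = "truth"              # truth | identity | estimate
    sources: tuple[str, ...] = ("mri", "rec-mri", "ct", "rec-ct")
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    plan_table: str | None = None            # default: <input_dir>/plan.tsv
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seg = SegmentationSettings(**raw.pop("segmentation", {}))
        sources = tuple(raw.pop("sources", ("mri", "rec-mri", "ct", "rec-ct")))
        return cls(segmentation=seg, sources=sources, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else
                 v.__dict__ if isinstance(v, SegmentationSettings) else v)
             for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_phantom(bundle: PhantomBundle, outdir: str | Path) -> Path:
    """Write a phantom bundle in the on-disk layout the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.template, outdir / "template.nii.gz")
    write_volume(bundle.brain_mask, outdir / "brain_mask.nii.gz")
    write_volume(bundle.truth.region.labelmap, outdir / "target_region.nii.gz")
    write_point_table(bundle.truth.landmarks, outdir / "landmarks.tsv")
    plan = bundle.truth.plan
    pd.DataFrame([{
        "id": "traj1", "hemisphere": plan.hemisphere,
        "AP": plan.target_stereo[0], "ML": plan.target_stereo[1],
        "DV_depth": plan.target_stereo[2], "alpha_deg": plan.alpha,
        "beta_deg": plan.beta,
    }]).to_csv(outdir / "plan.tsv", sep="\t", index=False)
    adir = outdir / "animals" / "A001"
    adir.mkdir(parents=True, exist_ok=True)
    for name, vol in bundle.modalities.items():
        write_volume(vol, adir / f"{name}.nii.gz")
    tdir = adir / "transforms"
    tdir.mkdir(exist_ok=True)
    for name, t in bundle.truth.transforms.items():
        t.to_json(tdir / f"{name}_to_template.json")
    manifest = {
        "version": __version__, "seed": bundle.spec.seed,
        "modalities": sorted(bundle.modalities),
        "animals": ["A001"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured pipeline over a phantom-layout input directory.

    Produces trajectory and metrics TSVs, transform JSONs, QC projection
    PNGs and a manifest recording the package version, seed and config
    hash.  Re-running with an identical config reproduces all
    non-stochastic outputs bit-identically.
    """
    t_start = time.time()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    plan_path = Path(config.plan_table) if config.plan_table else indir / "plan.tsv"
    for required in (indir, indir / "manifest.json", plan_path,
                     indir / "template.nii.gz", indir / "brain_mask.nii.gz"):
        if not Path(required).exists():
            raise ConfigurationError(f"missing required input: {required}")
    if config.route not in ("exp1", "exp2"):
        raise ConfigurationError(f"unknown route: {config.route!r}")

    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{time.time() - t_start:8.2f}s  [{stage}] {msg}")

    template = read_volume(indir / "template.nii.gz")
    brain_mask = read_volume(indir / "brain_mask.nii.gz", "MASK")
    landmarks = read_point_table(indir / "landmarks.tsv")
    plan_df = pd.read_csv(plan_path, sep="\t")
    manifest_in = json.loads((indir / "manifest.json").read_text())
    log("load", f"template {template.shape}, {len(plan_df)} planned trajectories")

    bregma = landmarks.loc[landmarks["id"] == "bregma", ["x", "y", "z"]].to_numpy()[0]
    lam = landmarks.loc[landmarks["id"] == "lambda", ["x", "y", "z"]].to_numpy()[0]
    frame = build_frame(bregma, lam)
    dura = DuralSurface.from_mask(brain_mask)

    region = None
    region_path = indir / "target_region.nii.gz"
    if region_path.exists():
        from .atlas_regions import region_from_labelmap
        region = region_from_labelmap("target", read_volume(region_path, "LABEL"))

    all_trajs: list[Trajectory] = []
    errors: list[TargetingErrors] = []
    outdir.mkdir(parents=True, exist_ok=True)
    for animal in manifest_in["animals"]:
        adir = indir / "animals" / animal
        row = plan_df.iloc[0]
        plan = derive_planned(
            (row["AP"], row["ML"], row["DV_depth"]), row["alpha_deg"],
            row["beta_deg"], row["hemisphere"], dura, frame)
        mods = {}
        wanted = (["MRIpost", "CTpost"] if config.route == "exp2"
                  else ["MRIpre", "CTpre", "MRIpost"])
        for name in wanted:
            p = adir / f"{name}.nii.gz"
            if p.exists():
                mods[name] = read_volume(p)
        chains = _resolve_chains(config, adir, mods, template)
        log("register", f"{animal}: {config.registration} transforms for {sorted(chains)}")
        trajs = _reconstruct_sources(config, mods, chains, plan, dura, animal,
                                     brain_mask)
        for src, traj in trajs.items():
            all_trajs.append(traj)
            errors.append(targeting_errors(traj, plan, frame, region))
            log("reconstruct", f"{animal}/{src}: tip {np.round(traj.tip, 3).tolist()}")
        # QC projections
        if "MRIpost" in mods:
            proj = render_projection(mods["MRIpost"], "mIP", axis=1)
            save_projection_png(proj, outdir / "qc" / f"{animal}_MRIpost_mIP.png",
                                f"{animal} MRIpost mIP")
        if "CTpost" in mods:
            proj = render_projection(mods["CTpost"], "MIP", axis=1)
            save_projection_png(proj, outdir / "qc" / f"{animal}_CTpost_MIP.png",
                                f"{animal} CTpost MIP")

    traj_table = trajectories_to_table(all_trajs)
    traj_table.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    metrics_df = pd.DataFrame([e.as_row() for e in errors])
    metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    summary = cohort_table(errors)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "route": config.route,
        "n_trajectories": len(all_trajs),
        "outputs": ["trajectories.tsv", "metrics.tsv", "summary.tsv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"trajectories": traj_table, "metrics": metrics_df,
            "summary": summary, "manifest": manifest}


def _resolve_chains(config: PipelineConfig, adir: Path, mods: dict,
                    template: Volume3D) -> dict[str, list[AffineTransform]]:
    chains: dict[str, list[AffineTransform]] = {}
    for name in mods:
        if config.registration == "identity":
            chains[name] = [identity_transform()]
        elif config.registration == "truth":
            p = adir / "transforms" / f"{name}_to_template.json"
            if not p.exists():
                raise ConfigurationError(f"missing truth transform: {p}")
            chains[name] = [AffineTransform.from_json(p)]
        elif config.registration == "estimate":
            chains[name] = [_registration_route(config.route, name, mods, template)]
        else:
            raise ConfigurationError(
                f"unknown registration mode: {config.registration!r}")
    return chains


def _registration_route(route: str, name: str, mods: dict,
                        template: Volume3D) -> AffineTransform:
    """Chain per study design, composed into a single to-template map."""
    if route == "exp2":
        mripost_to_tpl = register_mi(mods["MRIpost"], template, "rigid6")
        if name == "MRIpost":
            return mripost_to_tpl
        ct_to_mripost = register_mi(mods["CTpost"], mods["MRIpost"], "rigid6")
        return compose(mripost_to_tpl, ct_to_mripost)
    # exp1
    mripre_to_tpl = register_mi(mods["MRIpre"], template, "rigid6")
    if name == "MRIpre":
        return mripre_to_tpl
    if name == "CTpre":
        return compose(mripre_to_tpl, register_mi(mods["CTpre"], mods["MRIpre"], "rigid6"))
    return compose(mripre_to_tpl,
                   register_mi(mods["MRIpost"], mods["MRIpre"], "affine12"))


def _reconstruct_sources(config: PipelineConfig, mods: dict, chains: dict,
                         plan, dura: DuralSurface, animal: str,
                         brain_mask: Volume3D) -> dict[str, Trajectory]:
    settings = config.segmentation
    roi = _plan_roi(plan, settings.roi_margin_mm)
    hemi = plan.hemisphere
    out: dict[str, Trajectory] = {}
    if "MRIpost" in mods and any(s in config.sources for s in ("mri", "rec-mri")):
        chain = chains["MRIpost"]
        roi_native = _map_roi(roi, invert(chain[0]))
        brain_native = _native_mask(brain_mask, chain[0], mods["MRIpost"])
        mask = segment_trace_mri(mods["MRIpost"], roi_native, settings.mri_mode,
                                 settings.mri_value, within=brain_native)
        if "mri" in config.sources:
            out["mri"] = to_template(
                trajectory_from_mask(mask, "mri", "native", hemi, animal), chain)
        if "rec-mri" in config.sources:
            centroid, direction, _ = principal_axis(mask)
            c_t, d_t = _map_axis(centroid, direction, chain)
            out["rec-mri"] = reconstruct_from_axis(
                c_t, d_t, dura, plan.d_plan, "rec-mri", "template", hemi, animal)
    if ("CTpost" in mods and config.route == "exp2"
            and any(s in config.sources for s in ("ct", "rec-ct"))):
        chain = chains["CTpost"]
        roi_native = _map_roi(roi, invert(chain[0]))
        mask = segment_electrode_ct(mods["CTpost"], roi_native,
                                    settings.ct_threshold, settings.ct_erosion_mm)
        if "ct" in config.sources:
            out["ct"] = to_template(
                trajectory_from_mask(mask, "ct", "native", hemi, animal), chain)
        if "rec-ct" in config.sources:
            centroid, direction, _ = principal_axis(mask)
            c_t, d_t = _map_axis(centroid, direction, chain)
            out["rec-ct"] = reconstruct_from_axis(
                c_t, d_t, dura, plan.d_plan, "rec-ct", "template", hemi, animal)
    return out
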