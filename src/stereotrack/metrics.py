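"""Per-trajectory targeting errors and cohort statistics.

Offsets are actual minus planned, resolved on the stereotaxic axes, so
a negative offset is more posterior (AP), toward the animal's left (ML)
or more ventral (DV).  For reconstructed (``rec-*``) trajectories the
DV offsets use the depth-along-trajectory convention: the entry sits on
the dural surface by construction (depth 0, like the planned entry) and
the tip at exactly the planned distance from it, so both DV offsets are
identically zero — the reconstruction assumes no inaccuracy in
insertion depth, and the statistics must reflect that rather than
re-measure it.

Significance stars follow the reporting convention ***p < 0.001,
**p < 0.005, *p < 0.05.  One-sided t-tests against zero take the
direction of the observed sample mean.  No multiple-testing correction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import atlas_regions
from .errors import InputError
from .stereotaxic_frame import PlannedTrajectory, StereotaxicFrame
from .trajectory import Trajectory

__all__ = [
    "TargetingErrors",
    "GroupStats",
    "targeting_errors",
    "one_sided_t_vs_zero",
    "paired_compare",
    "pearson",
    "cohort_table",
    "stars",
]


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TargetingErrors:
    """Offsets of one actual trajectory from its plan (mm / deg)."""

    traj_id: str
    source: str
    d_target: np.ndarray      # (dAP, dML, dDV) at target
    d_entry: np.ndarray       # (dAP, dML, dDV) at entry
    ed_target: float
    ed_entry: float
    d_alpha: float
    d_beta: float
    in_target: str            # inside | outside | indeterminate | n/a
    dv_convention: str        # axis | depth-along-trajectory

    def as_row(self) -> dict:
        return {
            "id": self.traj_id, "source": self.source,
            "dAP_T": self.d_target[0], "dML_T": self.d_target[1],
            "dDV_T": self.d_target[2], "ED_T": self.ed_target,
            "dAP_E": self.d_entry[0], "dML_E": self.d_entry[1],
            "dDV_E": self.d_entry[2], "ED_E": self.ed_entry,
            "dAlpha": self.d_alpha, "dBeta": self.d_beta,
            "in_target": self.in_target, "dv_convention": self.dv_convention,
        }


@dataclass(frozen=True)
class GroupStats:
    """n, mean +/- sd and the test outcome for one error component."""

    n: int
    mean: float
    sd: float
    t: float
    p: float
    stars: str
    kind: str = "one-sided-t"
    r: float | None = None  # Pearson R when kind == 'pearson'


def targeting_errors(actual: Trajectory, planned: PlannedTrajectory,
                     frame: StereotaxicFrame,
                     region: atlas_regions.TargetRegion | None = None,
                     gap_tolerance_mm: float | None = None) -> TargetingErrors:
    """Offsets of ``actual`` from ``planned`` on the stereotaxic axes.

    Reconstructed sources switch the DV components to the
    depth-along-trajectory convention (exact zeros); the convention used
    is recorded alongside the numbers.
    """
    if actual.space != "template":
        raise InputError(
            f"trajectory {actual.traj_id!r} is in space {actual.space!r}; "
            "targeting errors are defined in template space"
        )
    dt = np.asarray(actual.tip, float) - planned.target
    de = np.asarray(actual.entry, float) - planned.entry
    d_target = np.array([dt @ frame.ap_axis, dt @ frame.ml_axis, dt @ frame.dv_axis])
    d_entry = np.array([de @ frame.ap_axis, de @ frame.ml_axis, de @ frame.dv_axis])
    convention = "axis"
    if actual.source.startswith("rec"):
        convention = "depth-along-trajectory"
        # entry: both points lie on the dural surface, depth 0 each;
        # target: depth along trajectory is D = D_plan exactly
        d_entry[2] = 0.0
        d_target[2] = actual.depth - planned.d_plan
    ed_target = float(np.linalg.norm(d_target))
    ed_entry = float(np.linalg.norm(d_entry))
    d_alpha = actual.alpha - planned.alpha
    d_beta = actual.beta - planned.beta
    membership = "n/a"
    if region is not None:
        membership = atlas_regions.in_target(actual.tip, region, gap_tolerance_mm)
    return TargetingErrors(actual.traj_id, actual.source, d_target, d_entry,
                           ed_target, ed_entry, float(d_alpha), float(d_beta),
                           membership, convention)


def one_sided_t_vs_zero(differences: np.ndarray) -> GroupStats:
    """One-sample t-test against zero mean, one-sided in the direction of
    the observed mean (t = mean / (sd / sqrt(n)), df = n - 1)."""
    x = np.asarray(differences, float)
    if x.ndim != 1 or len(x) < 2:
        raise InputError("need at least 2 finite differences")
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite differences")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf * np.sign(mean)
        p = 0.5 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(stats.t.sf(abs(t), n - 1))
    return GroupStats(n, mean, sd, float(t), p, stars(p))


def paired_compare(a: np.ndarray, b: np.ndarray) -> GroupStats:
    """Two-tailed paired t-test on a - b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("paired comparison needs equal-length vectors, n >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return GroupStats(n, mean, sd, 0.0, 1.0, "", kind="paired-t")
        # constant nonzero difference: degenerate, report p ~ 0 loudly
        import warnings
        warnings.warn("paired_compare: zero-variance nonzero difference",
                      RuntimeWarning, stacklevel=2)
        return GroupStats(n, mean, sd, float(np.inf * np.sign(mean)),
                          1e-300, stars(1e-300), kind="paired-t")
    t, p = stats.ttest_rel(a, b)
    return GroupStats(n, mean, sd, float(t), float(p), stars(float(p)),
                      kind="paired-t")


def pearson(x: np.ndarray, y: np.ndarray) -> GroupStats:
    """Pearson correlation with a two-tailed p via the t-transform (df = n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("Pearson correlation needs equal-length vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise InputError("Pearson correlation undefined for zero variance")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    n = len(x)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    return GroupStats(n, float(np.mean(x - y)), float(np.std(x - y, ddof=1)),
                      float(t), p, stars(p), kind="pearson", r=r)


# -- cohort reporting -----------------------------------------------------

_COMPONENTS = [
    ("dAP_T", "target AP (mm)"), ("dML_T", "target ML (mm)"),
    ("dDV_T", "target DV (mm)"), ("ED_T", "target ED (mm)"),
    ("dAP_E", "entry AP (mm)"), ("dML_E", "entry ML (mm)"),
    ("dDV_E", "entry DV (mm)"), ("ED_E", "entry ED (mm)"),
    ("dAlpha", "delta alpha (deg)"), ("dBeta", "delta beta (deg)"),
]


def cohort_table(errors: list[TargetingErrors],
                 group_by_source: bool = True) -> pd.DataFrame:
    """Group summary: per-axis mean +/- sd with stars, EDs (means of the
    per-trajectory EDs), max |d_alpha| / |d_beta|, and fraction in target.
    """
    if not errors:
        raise InputError("no targeting errors to summarize")
    df = pd.DataFrame([e.as_row() for e in errors])
    groups = df.groupby("source") if group_by_source else [("all", df)]
    rows = []
    for source, g in groups:
        row: dict = {"source": source, "n": len(g)}
        for col, label in _COMPONENTS:
            vals = g[col].to_numpy(float)
            if len(vals) >= 2:
                gs = one_sided_t_vs_zero(vals)
                row[f"{col}_mean"] = gs.mean
                row[f"{col}_sd"] = gs.sd
                row[f"{col}_p"] = gs.p
                row[f"{col}_stars"] = gs.stars
            else:
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = 0.0
                row[f"{col}_p"] = np.nan
                row[f"{col}_stars"] = ""
        row["dAlpha_max_abs"] = float(np.abs(g["dAlpha"]).max())
        row["dBeta_max_abs"] = float(np.abs(g["dBeta"]).max())
        determinate = g[g["in_target"] != "indeterminate"]
        row["n_indeterminate"] = int((g["in_target"] == "indeterminate").sum())
        if (determinate["in_target"] != "n/a").any():
            row["fraction_in_target"] = float(
                (determinate["in_target"] == "inside").mean())
        else:
            row["fraction_in_target"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
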