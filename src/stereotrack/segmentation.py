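"""Electrode (CT) and trace (MRI) segmentation.

CT keeps voxels at or above an intensity threshold inside a world-space
cuboid ROI (the electrode is hyper-intense); MRI keeps voxels at or
below a cutoff (the retraction trace is hypo-intense).  The CT mask is
additionally cut back from its dorsal end along DV to exclude residual
dental cement near the entry — a deterministic depth cut, not a
morphological erosion.  The largest 26-connected component is kept,
with ties broken by voxel count then by the more ventral centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .volume_io import Modality, Volume3D

__all__ = ["ElectrodeMask", "segment_electrode_ct", "segment_trace_mri", "ingest_mask"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ElectrodeMask:
    """Boolean electrode/trace mask with its provenance."""

    mask: Volume3D
    source_modality: Modality
    roi_world: np.ndarray | None  # (2, 3) min/max world mm, or None
    threshold: float | None
    erosion_mm: float = 0.0
    n_components_raw: int = 1
    boundary_warning: bool = False

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask.data))

    def world_points(self) -> np.ndarray:
        """World coordinates of the centers of the masked voxels."""
        idx = np.argwhere(np.asarray(self.mask.data) > 0)
        return self.mask.voxel_to_world(idx.astype(float))


def _roi_slices(v: Volume3D, roi_world: np.ndarray | None) -> tuple[slice, slice, slice]:
    if roi_world is None:
        return (slice(None),) * 3  # type: ignore[return-value]
    roi = np.asarray(roi_world, float).reshape(2, 3)
    corners = np.array([[roi[i, 0], roi[j, 1], roi[k, 2]]
                        for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    vox = v.world_to_voxel(corners)
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, np.array(v.shape))
    if np.any(lo >= hi):
        raise SegmentationError("ROI does not intersect the volume grid")
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def _largest_component(binary: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n <= 1:
        return binary, n
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    top = counts.max()
    tied = [lab for lab in range(1, n + 1) if counts[lab] == top]
    if len(tied) > 1:
        # more ventral centroid wins (lower k under a dorsal-positive affine)
        cents = ndimage.center_of_mass(binary, labels, tied)
        best = tied[int(np.argmin([c[2] for c in cents]))]
    return labels == best, n


def _dorsal_cut(binary: np.ndarray, v: Volume3D, slices, erosion_mm: float) -> np.ndarray:
    """Remove voxels within ``erosion_mm`` of the mask's dorsal-most DV level."""
    if erosion_mm <= 0 or not binary.any():
        return binary
    idx = np.argwhere(binary).astype(float)
    idx += [s.start or 0 for s in slices]
    z = v.voxel_to_world(idx)[:, 2]
    keep = z <= z.max() - erosion_mm
    out = binary.copy()
    coords = np.argwhere(binary)
    out[tuple(coords[~keep].T)] = False
    return out


def _finalize(binary: np.ndarray, v: Volume3D, slices, modality: Modality,
              roi_world, threshold, erosion_mm) -> ElectrodeMask:
    if not binary.any():
        raise SegmentationError("segmentation produced an empty mask")
    binary, n_raw = _largest_component(binary)
    if erosion_mm > 0:
        binary = _dorsal_cut(binary, v, slices, erosion_mm)
        if not binary.any():
            raise SegmentationError("mask empty after dorsal erosion")
    full = np.zeros(v.shape, dtype=np.uint8)
    full[slices] = binary.astype(np.uint8)
    warn = _touches_boundary(binary)
    mask_vol = Volume3D(full, v.affine.copy(), Modality.MASK)
    return ElectrodeMask(mask_vol, modality, None if roi_world is None
                         else np.asarray(roi_world, float), threshold,
                         erosion_mm, n_raw, warn)


def _touches_boundary(binary: np.ndarray) -> bool:
    return bool(
        binary[0].any() or binary[-1].any() or binary[:, 0].any()
        or binary[:, -1].any() or binary[:, :, 0].any() or binary[:, :, -1].any()
    )


def segment_electrode_ct(v: Volume3D, roi_world: np.ndarray | None,
                         threshold: float, erosion_mm: float = 0.7) -> ElectrodeMask:
    """Threshold the hyper-intense electrode in a post-operative CT.

    Keeps ROI voxels with intensity >= ``threshold``, removes the dorsal
    ``erosion_mm`` band (cement exclusion), keeps the largest 26-connected
    component.  The threshold (``I_max-ct``) is a per-image setting.
    """
    slices = _roi_slices(v, roi_world)
    sub = np.asarray(v.data, float)[slices]
    return _finalize(sub >= threshold, v, slices, Modality.CT, roi_world,
                     float(threshold), erosion_mm)


def segment_trace_mri(v: Volume3D, roi_world: np.ndarray | None,
                      threshold_mode: str = "percentile",
                      value: float = 50.0,
                      within: Volume3D | None = None) -> ElectrodeMask:
    """Threshold the hypo-intense electrode trace in a post-operative MRI.

    ``threshold_mode='absolute'`` keeps ROI voxels <= ``value``;
    ``'percentile'`` keeps voxels at or below that percentile of the ROI
    intensities.  ``within`` optionally restricts the search to a mask on
    the same grid (typically the brain mask: the trace is by definition
    intra-cerebral, and skull/background are also dark in T2*-weighted
    MRI).  No dorsal erosion is applied by default.
    """
    slices = _roi_slices(v, roi_world)
    sub = np.asarray(v.data, float)[slices]
    allowed = None
    if within is not None:
        if within.shape != v.shape:
            raise SegmentationError("'within' mask must share the volume grid")
        allowed = np.asarray(within.data)[slices] > 0
        if not allowed.any():
            raise SegmentationError("ROI does not intersect the brain mask")
    if threshold_mode == "absolute":
        cutoff = float(value)
    elif threshold_mode == "percentile":
        if not 0 <= value <= 100:
            raise SegmentationError("percentile must be in [0, 100]")
        pool = sub[allowed] if allowed is not None else sub
        cutoff = float(np.percentile(pool, value))
    else:
        raise SegmentationError(f"unknown threshold mode: {threshold_mode!r}")
    binary = sub <= cutoff
    if allowed is not None:
        binary &= allowed
    return _finalize(binary, v, slices, Modality.MRI, roi_world, cutoff, 0.0)


def ingest_mask(mask: Volume3D, source_modality: Modality | str,
                provenance_threshold: float | None = None) -> ElectrodeMask:
    """Wrap a hand-drawn (e.g. manually delineated) mask unchanged."""
    data = np.asarray(mask.data) > 0
    if not data.any():
        raise SegmentationError("ingested mask is empty")
    labels, n = ndimage.label(data, structure=_CONN26)
    vol = Volume3D(data.astype(np.uint8), mask.affine.copy(), Modality.MASK)
    return ElectrodeMask(vol, Modality(source_modality), None,
                         provenance_threshold, 0.0, n, _touches_boundary(data))
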