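"""Local and global interhemispheric differences of FA-thresholded averages.

The global statistic is the healthy-hemisphere mean minus the tumor-side
hemisphere mean of a scalar map, averaged over voxels whose FA exceeds a
threshold (default 0.2, which excludes gray matter and tumor tissue).
Local differences use mirrored spheres of growing radius around the tumor
center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dti import ScalarMap

__all__ = [
    "ROISpec",
    "DeltaResult",
    "center_of_mass",
    "hemisphere_masks",
    "thresholded_mean",
    "local_deltas",
    "global_delta",
    "sphere_mask",
]

FA_THRESHOLD_DEFAULT = 0.2
DEFAULT_RADII_MM = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

# local difference sign: contralateral minus ipsilateral
LOCAL_DELTA_SIGN = +1


@dataclass
class ROISpec:
    """Sphere centers/radii for the local analysis."""

    center: tuple[float, float, float]  # voxel coords, real-valued
    radii: tuple[float, ...] = DEFAULT_RADII_MM  # mm, strictly increasing
    restrict_to_hemisphere: bool = True

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")


@dataclass
class DeltaResult:
    """Interhemispheric differences for one session."""

    session_id: str
    global_deltas: dict[str, float]  # metric -> healthy mean - tumor-side mean
    local_deltas: dict[float, float] = field(default_factory=dict)  # radius -> dFA
    n_voxels_healthy: int = 0
    n_voxels_tumor_side: int = 0
    fa_threshold: float = FA_THRESHOLD_DEFAULT
    valid: bool = True
    notes: list[str] = field(default_factory=list)


def center_of_mass(mask: np.ndarray) -> np.ndarray:
    """Unweighted mean coordinate of the foreground voxels."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no center of mass")
    return np.argwhere(mask).mean(axis=0)


def hemisphere_masks(brain_mask: np.ndarray, midsagittal_x: float):
    """Split a brain mask at the midsagittal plane into (left, right).

    An integer plane index excludes that voxel column from both hemispheres;
    a half-integer plane (even-sized grids) partitions every column.
    """
    brain_mask = np.asarray(brain_mask, bool)
    nx = brain_mask.shape[0]
    if not -0.5 <= midsagittal_x <= nx - 0.5:
        raise ValueError(f"midsagittal plane {midsagittal_x} outside grid (nx={nx})")
    x = np.arange(nx, dtype=float).reshape(-1, 1, 1)
    left = brain_mask & (x < midsagittal_x)
    right = brain_mask & (x > midsagittal_x)
    return left, right


def thresholded_mean(scalar: ScalarMap | np.ndarray, region: np.ndarray,
                     fa_map: ScalarMap | np.ndarray,
                     fa_threshold: float = FA_THRESHOLD_DEFAULT,
                     tumor_mask: np.ndarray | None = None):
    """Mean of ``scalar`` over region voxels with FA above the threshold.

    Returns ``(mean, n_voxels, valid)``; an empty surviving set yields
    ``(nan, 0, False)`` rather than raising. When a tumor mask is supplied,
    a programmatic quality check asserts that no tumor voxel survives the
    FA threshold (the replacement for a visual T2 inspection).
    """
    data = scalar.data if isinstance(scalar, ScalarMap) else np.asarray(scalar, float)
    fa = fa_map.data if isinstance(fa_map, ScalarMap) else np.asarray(fa_map, float)
    if data.shape != fa.shape:
        raise ValueError("scalar map and FA map must share a grid")
    surv = np.asarray(region, bool) & (fa > fa_threshold)
    if tumor_mask is not None:
        overlap = int(np.count_nonzero(surv & np.asarray(tumor_mask, bool)))
        if overlap:
            raise ValueError(
                f"quality check failed: {overlap} tumor voxels survive the "
                f"FA threshold {fa_threshold}"
            )
    n = int(np.count_nonzero(surv))
    if n == 0:
        return float("nan"), 0, False
    return float(data[surv].mean()), n, True


def sphere_mask(shape, center_voxel, radius_mm, voxel_size) -> np.ndarray:
    """Voxels whose centers lie within ``radius_mm`` of the (real-valued) center."""
    vs = np.asarray(voxel_size, float)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center_voxel, vs))
    return d2 <= radius_mm**2


def local_deltas(fa_map: ScalarMap, roi: ROISpec, hemis, midsagittal_x: float,
                 fa_threshold: float = FA_THRESHOLD_DEFAULT,
                 tumor_mask: np.ndarray | None = None) -> dict[float, float | None]:
    """Contralateral-minus-ipsilateral thresholded mean FA per sphere radius.

    The ipsilateral sphere sits at the ROI center clipped to its hemisphere;
    the contralateral sphere is its mirror across the midsagittal plane,
    clipped to the other hemisphere. Radii whose spheres retain no
    suprathreshold voxels map to ``None``.
    """
    left, right = hemis
    cx = roi.center[0]
    ipsi, contra = (left, right) if cx < midsagittal_x else (right, left)
    mirror_center = (2 * midsagittal_x - roi.center[0],) + tuple(roi.center[1:])

    out: dict[float, float | None] = {}
    for r in roi.radii:
        s_i = sphere_mask(fa_map.data.shape, roi.center, r, fa_map.voxel_size)
        s_c = sphere_mask(fa_map.data.shape, mirror_center, r, fa_map.voxel_size)
        if roi.restrict_to_hemisphere:
            s_i &= ipsi
            s_c &= contra
        m_i, n_i, ok_i = thresholded_mean(fa_map, s_i, fa_map, fa_threshold,
                                          tumor_mask)
        m_c, n_c, ok_c = thresholded_mean(fa_map, s_c, fa_map, fa_threshold)
        out[float(r)] = LOCAL_DELTA_SIGN * (m_c - m_i) if (ok_i and ok_c) else None
    return out


def global_delta(maps: dict[str, ScalarMap], hemis, tumor_hemisphere: str,
                 fa_threshold: float = FA_THRESHOLD_DEFAULT,
                 session_id: str = "", tumor_mask: np.ndarray | None = None,
                 roi: ROISpec | None = None,
                 midsagittal_x: float | None = None) -> DeltaResult:
    """Whole-hemisphere interhemispheric differences for every metric.

    All metrics are averaged over the same FA-thresholded voxel set
    (thresholding always on the FA map). Controls (``tumor_hemisphere`` =
    "none") use the fixed signed left-minus-right convention.
    """
    if tumor_hemisphere not in ("left", "right", "none"):
        raise ValueError(f"invalid hemisphere label {tumor_hemisphere!r}")
    left, right = hemis
    if tumor_hemisphere == "left":
        tumor_side, healthy_side = left, right
    else:  # "right" or the control convention (delta = left - right)
        tumor_side, healthy_side = right, left

    fa = maps["FA"]
    notes: list[str] = []
    deltas: dict[str, float] = {}
    n_h = n_t = 0
    valid = True
    for metric, sm in maps.items():
        m_h, n_h_m, ok_h = thresholded_mean(sm, healthy_side, fa, fa_threshold)
        m_t, n_t_m, ok_t = thresholded_mean(sm, tumor_side, fa, fa_threshold,
                                            tumor_mask if metric == "FA" else None)
        if metric == "FA":
            n_h, n_t = n_h_m, n_t_m
        if not (ok_h and ok_t):
            valid = False
            notes.append(f"{metric}: empty thresholded hemisphere")
            deltas[metric] = float("nan")
        else:
            deltas[metric] = m_h - m_t

    result = DeltaResult(session_id=session_id, global_deltas=deltas,
                         n_voxels_healthy=n_h, n_voxels_tumor_side=n_t,
                         fa_threshold=fa_threshold, valid=valid, notes=notes)
    if roi is not None and midsagittal_x is not None and tumor_hemisphere != "none":
        result.local_deltas = local_deltas(fa, roi, hemis, midsagittal_x,
                                           fa_threshold, tumor_mask)
    return result
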