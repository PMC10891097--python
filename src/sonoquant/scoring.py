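"""Per-emitter BBB-disruption grading from pre/post contrast T1w MRI.

After each sonication, gadolinium leaks through the opened blood-brain
barrier and enhances the post-contrast T1-weighted image inside the
sonicated cylinders.  This module turns a co-registered pre/post pair into
a relative enhancement map, thresholds it against non-sonicated control
tissue, and assigns each emitter a 0-3 opening grade:

* grade 0 - enhanced volume at or below the minimum graded volume,
* grade 1 - enhancement essentially confined to the subarachnoid space,
* grade 2 - enhancement reaching gray matter,
* grade 3 - enhancement reaching gray and white matter.

A session is a success when at least two-thirds of the evaluable emitters
reach grade 2-3.  Emitters whose cylinder is dominated by resection cavity
or pre-enhancing tumor are excluded from grading.  Two session-level
summaries accompany the grades: the I90 intensity metric (90th percentile
of relative enhancement over the evaluable sonicated ROI, the quantity the
closure-kinetics fit consumes) and the opening depth (largest axial
distance from the plate plane reached by suprathreshold enhancement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import EmitterArray, ROILabelMap, VoxelGrid, _axial_radial_coords

__all__ = [
    "TissueSegmentation",
    "ScoringConfig",
    "EmitterResult",
    "SessionScore",
    "EnhancementMap",
    "compute_enhancement_map",
    "control_threshold",
    "evaluable_emitters",
    "score_emitter",
    "score_session",
]

# tissue labels
BACKGROUND, SUBARACHNOID, GRAY, WHITE, CAVITY, TUMOR = range(6)
#: labels that enhance before sonication and are excluded from grading
PRE_ENHANCING_LABELS = (CAVITY, TUMOR)


@dataclass(frozen=True)
class TissueSegmentation:
    """Integer tissue label volume sharing the image grid.

    Labels: 0 background, 1 subarachnoid/CSF, 2 gray matter, 3 white
    matter, 4 resection cavity, 5 enhancing tumor.
    """

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ValueError("segmentation shape must match grid")
        if labels.min() < 0 or labels.max() > 5:
            raise ValueError("tissue labels must lie in 0..5")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable thresholds of the automated grading rule.

    ``control_tail_fraction`` is the upper-tail mass of control-tissue
    enhancement used to set the detection threshold; ``min_graded_volume_mL``
    is the minimum enhanced volume for a nonzero grade.
    """

    control_tail_fraction: float = 0.01
    min_graded_volume_mL: float = 0.5
    exclusion_overlap_fraction: float = 0.30
    subarachnoid_confinement_fraction: float = 0.90
    white_volume_for_grade3_mL: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "control_tail_fraction",
            "exclusion_overlap_fraction",
            "subarachnoid_confinement_fraction",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_graded_volume_mL <= 0 or self.white_volume_for_grade3_mL <= 0:
            raise ValueError("volume thresholds must be positive")


@dataclass(frozen=True)
class EnhancementMap:
    """Voxelwise relative pre-to-post gadolinium enhancement."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError("enhancement map shape must match grid")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class EmitterResult:
    emitter_id: int
    evaluable: bool
    enhanced_volume_mL: float = float("nan")
    grade: int | None = None


@dataclass(frozen=True)
class SessionScore:
    emitters: tuple[EmitterResult, ...]
    success: bool
    i90: float
    depth_mm: float
    tau: float

    @property
    def n_evaluable(self) -> int:
        return sum(e.evaluable for e in self.emitters)

    @property
    def n_opened(self) -> int:
        return sum(e.evaluable and e.grade is not None and e.grade >= 2 for e in self.emitters)


def compute_enhancement_map(
    pre: np.ndarray,
    post: np.ndarray,
    grid: VoxelGrid,
    brain_mask: np.ndarray,
    reference_mask: np.ndarray,
) -> EnhancementMap:
    """Relative enhancement (post - pre)/pre after reference normalization.

    The post image is rescaled so its median over ``reference_mask`` (a
    non-sonicated, non-pathological region) matches the pre image's,
    removing global intensity scaling between acquisitions.  The map is
    zero outside the brain; the denominator is floored at 1% of the pre
    image's brain median to keep near-zero voxels finite.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape or pre.shape != grid.shape:
        raise ValueError("pre, post and grid shapes must match")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_pre = float(np.median(pre[reference_mask]))
    ref_post = float(np.median(post[reference_mask]))
    if ref_post <= 0:
        raise ValueError("post image median over reference mask is non-positive")
    post_scaled = post * (ref_pre / ref_post)
    eps = 0.01 * float(np.median(pre[brain_mask]))
    denom = np.maximum(pre, max(eps, np.finfo(float).tiny))
    values = np.where(brain_mask, (post_scaled - pre) / denom, 0.0)
    return EnhancementMap(grid=grid, values=values)


def control_threshold(
    emap: EnhancementMap,
    control_mask: np.ndarray,
    config: ScoringConfig | None = None,
) -> float:
    """Detection threshold from the upper tail of control-tissue enhancement.

    Returns the enhancement value exceeded by ``control_tail_fraction`` of
    control voxels (the 1 - fraction linear-interpolation quantile),
    floored at zero.
    """
    config = config or ScoringConfig()
    control_mask = np.asarray(control_mask, dtype=bool)
    if not control_mask.any():
        raise ValueError("control mask is empty")
    vals = emap.values[control_mask]
    if np.ptp(vals) == 0:
        warnings.warn("control region is constant; threshold degenerate", stacklevel=2)
        return max(float(vals.flat[0]), 0.0)
    tau = float(np.quantile(vals, 1.0 - config.control_tail_fraction))
    return max(tau, 0.0)


def evaluable_emitters(
    rois: ROILabelMap,
    seg: TissueSegmentation,
    config: ScoringConfig | None = None,
) -> np.ndarray:
    """Flag emitters whose cylinder is gradable.

    An emitter is excluded when resection cavity plus pre-enhancing tumor
    occupy strictly more than ``exclusion_overlap_fraction`` of its
    cylinder (such enhancement pre-dates the sonication and confounds the
    map).  Returns nine booleans, index 0 = emitter 1.
    """
    config = config or ScoringConfig()
    if rois.grid.shape != seg.grid.shape:
        raise ValueError("ROI and segmentation grids must match")
    excluded_tissue = np.isin(seg.labels, PRE_ENHANCING_LABELS)
    flags = np.ones(9, dtype=bool)
    for k in range(1, 10):
        cyl = rois.mask(k)
        n = int(cyl.sum())
        if n == 0:
            flags[k - 1] = False
            continue
        frac = float((cyl & excluded_tissue).sum()) / n
        flags[k - 1] = frac <= config.exclusion_overlap_fraction
    return flags


def _enhanced_mask(
    emap: EnhancementMap, tau: float, roi_mask: np.ndarray, seg: TissueSegmentation
) -> np.ndarray:
    """Suprathreshold voxels inside the ROI, restricted to brain tissue
    that was not enhancing before sonication."""
    gradable = np.isin(seg.labels, (SUBARACHNOID, GRAY, WHITE))
    return (emap.values > tau) & roi_mask & gradable


def score_emitter(
    emap: EnhancementMap,
    tau: float,
    rois: ROILabelMap,
    emitter_id: int,
    seg: TissueSegmentation,
    config: ScoringConfig | None = None,
) -> EmitterResult:
    """Assign a 0-3 BBB opening grade to one (evaluable) emitter.

    Enhanced volume below the minimum graded volume is grade 0; otherwise
    predominantly subarachnoid enhancement is grade 1, gray-matter
    enhancement grade 2, and gray plus substantial white-matter enhancement
    grade 3.
    """
    if tau is None or not np.isfinite(tau):
        raise ValueError("detection threshold tau is required")
    config = config or ScoringConfig()
    enhanced = _enhanced_mask(emap, tau, rois.mask(emitter_id), seg)
    vox_mL = rois.grid.voxel_volume_mm3 / 1000.0
    v_e = float(enhanced.sum()) * vox_mL
    if v_e <= config.min_graded_volume_mL:
        grade = 0
    else:
        labels = seg.labels[enhanced]
        frac_sub = float((labels == SUBARACHNOID).sum()) / labels.size
        if frac_sub >= config.subarachnoid_confinement_fraction:
            grade = 1
        elif float((labels == WHITE).sum()) * vox_mL > config.white_volume_for_grade3_mL:
            grade = 3
        else:
            grade = 2
    return EmitterResult(
        emitter_id=emitter_id, evaluable=True, enhanced_volume_mL=v_e, grade=grade
    )


def score_session(
    emap: EnhancementMap,
    tau: float,
    rois: ROILabelMap,
    seg: TissueSegmentation,
    array: EmitterArray,
    config: ScoringConfig | None = None,
) -> SessionScore:
    """Grade all emitters of one sonication session and summarize it.

    Success requires grade >= 2 on at least two-thirds of evaluable
    emitters.  I90 is the 90th percentile of relative enhancement over the
    union of evaluable cylinders; depth is the maximum axial coordinate
    (mm from the plate plane) of any suprathreshold enhanced voxel there,
    zero when nothing is enhanced.
    """
    config = config or ScoringConfig()
    flags = evaluable_emitters(rois, seg, config)
    if not flags.any():
        raise ValueError("no evaluable emitter in session")
    results: list[EmitterResult] = []
    enhanced_union = np.zeros(rois.grid.shape, dtype=bool)
    roi_union = np.zeros(rois.grid.shape, dtype=bool)
    for k in range(1, 10):
        if not flags[k - 1]:
            results.append(EmitterResult(emitter_id=k, evaluable=False))
            continue
        results.append(score_emitter(emap, tau, rois, k, seg, config))
        roi_union |= rois.mask(k)
        enhanced_union |= _enhanced_mask(emap, tau, rois.mask(k), seg)
    n_eval = int(flags.sum())
    n_open = sum(r.evaluable and r.grade >= 2 for r in results)
    success = n_open / n_eval >= 2.0 / 3.0
    i90 = float(np.percentile(emap.values[roi_union], 90)) if roi_union.any() else 0.0
    if enhanced_union.any():
        s, _ = _axial_radial_coords(array, rois.grid)
        labels_flat = rois.labels.ravel()
        idx = np.flatnonzero(enhanced_union.ravel())
        # axial coordinate measured along the emitter owning each voxel
        depth = float(s[labels_flat[idx] - 1, idx].max())
    else:
        depth = 0.0
    return SessionScore(
        emitters=tuple(results), success=success, i90=i90, depth_mm=depth, tau=tau
    )
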