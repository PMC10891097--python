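"""Synthetic study generator: phantoms, sessions, closure data, cohorts.

No patient imaging is distributed with the trial, so every analysis in
this package is exercised on synthetic data whose generative model
mirrors the quantities the pipeline measures:

* a geometric head phantom -- planar tissue layers under the implant
  plate (subarachnoid rim, gray ribbon, white core) with optional
  spherical resection cavity and enhancing tumor -- co-registered by
  construction, removing the registration steps the real pipeline
  delegates to external tools;
* pre/post sonication pairs with enhancement injected into the planned
  tissue classes of each emitter's 10 x 75 mm cylinder, the amplitude
  decaying exponentially with the sonication-to-contrast delay;
* (delay, intensity) closure datasets with delays uniform on the
  observed 10-77 min scheduling window; and
* longitudinal growth cohorts with patient slopes drawn around a cohort
  median, optionally rasterized to voxel tumor masks whose near-axis
  growth is suppressed in the chemotherapy-before-sonication cohort.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import TumorTrajectory, infield_outfield_volumes
from .geometry import (
    CylinderSpec,
    EmitterArray,
    ROILabelMap,
    VoxelGrid,
    axial_distance_map,
    build_emitter_array,
    rasterize_cylinder_rois,
    _axial_radial_coords,
)
from .kinetics import ClosureObservation
from .scoring import GRAY, SUBARACHNOID, TissueSegmentation, WHITE

__all__ = [
    "PhantomSpec",
    "SessionPlan",
    "CohortSpec",
    "make_head_phantom",
    "inject_session",
    "simulate_closure_observations",
    "simulate_growth_cohorts",
]

#: per-emitter enhancement patterns and the tissue labels they reach
PLAN_PATTERNS: dict[str, tuple[int, ...]] = {
    "none": (),
    "subarachnoid": (SUBARACHNOID,),
    "gray": (SUBARACHNOID, GRAY),
    "gray_white": (SUBARACHNOID, GRAY, WHITE),
}

#: baseline T1w intensity per tissue label (arbitrary units)
TISSUE_INTENSITY = {0: 0.0, 1: 40.0, 2: 80.0, 3: 100.0, 4: 20.0, 5: 120.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of the layered head phantom.

    Tissue layers are stacked by depth below the plate plane (z = 0,
    brain toward +z): a cerebrospinal/subarachnoid rim, a gray-matter
    ribbon, then white matter down to ``brain_depth_mm``.  Layer
    thicknesses are deliberately generous so each 10-mm cylinder holds
    more than the minimum gradable volume of every tissue class.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 1.5
    standoff_mm: float = 2.0  # epidural gap between plate and brain surface
    subarachnoid_mm: float = 10.0
    gray_mm: float = 8.0
    brain_depth_mm: float = 110.0
    brain_radius_mm: float = 80.0
    cavity_radius_mm: float = 0.0
    cavity_center_mm: tuple[float, float, float] = (0.0, 0.0, 30.0)
    tumor_radius_mm: float = 0.0
    tumor_center_mm: tuple[float, float, float] = (20.0, 20.0, 40.0)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or self.voxel_mm <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    def grid(self) -> VoxelGrid:
        """Grid centered laterally on the plate, plate plane at z = 0.

        The first axial voxel center sits exactly on the plate plane so
        axial coordinates of voxel centers are integer multiples of the
        voxel size.
        """
        nx, ny, _ = self.shape
        origin = (
            -(nx - 1) / 2.0 * self.voxel_mm,
            -(ny - 1) / 2.0 * self.voxel_mm,
            0.0,
        )
        return VoxelGrid.isotropic(self.shape, self.voxel_mm, origin)


def make_head_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, TissueSegmentation, np.ndarray]:
    """Baseline T1w volume, tissue segmentation and brain mask.

    Deterministic given the spec's seed; raises if the requested brain
    depth does not fit the grid.
    """
    grid = spec.grid()
    if spec.standoff_mm + spec.brain_depth_mm > (spec.shape[2] - 1) * spec.voxel_mm:
        raise ValueError("brain depth exceeds the voxel grid")
    x = grid.voxel_centers()
    depth = x[:, 2] - spec.standoff_mm  # depth below the brain surface
    lateral = np.hypot(x[:, 0], x[:, 1])
    labels = np.zeros(grid.n_voxels, dtype=np.uint8)
    in_brain = (depth >= 0) & (depth <= spec.brain_depth_mm) & (
        lateral <= spec.brain_radius_mm
    )
    labels[in_brain & (depth < spec.subarachnoid_mm)] = SUBARACHNOID
    labels[in_brain & (depth >= spec.subarachnoid_mm) & (
        depth < spec.subarachnoid_mm + spec.gray_mm
    )] = GRAY
    labels[in_brain & (depth >= spec.subarachnoid_mm + spec.gray_mm)] = WHITE
    for radius, center, lab in (
        (spec.cavity_radius_mm, spec.cavity_center_mm, 4),
        (spec.tumor_radius_mm, spec.tumor_center_mm, 5),
    ):
        if radius > 0:
            d2 = ((x - np.asarray(center)) ** 2).sum(axis=1)
            labels[(d2 <= radius**2) & (labels > 0)] = lab
    labels = labels.reshape(grid.shape)
    rng = np.random.default_rng(spec.seed)
    base = np.vectorize(TISSUE_INTENSITY.get)(labels).astype(float)
    pre = base * (1.0 + spec.noise_sigma * rng.standard_normal(grid.shape))
    pre = np.maximum(pre, 0.0)
    seg = TissueSegmentation(grid=grid, labels=labels)
    return pre, seg, seg.brain_mask


@dataclass(frozen=True)
class SessionPlan:
    """Per-emitter opening plan for one synthetic sonication session.

    ``patterns`` holds nine entries among 'none', 'subarachnoid', 'gray'
    and 'gray_white' (the intended grades 0, 1, 2 and 3).  The injected
    amplitude is ``e0`` attenuated by the exponential closure factor for
    the session's sonication-to-contrast delay; ``depth_mm`` optionally
    truncates the enhancement along every cylinder axis.
    """

    patterns: tuple[str, ...] = ("gray_white",) * 9
    e0: float = 0.30
    delay_min: float = 0.0
    half_time_hours: float = 1.3
    noise_sigma: float = 0.01
    depth_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.patterns) != 9:
            raise ValueError("a session plan has exactly 9 per-emitter entries")
        for p in self.patterns:
            if p not in PLAN_PATTERNS:
                raise ValueError(f"unknown plan pattern {p!r}")
        if self.e0 < 0 or self.delay_min < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude, delay and noise must be non-negative")
        if self.half_time_hours <= 0:
            raise ValueError("half time must be positive")

    @property
    def effective_amplitude(self) -> float:
        """Amplitude after exponential closure over the delay."""
        return self.e0 * math.exp(
            -math.log(2) * (self.delay_min / 60.0) / self.half_time_hours
        )

    def planned_grade(self, emitter_id: int) -> int:
        return {"none": 0, "subarachnoid": 1, "gray": 2, "gray_white": 3}[
            self.patterns[emitter_id - 1]
        ]


def inject_session(
    pre: np.ndarray,
    seg: TissueSegmentation,
    array: EmitterArray,
    plan: SessionPlan,
    rois: ROILabelMap | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a post-sonication image from the baseline and a plan.

    Inside each planned emitter's native (10 x 75 mm) cylinder, voxels of
    the planned tissue classes are scaled by 1 + e_eff; multiplicative
    Gaussian noise then models acquisition variability.  Returns the
    (pre, post) pair on the phantom grid.
    """
    grid = seg.grid
    if pre.shape != grid.shape:
        raise ValueError("baseline volume must live on the segmentation grid")
    if rois is None:
        rois = rasterize_cylinder_rois(array, grid, CylinderSpec())
    if rois.grid.shape != grid.shape:
        raise ValueError("ROI map must live on the segmentation grid")
    e_eff = plan.effective_amplitude
    post = np.asarray(pre, dtype=float).copy()
    if plan.depth_mm is not None:
        s, _ = _axial_radial_coords(array, grid)
    for k in range(1, 10):
        targets = PLAN_PATTERNS[plan.patterns[k - 1]]
        if not targets:
            continue
        mask = rois.mask(k) & np.isin(seg.labels, targets)
        if plan.depth_mm is not None:
            mask &= (s[k - 1] <= plan.depth_mm).reshape(grid.shape)
        post[mask] *= 1.0 + e_eff
    if plan.noise_sigma > 0:
        rng = np.random.default_rng(plan.seed)
        post *= 1.0 + plan.noise_sigma * rng.standard_normal(grid.shape)
        post = np.maximum(post, 0.0)
    return np.asarray(pre, dtype=float), post


def simulate_closure_observations(
    n: int = 31,
    delay_range_min: tuple[float, float] = (10.0, 77.0),
    half_time_hours: float = 1.3,
    e0: float = 1.0,
    sigma: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> list[ClosureObservation]:
    """Synthetic (delay, intensity) pairs from the exponential closure model.

    Delays are uniform on the scheduling window (default 10-77 min);
    intensities follow E0*exp(-ln2 * t / t_half) plus Gaussian noise of
    ``sigma`` x E0.  Defaults reproduce the observed closure conditions:
    31 sessions, 1.3 h half-time, 15% noise.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    lo, hi = delay_range_min
    if not 0 <= lo < hi:
        raise ValueError("invalid delay range")
    rng = np.random.default_rng(seed)
    delays = rng.uniform(lo, hi, size=n)
    clean = e0 * np.exp(-math.log(2) * (delays / 60.0) / half_time_hours)
    intensities = clean + sigma * e0 * rng.standard_normal(n)
    return [
        ClosureObservation(delay_min=float(t), intensity=float(e))
        for t, e in zip(delays, intensities)
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of one growth cohort.

    Patient slopes are drawn from a normal distribution (symmetric, so
    its median equals ``median_slope``); monthly in-field volumes follow
    baseline + slope x t with additive measurement noise, floored at
    zero.  ``near_axis_control_radius_mm`` > 0 suppresses voxel-mask
    growth within that distance of the emitter axes, emulating local
    tumor control in the sonicated columns.
    """

    cohort: str = "C"
    n_patients: int = 14
    median_slope: float = 2.31  # mL/month
    slope_sd: float = 1.0
    n_cycles_range: tuple[int, int] = (4, 6)
    baseline_mL: float = 2.0
    outfield_baseline_mL: float = 1.0
    noise_mL: float = 0.2
    near_axis_control_radius_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        if self.slope_sd < 0 or self.noise_mL < 0:
            raise ValueError("dispersions must be non-negative")
        lo, hi = self.n_cycles_range
        if not 2 <= lo <= hi:
            raise ValueError("need at least 2 cycles per patient")


def _sphere_radius_mm(volume_mL: float) -> float:
    return (3.0 * max(volume_mL, 1e-6) * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def _tabular_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[TumorTrajectory]:
    out = []
    for i in range(spec.n_patients):
        slope = rng.normal(spec.median_slope, spec.slope_sd)
        n_cycles = int(rng.integers(spec.n_cycles_range[0], spec.n_cycles_range[1] + 1))
        t = np.arange(n_cycles, dtype=float)
        infield = np.maximum(
            spec.baseline_mL + slope * t + spec.noise_mL * rng.standard_normal(n_cycles),
            0.0,
        )
        outfield = np.maximum(
            spec.outfield_baseline_mL + spec.noise_mL * rng.standard_normal(n_cycles),
            0.0,
        )
        out.append(
            TumorTrajectory(
                patient_id=f"{spec.cohort}{i + 1:02d}",
                cohort=spec.cohort,
                times_months=t,
                infield_mL=infield,
                outfield_mL=outfield,
            )
        )
    return out


def _mask_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    array: EmitterArray,
    grid: VoxelGrid,
    margin_rois: ROILabelMap,
    brain_mask: np.ndarray,
) -> tuple[list[TumorTrajectory], dict[str, list[np.ndarray]]]:
    """Cohort with voxel tumor masks grown as spheres off an inter-emitter
    seed point; trajectory volumes are tabulated from the masks so the two
    representations stay consistent."""
    dmap = axial_distance_map(array, grid, max_length_mm=80.0)
    suppress = (
        dmap.radial_mm < spec.near_axis_control_radius_mm
        if spec.near_axis_control_radius_mm > 0
        else np.zeros(grid.shape, dtype=bool)
    )
    x = grid.voxel_centers()
    trajectories: list[TumorTrajectory] = []
    masks: dict[str, list[np.ndarray]] = {}
    pitch = float(np.linalg.norm(array.centers[1] - array.centers[0]))
    center = array.centers[4] + array.axes[4] * 40.0 + np.array([pitch / 2, 0.0, 0.0])
    for i in range(spec.n_patients):
        slope = rng.normal(spec.median_slope, spec.slope_sd)
        n_cycles = int(rng.integers(spec.n_cycles_range[0], spec.n_cycles_range[1] + 1))
        t = np.arange(n_cycles, dtype=float)
        target = np.maximum(spec.baseline_mL + slope * t, 0.05)
        pid = f"{spec.cohort}{i + 1:02d}"
        patient_masks = []
        infield = np.empty(n_cycles)
        outfield = np.empty(n_cycles)
        for c in range(n_cycles):
            r = _sphere_radius_mm(float(target[c]))
            d2 = ((x - center) ** 2).sum(axis=1).reshape(grid.shape)
            mask = (d2 <= r * r) & brain_mask & ~suppress
            patient_masks.append(mask)
            vin, vout = infield_outfield_volumes(mask, margin_rois, brain_mask)
            infield[c] = vin
            outfield[c] = vout
        noise = spec.noise_mL * rng.standard_normal(n_cycles)
        trajectories.append(
            TumorTrajectory(
                patient_id=pid,
                cohort=spec.cohort,
                times_months=t,
                infield_mL=np.maximum(infield + noise, 0.0),
                outfield_mL=outfield,
            )
        )
        masks[pid] = patient_masks
    return trajectories, masks


def simulate_growth_cohorts(
    spec_c: CohortSpec,
    spec_d: CohortSpec,
    array: EmitterArray | None = None,
    grid: VoxelGrid | None = None,
    brain_mask: np.ndarray | None = None,
    make_masks: bool = False,
) -> dict[str, object]:
    """Two growth cohorts, tabular by default, with voxel masks on demand.

    Returns a dict with 'trajectories' ({cohort: [TumorTrajectory]}) and,
    when ``make_masks`` is set, 'masks' ({patient_id: [mask per cycle]})
    rasterized on ``grid`` (brain-restricted when ``brain_mask`` given).
    """
    out: dict[str, object] = {"trajectories": {}}
    if not make_masks:
        for spec in (spec_c, spec_d):
            rng = np.random.default_rng(spec.seed)
            out["trajectories"][spec.cohort] = _tabular_cohort(spec, rng)
        return out
    if array is None:
        array = build_emitter_array()
    if grid is None:
        grid = PhantomSpec().grid()
    if brain_mask is None:
        brain_mask = np.ones(grid.shape, dtype=bool)
    margin_rois = rasterize_cylinder_rois(
        array, grid, CylinderSpec(margin_mm=5.0)
    )
    out["masks"] = {}
    for spec in (spec_c, spec_d):
        rng = np.random.default_rng(spec.seed)
        trajs, masks = _mask_cohort(spec, rng, array, grid, margin_rois, brain_mask)
        out["trajectories"][spec.cohort] = trajs
        out["masks"].update(masks)
    return out
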