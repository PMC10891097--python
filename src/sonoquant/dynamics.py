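"""Tumor-control dynamics: growth slopes and radial coverage profiles.

Monthly pre-sonication T1w images give a per-patient time series of
contrast-enhancing tumor volume, split into the in-field part (inside the
margin-dilated emitter cylinders) and the out-field remainder.  Tumor
control is summarized two ways:

* a per-patient ordinary-least-squares growth slope (mL/month) of
  enhancing volume versus time, compared between treatment-sequence
  cohorts with a two-sided Wilcoxon-Mann-Whitney test, and
* a radial coverage profile: the end-of-study progression mask (voxels
  enhancing at the last visit but not at cycle 1) intersected with
  tube-shaped shells at increasing distance from the emitter axes, tested
  per shell between cohorts.

Cohort labels follow the trial: C = chemotherapy after sonication,
D = chemotherapy immediately before sonication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import DistanceMap, ROILabelMap

__all__ = [
    "TumorTrajectory",
    "GrowthRate",
    "ProgressionProfile",
    "infield_outfield_volumes",
    "growth_slope",
    "cohort_slope_comparison",
    "progression_mask",
    "radial_coverage_profile",
    "per_bin_cohort_test",
]

#: days per month used to convert calendar time to slope units
DAYS_PER_MONTH = 30.44

#: combined sample size up to which rank tests use exact enumeration
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class TumorTrajectory:
    """Per-patient enhancing-tumor volume time series (mL vs months)."""

    patient_id: str
    cohort: str
    times_months: np.ndarray
    infield_mL: np.ndarray
    outfield_mL: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_months, dtype=float)
        vin = np.asarray(self.infield_mL, dtype=float)
        vout = np.asarray(self.outfield_mL, dtype=float)
        if not (t.shape == vin.shape == vout.shape) or t.ndim != 1:
            raise ValueError("times and volumes must be equal-length 1-D arrays")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(vin < 0) or np.any(vout < 0):
            raise ValueError("volumes must be non-negative")
        object.__setattr__(self, "times_months", t)
        object.__setattr__(self, "infield_mL", vin)
        object.__setattr__(self, "outfield_mL", vout)

    @property
    def total_mL(self) -> np.ndarray:
        return self.infield_mL + self.outfield_mL

    @property
    def n_points(self) -> int:
        return int(self.times_months.size)


@dataclass(frozen=True)
class GrowthRate:
    patient_id: str
    slope_mL_per_month: float
    intercept_mL: float
    n_points: int


@dataclass(frozen=True)
class ProgressionProfile:
    """Fraction of each distance-to-axis shell covered by progression."""

    patient_id: str
    cohort: str
    bin_edges_mm: np.ndarray
    coverage: np.ndarray  # NaN where the shell is empty on the grid

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_mm, dtype=float)
        cov = np.asarray(self.coverage, dtype=float)
        if cov.size != edges.size - 1:
            raise ValueError("coverage must have one value per bin")
        finite = cov[np.isfinite(cov)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("coverage fractions must lie in [0, 1]")
        object.__setattr__(self, "bin_edges_mm", edges)
        object.__setattr__(self, "coverage", cov)


def infield_outfield_volumes(
    tumor_mask: np.ndarray,
    margin_rois: ROILabelMap,
    brain_mask: np.ndarray,
) -> tuple[float, float]:
    """Split an enhancing-tumor mask into in-field and out-field volume (mL).

    In-field is the intersection with the union of the margin-dilated
    emitter cylinders; out-field is the rest of the tumor within the
    brain.  The two parts always sum to the total tumor-in-brain volume.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if tumor_mask.shape != margin_rois.grid.shape or brain_mask.shape != tumor_mask.shape:
        raise ValueError("tumor, brain and ROI grids must match")
    vox_mL = margin_rois.grid.voxel_volume_mm3 / 1000.0
    tumor_in_brain = tumor_mask & brain_mask
    infield = tumor_in_brain & margin_rois.any_mask
    outfield = tumor_in_brain & ~margin_rois.any_mask
    return float(infield.sum()) * vox_mL, float(outfield.sum()) * vox_mL


def growth_slope(traj: TumorTrajectory, field: str = "infield") -> GrowthRate:
    """OLS slope of enhancing volume versus time for one patient.

    ``field`` selects the in-field, out-field or total volume series.
    Patients with fewer than two time points cannot contribute a slope
    and raise; callers exclude them from cohort summaries.
    """
    if field not in ("infield", "outfield", "total"):
        raise ValueError("field must be 'infield', 'outfield' or 'total'")
    if traj.n_points < 2:
        raise ValueError(
            f"patient {traj.patient_id}: need >= 2 time points for a slope"
        )
    v = {
        "infield": traj.infield_mL,
        "outfield": traj.outfield_mL,
        "total": traj.total_mL,
    }[field]
    slope, intercept = np.polyfit(traj.times_months, v, 1)
    return GrowthRate(
        patient_id=traj.patient_id,
        slope_mL_per_month=float(slope),
        intercept_mL=float(intercept),
        n_points=traj.n_points,
    )


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact for small samples, otherwise normal
    approximation with tie and continuity correction."""
    method = "exact" if (len(x) + len(y) <= EXACT_RANKSUM_MAX_N) else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([x, y])).size < len(x) + len(y)):
        method = "asymptotic"  # scipy's exact null does not handle ties
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def cohort_slope_comparison(
    slopes_c: np.ndarray, slopes_d: np.ndarray
) -> dict[str, float]:
    """Median growth slope per cohort and the rank-sum p comparing them."""
    x = np.asarray(slopes_c, dtype=float)
    y = np.asarray(slopes_d, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both cohorts must be nonempty")
    return {
        "median_C": float(np.median(x)),
        "median_D": float(np.median(y)),
        "p_value": _ranksum_p(x, y),
        "n_C": int(x.size),
        "n_D": int(y.size),
    }


def progression_mask(first_mask: np.ndarray, last_mask: np.ndarray) -> np.ndarray:
    """Voxels enhancing on the last MRI but not at the first cycle."""
    first_mask = np.asarray(first_mask, dtype=bool)
    last_mask = np.asarray(last_mask, dtype=bool)
    if first_mask.shape != last_mask.shape:
        raise ValueError("first and last masks must share a grid")
    return last_mask & ~first_mask


def radial_coverage_profile(
    prog_mask: np.ndarray,
    shells: list[np.ndarray],
    bin_edges_mm: np.ndarray,
    patient_id: str = "",
    cohort: str = "",
) -> ProgressionProfile:
    """Fraction of each tube shell covered by the progression mask.

    Empty shells (no voxels on this grid) yield NaN coverage and are
    flagged by the NaN rather than an error so profiles with partially
    off-grid shells remain usable.
    """
    prog_mask = np.asarray(prog_mask, dtype=bool)
    coverage = np.empty(len(shells), dtype=float)
    for i, shell in enumerate(shells):
        if prog_mask.shape != shell.shape:
            raise ValueError("progression mask and shells must share a grid")
        n = int(shell.sum())
        coverage[i] = (prog_mask & shell).sum() / n if n else np.nan
    return ProgressionProfile(
        patient_id=patient_id,
        cohort=cohort,
        bin_edges_mm=np.asarray(bin_edges_mm, dtype=float),
        coverage=coverage,
    )


def default_bin_edges(max_mm: float = 20.0, width_mm: float = 2.5) -> np.ndarray:
    """Radial bin edges 0..max in fixed-width steps (default 2.5 mm)."""
    return np.arange(0.0, max_mm + width_mm / 2, width_mm)


def per_bin_cohort_test(
    profiles_c: list[ProgressionProfile],
    profiles_d: list[ProgressionProfile],
    holm: bool = False,
) -> dict[str, np.ndarray]:
    """Per-shell two-sided Mann-Whitney test of coverage between cohorts.

    Raw p-values are reported by default; Holm step-down adjustment is
    available behind the flag.  Bins where either cohort has no finite
    coverage values yield NaN.
    """
    if not profiles_c or not profiles_d:
        raise ValueError("both cohorts must be nonempty")
    edges = profiles_c[0].bin_edges_mm
    for p in profiles_c + profiles_d:
        if not np.array_equal(p.bin_edges_mm, edges):
            raise ValueError("all profiles must share the same bin edges")
    n_bins = edges.size - 1
    pvals = np.full(n_bins, np.nan)
    for i in range(n_bins):
        x = np.array([p.coverage[i] for p in profiles_c])
        y = np.array([p.coverage[i] for p in profiles_d])
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if x.size == 0 or y.size == 0:
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            pvals[i] = 1.0
            continue
        pvals[i] = _ranksum_p(x, y)
    out = {"bin_edges_mm": edges, "p_raw": pvals}
    if holm:
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="holm")[1]
        out["p_holm"] = adj
    return out
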