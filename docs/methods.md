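# Methods

This note documents the models behind each `sonoquant` module, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Geometry and rasterization

All coordinates are world millimetres (RAS+, NIfTI convention); voxel
indices are 0-based, and a voxel belongs to a region iff its center
does. Volumes are voxel counts times |det| of the affine's 3×3 block.

The implant is modeled as a flat 3 × 3 grid of 10-mm circular emitters.
The center-to-center pitch is not a published device parameter; the
default of 19.3 mm is chosen so the array footprint (2·pitch + 10 mm =
48.6 mm) fits the 58-mm plate the implant replaces, and it is
configurable (`build_emitter_array(pitch_mm=...)`). The flexible
implant's conformation to skull curvature is deliberately not modeled:
no bending parameters are available, and a flat plate with parallel
axes is the reproducible reference configuration. Consequences of this
choice are noted under *Acoustics* below.

Each emitter's sonicated region of interest is a cylinder of 5 mm
radius and 75 mm length starting at the plate plane; tumor-field
analyses dilate it by a 5-mm margin (radially and at the distal end) to
10 mm × 80 mm. Where margin-dilated cylinders overlap, voxels are
assigned to the nearest axis (ties to the lowest emitter index) so the
per-emitter regions partition the labeled volume; the union is kept
separately for field-level analyses.

Rasterization accuracy: in generic position (axis not exactly parallel
to a grid axis, or axis offset not commensurate with the voxel size)
the voxel-center rule recovers the analytic cylinder volume to well
under 2% at 1-mm resolution and converges as the voxel size shrinks.
On a grid exactly aligned with the axis every axial slice shares one
lateral quantization pattern and boundary voxels (center exactly on the
radius) are all included, producing a systematic excess of a few
percent that does not average out along the cylinder. This is a
property of any center-in-region rasterizer; analyses that compare
volumes across emitters or sessions are unaffected because injection
and measurement share one grid.

The distance-to-axis map stores, per voxel, the minimum over emitters
of the perpendicular distance to the emitter axis, counting only
emitters whose axial coordinate for that voxel lies within the cylinder
length; `inf` marks voxels outside every axial range. Tube ("ring")
shells between radial bin edges are half-open intervals [r₁, r₂), so a
set of edges partitions the tube exactly. Default radial bins are
2.5-mm wide over 0–20 mm.

## Enhancement scoring

The relative enhancement map is (post′ − pre)/pre inside the brain
mask, where post′ is the post-contrast image rescaled so its median
over a non-sonicated reference region matches the pre image (removing
global intensity scaling between acquisitions), and the denominator is
floored at 1% of the pre image's brain median. Inputs are assumed
co-registered and bias-corrected; those preprocessing steps belong to
external registration tools, and the synthetic generator produces
co-registered volumes by construction.

The detection threshold τ is the value exceeded by 1% of control-tissue
enhancement values — the (1 − 0.01) linear-interpolation quantile,
floored at 0. A lower-tail reading of "1st centile" would threshold
near zero and mark essentially all control tissue enhanced, so the
upper tail is the only self-consistent interpretation; the tail
fraction is configurable. A constant control region (e.g. a noiseless
synthetic session) degenerates to τ = that constant with a warning.

Per-emitter grading operates on suprathreshold voxels inside the
emitter's cylinder, restricted to brain tissue that was not enhancing
before sonication (resection cavity and pre-enhancing tumor labels are
removed). With enhanced volume V:

- V ≤ 0.5 mL → grade 0;
- otherwise, if ≥ 90% of enhanced voxels are subarachnoid/CSF → grade 1;
- otherwise, if enhanced white-matter volume > 0.25 mL → grade 3;
- otherwise → grade 2.

The published scale lumps grades 0–1 (subarachnoid-only) and separates
gray (2) from gray-and-white (3) without stating the splits; the 0.5-mL
minimum is the published rule, while the 90% confinement fraction and
the 0.25-mL white-matter threshold are this package's defaults, exposed
in `ScoringConfig`. An emitter is non-evaluable when cavity plus tumor
occupy strictly more than 30% of its cylinder (fraction configurable;
the exclusion rule itself is published, the fraction is not).

Session metrics: success iff grade ≥ 2 on at least two-thirds of
evaluable emitters (boundary inclusive — 6/9 succeeds); I90 is the 90th
percentile of the enhancement map over the union of evaluable
cylinders; depth is the maximum axial coordinate (mm from the plate
plane) of any suprathreshold enhanced voxel. Depth is deliberately a
maximum, which makes it exact on constructed data but sensitive to
suprathreshold noise voxels on noisy data — by construction of τ, about
1% of in-cylinder noise voxels exceed it, so on noisy sessions the
depth metric saturates toward the cylinder length.

## Closure kinetics

The barrier reseals over hours; intensity I90 versus
sonication-to-contrast delay t is fitted with the two-parameter model
E(t) = E₀·e^(−λt) by nonlinear least squares (scipy `curve_fit`,
initialized from a log-linear regression on positive intensities).
There is no asymptotic offset term by default — observed closure is
complete — but the model form keeps λ free, and a best-fit λ ≤ 0 is
flagged as a non-closing fit with t½ = ∞ rather than an error. Delays
are recorded in minutes; t½ = ln 2/λ is reported in hours.

The confidence interval is a case-resampling percentile bootstrap
(default 1000 resamples, seeded); resamples that fail the fit
preconditions are dropped, with a warning when more than 20% fail. The
published interval's method is unstated; the bootstrap makes no
distributional assumption and its empirical coverage at the study's
noise level is ≥ 90% at nominal 95% (checked in the test suite). The
Spearman rank correlation between delay and intensity (exact
permutation p for n ≤ 9, asymptotic beyond) provides a
distribution-free check that intensity falls with delay.

## Tumor dynamics

In-field volume is the enhancing-tumor mask intersected with the union
of margin-dilated cylinders; out-field is the remainder within the
brain; the two sum to the total by construction. Per-patient growth is
the OLS slope of volume versus time in mL/month (months = 30.44 days
when converting calendar dates); patients with fewer than two time
points are excluded from cohort summaries. Cohorts are compared with a
two-sided Wilcoxon–Mann–Whitney test, exact for combined n ≤ 20 without
ties and normal-approximated with tie/continuity correction otherwise.

The progression mask is the voxelwise set difference last ∖ first (not
a signed volume difference), which requires co-registration; radial
coverage is the fraction of each distance-to-axis shell covered by the
progression mask, tested per shell between cohorts with raw p-values by
default (Holm step-down available behind a flag, via statsmodels).
Empty shells yield NaN coverage and are excluded from tests.

## Trial design

The phase-2 rule rejects the objective performance criterion p₀ = 0.30
when the exact Clopper–Pearson lower limit of the observed success
proportion exceeds it; at one-sided α = 2.5% this is equivalent to the
smallest k with P(X ≥ k | n, p₀) ≤ α, and the equivalence is asserted
in tests for all n ≤ 100. All tail probabilities are exact binomial
sums — no normal approximation. For n = 15, p₁ = 0.70 the critical
count is 9 and the exact power 86.89%; the protocol's stated 86% is
treated as a lower bound since its rounding is unknown. The Calvert
formula (dose = AUC·(GFR + 25) mg) is included with a warning outside
the protocol's AUC 4–6 range.

## Acoustics

Each emitter is a baffled circular piston radiating at 1 MHz into a
linear, lossy, homogeneous medium (defaults c = 1540 m/s, α = 0.5
dB/cm/MHz, ρ = 1040 kg/m³ — standard soft-tissue constants; the implant
sits epidurally where bone has been removed, so no skull layer is
modeled, and nonlinear propagation and microbubble dynamics are out of
scope). The steady-state pressure magnitude is the Rayleigh–Sommerfeld
integral over the piston surface, discretized with ≥ 10 elements per
wavelength and scaled so the plane-wave surface pressure equals the
calibrated 1.03 MPa; absorption enters as e^(−αR) per propagation path.
Pulsing enters only through the duty cycle (25 ms/2 s = 1.25%) in the
energy metric.

Because each piston's field is axisymmetric, the solver tabulates
|p|(ρ, z) once on a fine polar lattice (default 0.15 mm radially,
0.25 mm axially) and bilinearly interpolates onto each emitter's
voxels; interpolating the magnitude rather than the complex field
concentrates the (small) interpolation error at near-field nulls, far
from the 0.2-MPa contour that defines the opening region. The direct
summation path is validated against the closed-form on-axis solution
p/p₀ = 2|sin((π/λ)(√(z²+a²) − z))| to < 2% for z > 2a.

The emitters fire sequentially, so per-emitter fields are never summed
coherently; the simulated opening region is the union of per-emitter
volumes above 0.2 MPa. Overlap metrics report the fraction of that
union seen by ≥ 2 beams and the largest single-beam energy (p²·duty
cycle) inside the overlap relative to the field maximum, as a signed
percentage. With the flat parallel-axis array the beams barely converge
and the ≥ 2-beam overlap at 0.2 MPa is essentially zero — comfortably
below the ≤ 10% bound observed clinically. Reproducing the clinically
observed overlap magnitude (beams crossing ~5 cm deep) would require
the curved, patient-specific conformation that is explicitly not
modeled; the flat configuration bounds the overlap from below, and
at lower thresholds, where overlap exists, its energy deficit relative
to the field maximum is negative as expected.

## Synthetic data

The phantom is geometric, not anatomical: planar tissue layers under
the plate plane (2-mm epidural standoff, then a subarachnoid/CSF rim,
a gray-matter ribbon, and a white-matter core to 110 mm) with optional
spherical cavity and tumor, T1w baseline intensities per tissue, and
multiplicative Gaussian noise (Rician behavior is negligible at these
SNRs). Layer thicknesses (10 mm subarachnoid, 8 mm gray) are chosen so
each cylinder holds more than the 0.5-mL gradable minimum of every
tissue class — several times thicker than anatomy, because the grading
rules, not the anatomy, are under test. The default grid is 128³ at
1.5 mm with the first axial voxel plane exactly on the plate plane, so
axial coordinates are integer multiples of the voxel size (the depth
identity checks use a 1-mm variant for exact 64-mm truncation).

Sessions inject enhancement e_eff = e₀·e^(−ln2·t/t½) into the planned
tissue classes of each planned emitter's cylinder (defaults e₀ = 0.30,
t½ = 1.3 h), optionally truncated at a given axial depth, plus
multiplicative noise. Closure datasets draw delays uniformly on the
observed 10–77 min scheduling window with Gaussian noise of 15% of E₀
at n = 31 — the documented closure-analysis conditions. Growth cohorts
draw patient slopes from a normal (hence median-symmetric) distribution
around the cohort median (defaults: cohort C 14 patients, median 2.31
mL/month, sd 1.0; cohort D 12 patients, median 0.54 mL/month, sd 0.5),
with 4–6 monthly measurements, 2-mL baseline and 0.2-mL measurement
noise; voxel tumor masks, when requested, are spheres grown to match
the tabulated volumes, with cohort-D growth removed inside a
configurable near-axis control radius so radial profiles differ between
cohorts by construction. Every generator is a pure function of its spec
including the seed.

What passing tests therefore show — and do not show: the pipeline's
rules, estimators and numerics are correct on data satisfying its
assumptions (co-registration, known tissue labels, exponential decay,
linear growth). They say nothing about robustness to registration
error, bias fields, segmentation noise, contrast-agent differences or
pseudoprogression, none of which the generator emulates.

## Problem sizes and determinism

The acceptance script (`scripts/acceptance.py`) uses: exact enumeration
(n = 15) for design power; 200 replicates of 31 observations for
closure recovery; 300 replicates per cohort for slope recovery; a 1-mm,
81 × 81 × 80 grid to 80-mm depth for the acoustic overlap; ten 128³
1.5-mm sessions (90 emitters) for the grading worked example; and five
96³ 1-mm sessions for the depth identity. These sizes give stable
medians while keeping a full run to a few minutes on one core. All
randomness flows from the `--seed` argument through derived
sub-streams, so identical seeds reproduce identical JSON.

## Known limitations

- Flat-array acoustics bound, but do not reproduce, curved-implant beam
  overlap (see above).
- The depth metric's max-over-voxels definition is exact on constructed
  data but noise-saturating on real data; a robust quantile would trade
  the identity property for stability.
- Grade 0 vs 1 and grade 2 vs 3 splits use package defaults where the
  published scale is ambiguous; both are configurable.
- The exact Mann–Whitney null is unavailable under ties; tied samples
  fall back to the corrected normal approximation at any n.
- Within-patient clustering of sessions is ignored by the binomial
  machinery, which treats successes as independent.
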