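# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of the package.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Diffusion model and index maps

The single-tensor, single-shell model S = S₀·exp(−b·gᵀDg) is fit per voxel
by **log-linear least squares** (ln S regressed on the six unique tensor
components plus ln S₀).  Weighted or fully nonlinear fits improve noise
behaviour slightly but add iteration-dependent nondeterminism; the
log-linear solution is exact on clean data (round-trip error ~1e-15,
asserted at 1e-8) and fully reproducible.  Non-positive signals are floored
at 1e-8 of the volume maximum before the log and counted in the QC report.
Negative eigenvalues after the fit are **clamped to zero** and counted;
clamping keeps FA in [0, 1] and AD ≥ ADC ≥ RD algebraically forced.  Noisy
isotropic background voxels routinely clamp (λ₃ slightly negative); a large
clamp count in structured tissue is a QC signal.

ADC and MD are treated as synonyms.  FA := 0 where Σλᵢ² = 0.

### Motion screening

Sporadic motion ruins individual slice/direction images in segmented EPI.
Each (slice, frame) image's mean in-mask signal is normalized by that
frame's across-slice median (robust to the corrupted slice itself), the
per-slice across-frame median is subtracted within each shell (b0 and
diffusion frames screened separately), and deviations beyond k = 4 pooled
scaled MADs are excluded from the fit.  Deviations below 10 % of the slice
level are never flagged: anatomy-by-direction interaction reaches a few
percent, whereas motion artifacts are order-of-signal dropouts.  If
screening leaves a slice with fewer than 6 usable directions or no b0, the
pipeline stops with an error naming the affected voxel count.

### Smoothing

"0.3 mm Gaussian kernel" is interpreted as **FWHM** (σ = FWHM/2.3548), the
SPM convention; smoothing is mask-renormalized so edge voxels are not
diluted by background, and FWHM = 0 is the identity.

## T2 relaxometry and lesion volumetry

y(t) = A + C·e^(−t/T2) is fit per voxel by bounded nonlinear least squares
(A free, C ≥ 0, T2 > 0), initialized from a log-linear fit of y − min y.
Optional inverse-variance weighting accepts per-echo SDs.  Non-converged
and all-zero voxels are flagged, never silently filled.  On clean 16-echo
data the fit is exact to 1e-6; at 1 % amplitude noise the median |ΔT2| is
below 2 ms (both asserted).

The lesion is segmented on the **T2-weighted intensity image** (first
echo), not the fitted T2 map, matching absolute-intensity thresholding
practice; a configuration switch allows segmenting the T2 map instead.
Region growth is a deterministic breadth-first flood fill over 26-connected
neighbours (6-connectivity selectable) bounded by the [lo, hi] window —
equivalently, the connected component of the thresholded image containing
the seed, so the result is invariant to seed choice within the component.
The 6300–9000 default window is scanner- and gain-specific and is a
configuration value, not a constant.  Masks touching the volume boundary
are flagged in the QC report.

## Rigid registration

Subjects are aligned b0-to-template with a 6-parameter rigid transform
(angles about x, y, z applied in that order around the fixed-image centre,
then translation; world coordinates RAS, millimetres, transforms act in
world space).  The cost is negative normalized cross-correlation, minimized
by Nelder–Mead over a 2-level coarse-to-fine pyramid — deterministic given
the initial guess.  Two numerical details matter for sub-voxel accuracy and
were chosen after measuring the cost optimum directly:

- NCC is evaluated with **cubic-spline interpolation**; trilinear kinks
  displace the optimum by up to ~1° on desk-scale grids.
- NCC is restricted to the **eroded support of the fixed image**; edge
  voxels entering and leaving the overlap otherwise bias the optimum.

With these choices known displacements of ≤5° / ≤2 voxels are recovered
within 0.25° and 0.1 voxel on the small phantom (asserted).  The public
`resample` keeps the contract users rely on: trilinear for intensity maps,
nearest neighbour (value-set preserving) for labels, and an error if
trilinear is requested for an integer volume.  Affine (12-parameter)
registration and mutual information are out of scope of the default path.
Hemisphere identity always comes from the atlas region table, never from a
voxel-coordinate sign, so flipped acquisitions cannot silently swap sides.

## Bilateral region statistics

The in-pipeline test is a **two-tailed paired t-test across animals** on
ipsilateral − contralateral region means — the design treats the
non-concussed hemisphere as a within-animal control.  Printed summary
tables (mean, SD per side) cannot encode pairing, so `t_from_summary`
provides the pooled (df = n₁+n₂−2) and Welch variants for worked-example
reproduction; both variants are exposed because the provenance of published
table p-values (paired vs unpaired) is ambiguous, and summary-statistic
recomputation reproduces some printed significance levels but not all.
Rows are sorted by ascending p with ties broken by |t| descending then
region name, so output order is deterministic.  Arrows: ↑ iff ipsilateral
mean exceeds contralateral; suppressed when means are exactly equal.
Zero within-pair variance (legal on noiseless phantoms) yields a
machine-floor p with a warning rather than a crash or a silent NaN.

No multiplicity correction is applied by default, matching the reporting
style the pipeline reproduces; Benjamini–Hochberg q-values (via
`scipy.stats.false_discovery_control`) can be appended and never overwrite
raw p-values.

## Histology optical density

Staining is quantified as the count of pixels strictly above a threshold of
exactly 2.0× the background median inside standardized ROI boxes (all ROIs
in one comparison must share dimensions, enforced).  The background comes
from a user-designated background ROI via the median, which resists stain
speckle.  Whether darker means more stain is acquisition-dependent;
`invert_image` flips polarity when needed.  Hemispheres are compared by
two-tailed paired t-tests with animal as the experimental unit.

## Synthetic study conditions

The generator emulates the acquisition the pipeline was designed around:
10-direction b = 1000 s/mm² single-shell DWI plus one b0 on a 96×96×60 grid
of 0.313 mm isotropic voxels; 16 echoes at 11 ms spacing; a bilateral atlas
of 150 mirror-symmetric region pairs totalling ~20,000 labeled voxels with
a designated 46-voxel central-amygdala pair; a spherical edema of radius
1.4 mm (≈11.9 mm³, inside the 9–14 mm³ mild-to-moderate range); and
hemisphere-specific FA/RD/AD shifts in named regions.  A 24³ "small" preset
with 3 region pairs scales everything down so a complete run takes seconds;
the statistical simulations in the tests and the acceptance script use this
preset, with cohort sizes n = 5 (100 repetitions for power, 200 for the
null) — sizes chosen so the studies complete in about a minute while the
binomial error on the estimated rates stays a small fraction of the margins
being asserted.

Key fixed choices:

- **Noise**: Rician magnitude noise for DWI (σ = 2 % of S₀, i.e. SNR 50,
  typical of high-field rodent EPI; the channel SD is a free config since
  real scanner noise varies); plain Gaussian for multi-echo T2, where the
  model's bias term A absorbs the magnitude floor.
- **Injury effects act on eigenvalues**, so all indices move
  self-consistently: an "fa" effect re-shapes (λ₁ up, λ₂ = λ₃ down) at
  constant trace; "rd"/"ad" shift λ₂,λ₃ / λ₁ additively.  Effect sizes in
  the simulations are taken from published contralateral/ipsilateral means
  (e.g. central amygdala FA 0.414 → 0.582).
- **Inter-subject variability** is a bilateral per-region eigenvalue scale
  ~ N(1, 0.05), which keeps the across-animal SD of region means under
  10 % of the mean and cancels in the within-animal pairing, as in inbred
  cohorts of age-matched animals.
- **Subject displacement** is a recorded rigid transform within ±2 voxels
  and ±5°, enough to exercise registration without leaving its capture
  range.
- The phantom b0 carries a smooth band-limited proton-density texture and
  deliberately different left/right region contrast: a uniform ellipsoid
  gives the rotation cost no curvature.  Because that left/right SNR
  asymmetry also produces differential Rician index bias — a real
  systematic, large enough to inflate a paired test whose within-pair SD is
  tiny — the statistical calibration studies set `mirror_s0=True`, which
  mirrors the b0 so hemispheres are exchangeable (the exact null).
  Registration studies keep the asymmetric default.  Power and null cohorts
  run with displacement disabled so the detection loop isolates the
  statistics; registration accuracy is validated separately.

What the phantoms do **not** emulate: eddy currents, susceptibility
distortion, partial-volume mixing, anatomically realistic region shapes,
spatially correlated physiological noise, or atrophy/deformation at the
contusion site.  Passing tests therefore demonstrate the correctness and
calibration of the estimators and bookkeeping on data obeying the stated
models — not robustness to every artifact of real acquisitions.

## Degenerate inputs and tie-breaks

- Flood fill with a uniform in-range image returns the whole volume (and
  flags the boundary touch).
- An empty lesion mask reports volume 0 with a warning.
- Region blobs are placed on a lattice ordered by distance from the
  hemisphere centre; construction fails loudly if the requested pairs
  cannot be placed without overlap.
- Identical left/right data give t = 0, p = 1, arrow suppressed.
- `RunConfig` rejects unknown keys; every output directory carries a
  provenance JSON (package version, config hash), and rerunning an
  unchanged config reproduces byte-identical tables (the written
  region-means TSV is the single source of truth for the stats stage).

## Known limitations

- The published tables are reproduced from summary statistics only; without
  the underlying per-animal data, paired-test p-values for those rows are
  not recomputable, and the acceptance checks are restricted to rows whose
  printed significance the unpaired pooled test attains.
- The distinction between the original workflow's "normalization" step and
  its co-registration is not parameterized here; a single subject→atlas
  rigid transform stands for both.
- Two-repetition signal averaging is applied in signal space before the
  fit when duplicate acquisitions are supplied; map-space averaging is a
  config switch, and which the original toolchain used is unknown.
- The T2 fit loops over voxels in Python; it is intended for lesion-scale
  masks, not whole-brain relaxometry at full resolution.
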