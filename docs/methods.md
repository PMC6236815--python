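# Methods

`artqa` evaluates a simple adaptive-radiotherapy (ART) replan flag — "change
in external body contour exceeding 1.5 cm" — against ground-truth
dose-violation criteria, using per-fraction truth tables. This note records
the models, conventions and design choices behind each stage, and what the
synthetic cohort does and does not establish.

## The flag metric

For each assessed fraction the external body contour is compared with the
planning contour slice by slice. On every axial slice where both contours are
non-empty we compute the symmetric Hausdorff distance between boundary point
sets, and the flag value is the maximum over slices. The fraction is flagged
when this value *strictly* exceeds the threshold (default 1.5 cm, matching
the "exceeding" wording of the clinical protocol; a value of exactly 1.5 cm
does not flag).

Choices worth stating:

* **Symmetric vs directed.** "Largest pointwise distance between" the two
  contours reads as symmetric, and the symmetric form is the Hausdorff
  distance proper; a directed variant is available (`directed=True`) but
  carries no default claim about clinical practice.
* **Boundary sampling.** Boundary point sets are the centers of mask voxels
  with a non-mask in-slice 4-neighbor. This bounds the sampling error of any
  Hausdorff value by one in-plane voxel diagonal (0.28 cm at the default
  0.2 cm spacing), which is the tolerance used throughout the tests.
* **Slice policy.** Only slices where both externals are non-empty
  contribute, emulating the limited field of view of on-unit CBCT; a z-range
  crop is available.
* **Measurement noise.** Clinical contour-change values are manual therapist
  measurements; the simulator (not the flag itself) can add zero-mean
  Gaussian noise, default sigma 0.1 cm.

## Dose parameters and accumulation

DVH statistics use deliberately simple, oracle-testable conventions: Dmax is
the single hottest voxel (no small-volume smoothing); Dx% is the k-th highest
voxel dose with `k = ceil(x/100 * N)` and no fractional interpolation; VxGy
counts voxels with dose `>= x` (inclusive, the cumulative-DVH convention) as
a percent of the structure. The low-dose PTV is evaluated with the high-dose
PTV volume subtracted (`exclude: ptv_high` in the criteria file).

Course-level accumulation linearly interpolates each parameter between
assessed fractions, holds the nearest assessed value before the first and
after the last CBCT (inventing no pre-imaging trend), and averages the
33-fraction series. This is the conservative scalar-parameter estimate used
when voxel-wise dose warping is unavailable; it implicitly assumes, e.g.,
that Dmax stays in one spatial location. Accumulated estimates are graded
against the same criteria as single fractions (configurable).

## Violation criteria

Each criterion grades one parameter against `reference * (1 ± v/100)` — plus
for dose limits, minus for coverage — with strict comparisons, mirroring the
flag's comparator. `v` margins come from physician surveys: the per-parameter
median of the percentage violations respondents consider replan-warranting
(`aggregate_survey`), with the even-count median taken as the mean of the two
middle values. Severity (major vs minor) is a property of the criterion —
target coverage and brainstem/cord sparing are major; target hot spot and
parotid sparing are minor — not of the breach magnitude.

The packaged default criteria file is a reconstruction and says so in its
comments. The only absolute anchor recoverable from text is the spinal-cord
Dmax objective of 48 Gy with a 3% major margin (threshold 49.44 Gy, reported
as 49.4): note 0.70 × 70 Gy = 49 Gy approximately corresponds to this dose,
which is consistent with a 48 Gy objective but the objective itself is
inferred. Target-coverage criteria are referenced to planned values with a 5%
major margin; GTV/CTV criteria are copies of the PTV criteria (no formal
constraints exist for them); brainstem 54 Gy is an institutional-typical
objective. Users should replace the file with their own survey medians.

Truth-table categories are derived from structure names: *all major
violations*; *all major excluding PTV*; *organs at risk* (brainstem, cord,
optics); *target coverage with PTV* (GTV, CTV, PTV); *target coverage
without PTV* (GTV, CTV). The with/without-PTV split exists because CTV→PTV
margins make modest PTV-coverage loss expected under setup error, while
severe loss signals dose spilling into healthy tissue.

## Truth tables and the random-flag baseline

Each assessed fraction is an independent data point; TP/FN/FP/TN cross-
tabulate flag state against category violation, and the five metrics are
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), accuracy (TP+TN)/total. Ratios with zero denominators are
reported absent, not zero. An optional per-fraction weight vector (default
uniform) lets a center emphasise early-course accuracy.

The random-flag baseline models a cohort assembled the way flagged-patient
studies are: per fraction, flags (probability `p_flag` = 0.20) and
clinically significant deviations (`p_viol` = 0.15) are independent; each
patient contributes `k` assessed fractions; only patients with at least one
flag enter the cohort. Conditioning on inclusion raises the expected share
of flagged fractions per retained patient to

    p_flag / (1 - (1 - p_flag)^k),

and because violations are independent of flags, the pooled sensitivity
equals that share — independent of `p_viol` (verified by Monte Carlo across
a `p_viol` grid). At the defaults with `k = 6` the closed form is 0.271,
i.e. 27%. This inclusion-bias model is this package's reconstruction of the
baseline argument; `k` is exposed as a parameter (25–30% over `k` in [5, 7]),
and the Monte Carlo (1e5 patients) agrees with the closed form to within
3 standard errors. The uninformative-flag sensitivity is the benchmark any
meaningful flag must beat; a flag whose sensitivity is comparable to it
carries no information about who needs a replan.

## The synthetic phantom cohort

The phantom is an elliptic-cylinder neck (semi-axes 7.5 × 6.5 cm) over a
wide shoulder block, with a 1.5 cm-radius spherical GTV anterolateral to a
posterior spinal-cord cylinder (0.5 cm radius), lateral parotids, and a
superior brainstem stub. Planning structures follow the standard margins:
CTV = GTV + 0.75 cm (midpoint of the conventional 0.5–1.0 cm range),
PTV = CTV + 0.3 cm, PRV margins 0.3 cm (brainstem) and 0.5 cm (cord); CTV
expansion is cropped to the body surface (configurable — whether clinical
practice crops is not specified). Default grid: 0.2 cm isotropic voxels.

The dose engine is intentionally minimal: planned dose is the voxel-wise
maximum over prescription levels (70 / 59.4 Gy in 33 fractions) of the
level's PTV dilated by a 1 cm flash margin and convolved with a 0.5 cm
Gaussian penumbra. Per fraction, the planned dose stays fixed in the bony
frame (emulating image-guided bony alignment) and each voxel is rescaled by
`exp(mu * d)`, where `d` is the reduction in tissue path from the surface
averaged over the two lateral beam directions and `mu = 0.035`/cm is chosen
so that a 1.5 cm depth reduction yields the ~5% central-axis increase
characteristic of 6 MV. This engine is not a planning-system surrogate; it
exists to reproduce directions, not magnitudes: hot spots rise under tissue
loss, and coverage falls when targets shift relative to the fixed dose
field (the latter dominating, as the per-fraction D95 tests assert).

Scenarios:

* **weight_loss** — uniform in-plane erosion at `shrink_rate` (default
  0.06 cm/fraction, chosen once so the 1.5 cm flag trips in the final third
  of the course; no quantitative clinical trajectory is available to anchor
  it). Soft-tissue structures are advected bodily toward the axis by the
  in-plane area-contraction factor at the tumor slice; bony-frame structures
  (cord, brainstem, PRVs) stay fixed. With advection disabled the scenario
  is a pure shrink, under which Dmax-type parameters rise monotonically.
* **localized_edema** — the high-dose GTV/CTV/PTV scale isotropically along
  a piecewise-linear volume trajectory: ratio 1 → 1.256 at the changepoint
  (fraction 8) → 0.598 at fraction 33; masks are resampled with linear
  interpolation and a 0.5 threshold, which tracks the analytic ratios to
  well within 2%. A matching localized external bulge, displacement
  `bulge_gain` × the tumor-radius change through a 2.5 cm Gaussian weight
  anchored at the surface point nearest the tumor, makes the contour metric
  respond; its |displacement| has its growth-phase peak at the changepoint.
* **shoulder_shift** — external contour of the shoulder slices displaced
  in-plane (default 2 cm), producing flagged fractions with no dose change
  to neck structures: the false-positive mode that dominated clinical
  flagging.
* **composite** — weight loss plus the edema trajectory. An independent
  `target_drift` (cm/fraction) can be added to any scenario to model
  progressive target displacement relative to bony anatomy.

Default cohort mix: 40% shoulder shift, 25% weight loss, 20% edema, 15%
unchanged, with per-patient magnitude jitter; CBCTs at fractions
1, 5, 10, 15, 20, 25, 30 (≈ every five), optionally plus fractions 2–3.

What the simulator does *not* emulate: CBCT image content and artifacts,
deformable-registration error, realistic multi-beam fluence, inter-fraction
setup noise beyond the scripted scenarios, and correlated flag/violation
structure matching any real cohort. Passing tests therefore establish that
the pipeline's mechanics and statistics are correct and that the engine
reproduces the qualitative clinical phenomena — not that any quantitative
clinical result generalises. Because physically simulated scenarios couple
flags to violations, the closed-form baseline (which assumes independence)
is exercised on a stochastic overlay cohort (`random_flag_cohort`) drawn at
the calibrated 20%/15% rates, not on the physical mix.

## Numerical choices and degenerate inputs

* Margin expansion is voxel-center to voxel-center Euclidean distance
  (exact EDT), with a 1e-9 cm epsilon so centers exactly at the margin are
  included. Cascaded center-based dilation undershoots the continuum
  Minkowski sum by about half a voxel per step; tests bound shapes by
  containment brackets and volume-equivalent radii rather than raw volumes.
* Hausdorff distances use the exact early-break algorithm; brute-force
  double loops serve as independent oracles in tests only.
* Empty masks, empty contours, zero assessed fractions, zero truth-table
  denominators and schema mismatches all raise with the offending structure,
  parameter or row named; nothing degrades silently to zero.
* All randomness is seeded (`numpy.random.default_rng`); cohort generation
  is byte-reproducible for a given seed.
* Problem sizes: the default phantom grid is 130 × 75 × 80 voxels at 0.2 cm;
  the baseline Monte Carlo uses 1e5 patients × 6 fractions; property tests
  use exhaustive oracles at up to 1000 voxels / 100 boundary points.

## Known limitations

* The default criteria file is a reconstruction; absolute objectives other
  than the cord anchor are representative, not survey-derived.
* The baseline's `k` is a modelling parameter; the printed 27% corresponds
  to `k = 6` and nearby `k` give 25–30%.
* Scalar-parameter accumulation cannot detect compensating spatial shifts
  (a hot spot moving between fractions averages as if stationary).
* The dose engine's penumbra and falloff are single-parameter abstractions;
  absolute DVH values of the phantom are not clinically meaningful, only
  their trends under the scenarios are.
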