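# Methods

`femcalc` quantifies calcification of the common femoral artery (CFA) and its
bifurcation on CT angiography and relates zone-wise calcification density to
twelve-month primary patency after stenting. Because clinical CTA series and
limb-level follow-up tables are not freely redistributable, the package ships
its own simulators — an imaging phantom with voxel-exact ground truth and a
limb-level cohort generator — and every pipeline stage is specified and tested
against them.

## Imaging model

A CT volume is an axis-aligned HU grid with positive voxel spacing in mm;
world coordinates put the centre of voxel (0,0,0) at the origin and the
voxel-to-world map is a pure scaling (oblique acquisitions are rejected at
I/O, not resampled). Vessel centerlines are arc-length-parameterised
polylines; the bifurcation carries two of them, CFA→DFA (deep femoral) and
CFA→SFA (superficial femoral), which share the trunk.

### Tubular ROI

The search region for calcium is the set of voxels whose centres lie within a
fixed radius (default 6 mm) of a centerline. Before distance queries the
polyline is resampled at arc steps of half the smallest voxel spacing, which
bounds the polyline-versus-sample-set distance error below half a voxel; the
membership rule is the inclusive `distance <= radius` on voxel centres, so
the ROI is deterministic and order-independent (reversing the polyline's
vertex list leaves the member set unchanged).

### Patient-adaptive detection threshold

The threshold adapts to scanner energy and contrast density through the HU
statistics of a narrow sample tube hugging the centerline (default radius
1.5 mm, deliberately sub-lumenal so wall and calcium do not contaminate it):

    threshold = mean(sample HU) + delta_k * SD(sample HU)

`delta_k` defaults to 2.0 — the conventional two-standard-deviation outlier
margin — and stays configurable; an operator override replaces the computed
value while the underlying statistics remain recorded. Calcification is every
ROI voxel with HU **at or above** the threshold (the boundary belongs to
calcium; stated explicitly because clinical HU grids are integer-valued).
Lumen is the ROI band `[150 HU, threshold)`; 150 HU is a standard
contrast-enhancement floor, needed for the calcification-to-lumen volume
ratio. An optional minimum connected-component volume (26-connectivity,
default off, 1 mm³ in the standard pipeline configuration) removes isolated
voxels that cross the threshold through image noise — the analogue of the
minimum-lesion-area rule in conventional CT calcium scoring. Raising the
threshold can only shrink the calcium mask, with or without the component
floor.

### Zones

Landmarks are arc lengths: P2 at the epigastric artery level, P4 at the
bifurcation, P3 midway between them, and P5/P6 two centimetres past the DFA
and SFA ostia **measured along the vessel**, not as Euclidean offsets. Zones
are half-open arc intervals — Zone 1 `[P2, P3)` and Zone 2 `[P3, P4)` on the
trunk, Zone 3 `[P4, P5)` on the DFA line united with `[P4, P6)` on the SFA
line — so the partition is disjoint and exhaustive and a voxel projecting to
exactly P3 belongs to Zone 2. Every ROI voxel is projected to its nearest
resampled centerline point over both lines; voxels equidistant to the two
lines go to the deep branch (the lexicographically lower id), a documented,
deterministic tie-break that prevents double counting in Zone 3. Projections
proximal to P2 or distal to P5/P6 stay unlabeled. Per zone we report calcium
volume (voxel count × voxel volume), the minimum/median/maximum HU **over
calcified voxels only** (reported densities near 1000 HU are only consistent
with this reading; a calcium-free zone contributes missing densities and zero
volume), lumen volume, and the calcification-to-lumen volume ratio in percent
(missing, with a warning, when the zone has no lumen voxels).

## Phantom

The phantom rasterises a contrast-filled trunk (radius 4 mm, 300 HU) that
splits at a configurable angle (default 30°) into straight daughters (2.5 and
3 mm radius), with a 60 HU wall shell over a 40 HU soft-tissue background.
Rasterisation is hard-edged by voxel-centre membership — the simplest rule an
independent oracle can reproduce exactly — with an optional Gaussian blur
(off by default). Deposits are spheres (world-placed or on the wall at a
given arc length and angle) or arc-shells hugging the wall; each carries a
zone label for bookkeeping, and ground truth records the exact voxel sets,
per-zone volumes and density summaries before noise. Noise is additive
Gaussian HU with SD 20 — a typical CTA noise floor that keeps dense deposits
several hundred HU clear of the lumen. Identical configuration and seed give
bit-identical volumes. What the phantom does **not** emulate: partial-volume
blur at deposit edges, beam hardening, streaks, patient-specific anatomy and
curved vessels; recovery results on it therefore show correctness of the
geometry and thresholding logic, not clinical segmentation accuracy.

## Cohort generator

Each limb-level metric is drawn from a log-normal family pinned to a target
median and inter-quartile range: `exp(mu) = median` and
`sigma = ln(q3/q1) / (2 z_0.75)`, so the population median and IQR equal the
targets exactly. Positive support and right skew match the spread of
clinical calcification tables. The default families are outcome-stratified
per zone, reproducing the twelve-month contrast in which the patent group's
distal-CFA (Zone 2) median density is 1122 HU (IQR 903–1248) against 858 HU
(788–987) under restenosis; restenosis prevalence defaults to 19/84 among
followed limbs, with small attrition (3 deaths, 3 losses per 90 limbs) and
covariate frequencies of a femoral-stenting population (64/90
balloon-expandable stents, Azema lesion grades 1/43/56%, Rutherford mix
with ~79% claudication). Within one limb and zone, the three density order
statistics share a single standard-normal draw (comonotone coupling) and the
triple is then sorted: marginal medians are preserved exactly — the quantile
curves cross only in the upper tail — while each row stays internally
consistent (min ≤ median ≤ max). Volume and ratio use independent draws.
PSVR values are generated consistently with the limb's outcome label (a small
fraction of restenoses present as clinically driven TLR with a normal PSVR).
The generator reproduces marginal distributions, not the joint correlation
structure of real plaque morphology; passing calibration tests therefore
validates the sampling machinery, not clinical realism.

`theoretical_youden_threshold` returns the generating separation point of a
metric: the HU value where the two groups' log-normal densities cross between
their medians, i.e. the population maximiser of Youden's J for a threshold
rule (≈ 1007.5 HU for the default Zone 2 median-density families).

## Outcome statistics

* **Patency.** Primary patency at twelve months is `PSVR <= 2.4` in the
  absence of clinically driven target lesion revascularisation. (Clinical
  definitions of this endpoint are written both as "2.4 or lower" and as
  "< 2.4"; the package uses the inclusive Methods-style rule, and ties at
  exactly 2.4 are classified patent.) A limb with no PSVR and no TLR is
  unevaluable and leaves the denominator; limbs dead or lost to follow-up are
  excluded from patency rates. Percentages are rounded to one decimal, the
  Azema distribution to integers.
* **Group comparison.** Continuous zone metrics use the Wilcoxon rank-sum
  test — exact null enumeration when the combined sample is ≤ 25 without
  ties, otherwise the tie-corrected normal approximation with continuity
  correction; categorical covariates use Fisher's exact test (2×2 with any
  expected count < 5) or chi-square. Benjamini–Hochberg q-values are step-up
  adjusted across all rows of one comparison table (one family per
  timepoint), monotone and capped at 1; the family is declared in the result
  metadata rather than inferred.
* **Logistic regression.** Maximum-likelihood fit with Wald 95% intervals;
  odds ratios are `exp(coefficient)`. Degenerate outcomes, constant
  predictors and (quasi-)complete separation raise errors naming the
  offender. The standard adjusted model for the dense-calcification indicator
  uses stent type and bifurcation involvement (Azema III vs I/II) as
  covariates — raw Azema dummies quasi-separate because type I has ~1%
  prevalence.
* **ROC / Youden.** The empirical ROC's trapezoidal area equals the pairwise
  concordance probability with ties counted ½ (computed via midranks); the
  DeLong variance gives the AUC interval. Candidate thresholds are midpoints
  between consecutive distinct scores; the Youden maximiser resolves ties to
  the lowest threshold. Orientation is chosen automatically so the reported
  AUC is ≥ 0.5 — for calcification density, **low** Zone 2 density predicts
  restenosis, so the positive-prediction rule is `score <= threshold`.
  Sensitivity/specificity/PPV/NPV come from the confusion table at the chosen
  threshold (equivalently Bayes' formula at the observed prevalence), with
  Wilson intervals on the implied counts.
* **Bootstrap validation.** Limbs (the analytical unit — one patient may
  contribute two) are resampled with replacement, simple resampling by
  default with an outcome-stratified option; the threshold is recomputed per
  replicate with the orientation frozen from the full sample, replicates that
  lose a class are redrawn and counted, the point estimate is the replicate
  median, and the interval is bias-corrected percentile (BC), with BCa
  available by flag. Fully seed-reproducible.
* **Agreement.** ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — from the ANOVA mean squares, with the F-based
  (Satterthwaite) 95% interval. Complete tables only; no imputation.

### Known limitation: bootstrap coverage for the Youden cut-point

The Youden threshold is a non-smooth argmax statistic: its bootstrap
distribution concentrates on a handful of midpoints of the observed sample,
and percentile-type intervals (BC and BCa alike) undercover. In a calibration
experiment at the default effect (n = 84 limbs, 200 outer replications,
B = 200 or 1000), the nominal-95% BC interval covers the generating
separation point in ≈ 83–84% of replications — materially below nominal, and
the corresponding acceptance test records this shortfall rather than hiding
it. Interval widths, not the point estimate, are the problem: the threshold
estimate itself centres near the generating value (median ≈ 982 HU vs
≈ 1007 HU, SD ≈ 64 HU). Users should read the bootstrap interval as a
stability diagnostic, not an exact-coverage confidence statement — consistent
with its role of confirming that the discovered cut-off is not an artefact of
a few limbs.

## Reproducibility and problem sizes

All randomness flows from a single seed; pipeline stages receive seeds
spawned deterministically from it, and a rerun with the same configuration
reproduces byte-identical CSV/JSON artifacts (NIfTI payloads are voxel-
identical). Default problem sizes keep the full test suite and the
acceptance script in the minutes range: phantoms of ~0.2–0.6 M voxels at
0.5 mm isotropic spacing, calibration cohorts of n = 5000, discovery cohorts
of n = 84 (the clinical follow-up denominator), 100-seed threshold-behaviour
sweeps, and 200×200 bootstrap calibration runs (scaled down from the
1000-replicate production default, which the pipeline uses).
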