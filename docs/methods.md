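# Methods

## The diagnostic model

Albinism disturbs the normal centrifugal organisation of the macular ganglion
cell layer (GCL): ganglion cells that should sit temporal to the fovea are
reduced, and thickness shifts toward the centre. On the ETDRS grid this makes
the temporal/nasal GCL thickness ratio a near-scale-free discriminator:

* quotient I = temporal I / nasal I (parafoveal ring, 0.5–1.5 mm radius),
* quotient II = temporal II / nasal II (perifoveal ring, 1.5–3 mm radius),

computed per patient on eye-averaged subfield thicknesses. The unit of
analysis is the patient (two eyes of one person are strongly dependent). The
decision rule is *albinism if quotient < cut-off* with strict inequality;
equality is called non-albinism (the published rule leaves equality
undefined, so the tie side is pinned and documented here).

The statistical pipeline mirrors the clinical analysis: four confirmatory
Mann-Whitney U comparisons (healthy vs albinism and non-albinism vs albinism,
for each quotient) at the Bonferroni local level 0.05/4 = 0.0125, two
exploratory comparisons (healthy vs non-albinism), ROC analysis of albinism
vs non-albinism FH with Youden-index cut-off selection, and classification at
the fixed reference cut-offs 0.7995 (quotient I) and 0.7169 (quotient II).

## Orientation of sensitivity and specificity

With the standard convention (positive class = albinism), sensitivity is the
albinism-correct rate and specificity the non-albinism-correct rate. The
reference cohort's printed rates ("specificity 84.6%, sensitivity 100.0%"
for quotient II) are only arithmetically realisable the other way around:
84.6% = 11/13 can only arise on the 13 albinism patients and 100.0% = 10/10
on the 10 non-albinism patients (for quotient I, 84.6% = 11/13 and
90.0% = 9/10 likewise). The package therefore reports the standard-convention
rates as `sensitivity`/`specificity` and repeats them under the swapped
naming in `published_wording`, so both readings are always visible.

## Synthetic cohort generator

No patient-level data are public, so the generator is calibrated to the
published group summaries and is the package's test bed. It emulates:

* three groups of 15 / 10 / 13 patients, bilateral scans except two
  unilateral non-albinism patients (74 eyes in total);
* per-layer (GCL, INL, ONL), per-subfield thickness means and SDs;
* latent per-patient quotient distributions matching the printed
  medians/IQRs and the fixed-cut-off classification behaviour;
* decorative clinical metadata (FH grade, nystagmus, fundus
  hypopigmentation) drawn from the cohort's empirical frequencies.

### Two-level thickness sampling

Each eye value is `patient level + eye jitter`: the patient level is normal
with variance `rho * sd^2`, the jitter has variance `(1 - rho) * sd^2`, so
eye-level variance equals the published SD and the inter-eye correlation is
`rho` (default 0.9; no between-eye correlation is published, the default is
declared, not inferred, and exposed in `CohortSpec`). Between-subfield
correlation beyond the shared patient level is not modelled.

### Exact quotient injection

Latent quotients q_I, q_II are drawn per patient from calibrated mixture
distributions; the GCL temporal subfields are then rescaled so that the
eye-averaged temporal value is exactly `q * eye-averaged nasal value` (per-eye
temporal jitter sums to zero across a patient's eyes). This decouples the
quotient-level behaviour from subfield noise: the quotient pipeline reads the
latent draws back exactly, and quotient-level tests do not depend on the
subfield noise model. A consequence is that the generated temporal subfield
SDs are driven by the quotient model rather than by the printed temporal SDs.

Both quotient kinds are driven by one shared uniform per patient (comonotone
coupling), so the atypical albinism patients are the same individuals on both
rings — consistent with the reference confusion counts (11/13 correct on
both quotients).

### Quotient distribution calibration

Only a median and IQR are printed per group, so the base family is the
minimal two-parameter choice: a normal matched by `mu = median`,
`sigma = IQR / (2 * Phi^-1(0.75))`. Groups that participate in the two-class
classification task additionally have to reproduce the printed per-group
rates at the fixed cut-off; their distributions are support-ordered mixtures
around the cut-off:

* **albinism** (both quotients): 11/13 of the mass in a normal truncated
  above at the cut-off, 2/13 "contamination" in a uniform band just above it;
* **non-albinism, quotient II**: a normal truncated below at 0.7169
  (10/10 printed — the truncation reproduces the printed rate exactly;
  whether albinism-range quotients are truly impossible in non-albinism FH
  or this is a finite-sample artifact cannot be decided from the summaries);
* **non-albinism, quotient I**: 1/10 near-miss mass in a uniform band of
  width 0.10 below 0.7995, the rest truncated above it;
* **healthy**: plain normal (not part of the classification task).

Truncated components are fitted by root-finding on the truncated quantile
function with the quantile levels re-weighted for the contamination mass; the
mixture median is matched exactly and the quartiles in least squares. A
two-parameter truncated normal cannot always reproduce three quantiles — for
the albinism groups the residuals at the quartiles are about 0.01–0.015,
reported on the model object (`fit_residuals`); the median, which is the
study endpoint, is exact.

The albinism contamination band widths are solved so that the mixture mean
equals the printed temporal/nasal ratio of subfield means (26.92/38.27 for
quotient II, 35.2/48.58 for quotient I). This single constraint makes the
generated albinism temporal thicknesses consistent with the printed subfield
means (mean of quotient x nasal equals the printed temporal mean under the
independence of quotient and nasal draws). For the non-albinism near-miss
band the analogous solve produces an implausibly wide band (reaching ~0.31,
far outside the printed IQR), so a fixed 0.10 width is used; the printed
medians and quotient-I confusion still hold, and the non-albinism temporal
mean drifts from the printed value by under 1 um. The same inherent
mean-vs-median tension exists for the healthy group (ratio of printed means
0.930 vs printed median 0.945); with no free contamination mass there, the
healthy temporal mean drifts by ~0.6 um. Only the albinism temporal means
are study-level recovery targets.

Printed GCL summaries exist only for the five horizontal subfields; the
superior/inferior GCL and all INL/ONL means/SDs are realistic values chosen
once for plausibility (healthy GCL ring values mirror the nasal/temporal
ones; INL ~30–40 um inner ring; ONL thickest centrally; FH groups get raised
central values reflecting the absent pit). They make the maps and tables
complete but carry no calibration weight.

### What the generator does not emulate

B-scan imagery, speckle, segmentation error, nystagmus motion artifacts,
foveal pit shape, refraction-dependent scan scaling, and any real
between-subfield covariance structure. Passing tests therefore demonstrate
that the *pipeline* recovers the distributions it is fed at the study's
sample sizes — not that real OCT data meet those distributional assumptions.

## ETDRS geometry

Canonical frame: fovea at the origin, +x temporal retina, +y superior,
regardless of eye; image coordinates are converted by flipping x for left
eyes (OS). Ring assignment by pixel-centre radius: r < 0.5 mm central,
r < 1.5 mm inner, r <= 3 mm outer; quadrants by the 45-degree diagonals with
diagonal ties going to the horizontal (nasal/temporal) wedges. Pixel
membership is a pure pixel-centre point test (no boundary area weighting);
pixel-counted areas converge to the analytic areas (0.7854 / 1.5708 / 5.3014
mm^2) as the pitch decreases. Subfield volume = mean thickness x area x 1e-3
(um -> mm). Maps are rendered/read at 0.02 mm pitch for the round-trip
checks, where the recovery error is far below the 0.5 um requirement.

Fovea localisation assumes a central depression: the boxcar-smoothed map
(odd kernel, ~0.1 mm) is searched within the central 2 mm and the centroid
of the minimal region returned; if the minimum touches the search-window
boundary (no pit, as in albinism maps where the central subfield is the
thickest) the metadata centre is used with a warning, and a flat map is an
error.

## Numerical and procedural choices

* **Quantiles**: linear interpolation between order statistics at positions
  (n-1)p + 1 (`numpy` default); pinned because group medians are endpoints.
* **Mann-Whitney U**: delegated to `scipy.stats.mannwhitneyu`; exact
  enumeration when n_a + n_b <= 25 without ties (two-sided by doubling the
  one-sided tail, capped at 1), otherwise the tie-corrected normal
  approximation without continuity correction; ties in exact mode fall back
  to asymptotic with a warning. All values identical across both samples is
  degenerate: U = n_a n_b / 2, p = 1.
* **Eye-averaging order**: thicknesses are averaged across eyes first, then
  the ratio is formed; the alternative (mean of per-eye ratios) is available
  via `order="quotient_first"` and the per-patient discrepancy between the
  two is always reported as `*_order_gap`.
* **ROC**: candidate thresholds are midpoints of consecutive distinct scores
  plus sentinels just outside the data range; AUC is trapezoidal (equal to
  1 - U/(n1 n2) on tie-free data); the CI is Hanley-McNeil with a normal
  quantile, clipped to [0, 1]; Youden ties break by higher sensitivity, then
  lower threshold. The AUC orientation ("lower quotient predicts albinism")
  is stored on the result and never silently flipped.
* **Seeding**: one master integer seed; per-group and per-replicate streams
  are derived via `numpy.random.SeedSequence` spawn keys, so adding a group
  or replicate does not perturb the others. Identical configuration and seed
  give byte-identical cohort CSVs.
* **Degenerate inputs**: non-positive nasal thickness is a hard error
  (rejected-row report), not a NaN; negative generated thicknesses trigger
  bounded per-patient resampling; empty groups yield empty tables.
* **Problem sizes**: Monte-Carlo summaries use 1000 replicate cohorts at the
  study sample sizes — enough to push the Monte-Carlo standard error of
  every tracked mean one to two orders of magnitude below its comparison
  tolerance, while keeping a full run (including 26 000 map renders at
  0.02 mm pitch) around a minute on one CPU.

## Known limitations

* The calibration reproduces printed *summaries*, not patient-level reality;
  any inference about real OCT cohorts still needs real data.
* The truncated-normal bulk cannot match all three printed quantiles at once
  for the albinism groups (quartile residuals ~0.01); alternative families
  (e.g. lognormal) would shift, not remove, this tension.
* Exact Mann-Whitney enumeration with ties is not implemented (tie-corrected
  asymptotics are used instead).
* DeLong covariance between the two correlated ROC curves, and tests
  comparing AUCs, are out of scope.
* Heidelberg/DICOM container parsing is out of scope; all I/O is plain text
  (CSV, TSV, JSON, YAML).
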