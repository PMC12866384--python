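# Methods

`pyp-dynaquant` emulates and analyzes a quantitative dynamic
[99mTc]Tc-pyrophosphate (99mTc-PYP) SPECT/CT protocol for transthyretin
amyloid cardiomyopathy (ATTR-CM). The package has two halves: a synthetic
4-D thorax-phantom cohort generator whose tissue kinetics are anchored to
published group-mean SUVs, and an analysis pipeline (calibration, VOI
statistics, SUV / %ID/mL quantitation, time-activity curves, synthetic
static windowing, blood-pool subtraction, diagnostic classification) that is
agnostic to where its images came from.

## Acquisition model

The emulated protocol is a 5-min cardiac-focused dynamic scan started at
injection, a repositioning gap, a 55-min dynamic acquisition over 10-65 min,
and 15-min static acquisitions at 90 and 150 min. Frame durations within the
dynamic segments are not constrained by the protocol description, so the
defaults are 20 x 15 s over 0-5 min and 11 x 5 min over 10-65 min; both are
configurable through `FrameSchedule`.

Reconstruction effects are emulated, not modeled: an optional isotropic
Gaussian blur (default FWHM 12 mm when enabled, 0 = off) stands in for the
system PSF, and Poisson resampling of expected counts per voxel per frame
stands in for count statistics. The sensitivity scale (default 2e-5 counts/s
per Bq/mL per voxel) yields ~5-10 million counts in a 15-min chest static at
clinical activities, a realistic order for a full-ring CZT system. There is
no projection-domain physics: no attenuation, scatter, or motion. Voxel grid
defaults to 64^3 at 4.92 mm (the clinical reconstruction voxel size); 48^3
is the minimum that fits the phantom and is used widely in the tests for
speed.

## Phantom geometry

Analytic compartments voxelized at voxel centers: an elliptical-cylinder
body; a left-ventricular myocardial shell between concentric ellipsoids
(outer semi-axes 45/45/60 mm, inner 33/33/48 mm, ~290 mL shell — thick
walls, as in infiltrative hypertrophy, and robust to the 4.92-mm grid); the
inner ellipsoid as LV blood pool; a 16-mm-radius spherical left-atrial blood
pool clear of the shell and the spine; and a 12-mm-radius, 90-mm-long
cylinder for the cancellous core of the lower thoracic spine (LS). All
compartments are pairwise disjoint by construction and enclosed in the body.
Region volumes agree with the closed-form shape volumes to within
discretization error at any grid that fits them.

## Tissue kinetics

Each tissue's time-activity model is a list of (time, SUV) anchors
interpolated with a monotone shape-preserving cubic (PCHIP) and held
constant beyond the first/last anchor. Printed group values sit at the
midpoints of the acquisition windows they were measured in (17.5 min for the
10-25 min synthetic static, 97.5 and 157.5 min for the statics). Because a
15-min window average of a convex bolus descent exceeds its midpoint value,
curves with a pre-window bolus carry a "shaping" anchor at 12.5 min solved
(once, offline) so that the duration-weighted 10-25 min window average
equals the printed 10-min value; the printed anchors themselves are never
moved.

First-pass shapes are not printed and are chosen to satisfy the study's
qualitative findings simultaneously: ATTR myocardium rises to its
%ID/mL-derived peak at 2.5 min (SUV 5.5 = 0.007% x 79.1 kg x 10) and washes
out slowly; non-ATTR myocardium shows a blood-driven bolus of SUV 2.0 at
1 min (0.00225 %ID/mL, the reported "about 0.002% at 1 min") and is
otherwise flat; blood pools peak at 1 min (ATTR 10.0 — first-pass blood runs
far above tissue — non-ATTR 5.0) and clear monotonically; bone rises to its
90-min peak in both groups, higher in non-ATTR (4.40) than ATTR (2.6, kept
below myocardium). Soft tissue is flat at SUV 0.4. The ATTR bone curve is
entirely qualitative: the study prints no ATTR bone SUVs. The non-ATTR
150-min blood-pool value is also a chosen default (1.40): the source prints
the same number for 30 and 150 min, which is internally inconsistent with
the described continued decline.

## Inter-subject variability

Each subject scales each tissue curve by one multiplicative log-normal
factor with unit mean and CV matched to the printed group SDs (e.g. ATTR
myocardium 0.77/3.86 ~ 0.20). The per-tissue log-scales share a common
subject-level component (correlation rho = 0.8): the study observed the
myocardium >= blood-pool ordering in every ATTR subject despite overlapping
group SDs, which requires strongly correlated within-subject scales.
Subjects whose scaled curves violate their group's orderings (ATTR
myocardium >= blood pool from 10 min on; non-ATTR blood pool strictly above
myocardium at every frame) are redrawn — the same truncation mechanism used
for weight sampling. Measured redraw rates are ~4% (ATTR) and ~6%
(non-ATTR); the residual conditional bias on group-mean recovery is about
+1% and -4% respectively, well inside the sampling scatter of an 8- or
11-subject cohort mean (7-10% SD).

Weights are normal with the printed group means/SDs (79.1 +/- 17.2 kg ATTR,
89.0 +/- 15.8 kg non-ATTR), truncated at +/-3 SD. The syringe assay is
898.6 +/- 84.8 MBq at -30 min with a 10 +/- 3 MBq residual at +5 min, so the
net decay-referenced injected activity averages the printed 887.9 MBq.

## Voxel filling and units

Voxel values are physical activity concentration at the frame midpoint:

    C(t) = SUV_tissue(t) x m_subject,tissue x ID / (1000 x W) x 2^(-(t - t_assay)/T_half)

with ID the net injected activity (Bq) referenced to the assay time, W body
weight (kg), and T_half = 360.4 min (99mTc). The last factor applies
physical decay, which the analysis pipeline must undo; with blur, noise, and
variability disabled the full pipeline therefore recovers the anchor curves
exactly (the round-trip is tested to 0.1%).

## Analysis pipeline

* **Calibration** — a uniform cylinder of known activity/volume is imaged
  under the same acquisition model; cf = nominal concentration / mean count
  rate over the mask eroded by 2 voxel-widths (edge voxels excluded against
  spill-out). The cylinder VOI rule is a declared default; the study's
  supplement does not print one.
* **Decay correction** — every frame is referenced to the pre-injection
  assay time, the same reference used for the net dose; injection time is
  used only for frame timing. Whether the original analysis referenced assay
  or injection time is not stated; assay-time referencing is the declared
  convention throughout.
* **Synthetic statics** — duration-weighted voxelwise means over closed-open
  windows [10,25), [30,45), [45,60) minutes, named by their start; partial
  frame overlaps are weighted by overlap duration so the result is
  framing-invariant for noiseless piecewise-constant signals.
* **Segmentation** — myocardium is contoured on the 150-min static as the
  largest 26-connected component of search-region voxels above k x the
  left-atrial blood-pool mean (k = 1.0 by default, exposed and recorded in
  provenance; the original threshold is unpublished). The anatomical shell
  label plays the role of the CT-guided search region. A minimum component
  size (30 voxels in the pipeline) rejects noise-only "segmentations" in
  subjects without myocardial uptake, which then fall back to the anatomical
  contour, recorded as such. VOIs transfer to other images of the same
  subject by identity (no re-contouring), mirroring the original "minimal
  adjustment" limitation.
* **Quantitation** — SUV = C x 1000 W / ID (g/mL, 1 g/mL tissue density
  implied); %ID/mL = 100 x SUVmean / (1000 W), reported in percent
  (0.005 means 0.005%); ratios LV_myo/LS and LV_myo/LA_bp from SUVmeans.
* **Blood-pool subtraction** — template B = duration-weighted mean of the
  0-5 min frames; scale s matches the LA blood-pool means of target and
  template (the supplement's exact rule is unpublished; s can be overridden);
  output is max(target - sB, 0).
* **Classification** — blood-pool grade: positive iff myocardial SUVmean >=
  blood-pool SUVmean (ties positive, taking "equal to or greater" at face
  value); %ID/mL rule: positive iff %ID/mL >= 0.003% (the boundary itself is
  classified positive and the convention recorded; the source states only
  strict inequalities on either side). Ground truth for synthetic cohorts is
  the generator's group label, standing in for the 2.5-h clinical read.
* **Statistics** — Welch t from group summaries with Welch-Satterthwaite
  degrees of freedom; Cohen's kappa with marginal-product chance agreement,
  returning 1.0 for unanimous perfect agreement (otherwise 0/0); group
  summaries report mean, SD, and t-based 95% CIs (n <= 11 per group), with
  CIs flagged undefined for single-subject groups.

## Determinism and numerics

Every stochastic step draws from a `numpy` Generator seeded through
`SeedSequence` spawning: one stream per subject, one for calibration.
Identical (config, seed) produce bit-identical images and byte-identical
CSV outputs (tables are written with fixed float formatting, and the config
hash — which excludes the output path — is embedded in each file).
Truncated-normal draws resample within +/-3 SD; ordering redraws are capped
at 1000 attempts before raising.

## What passing tests do and do not show

The generator reproduces the published group kinetics, orderings, noise
magnitudes, and cohort structure, so passing tests demonstrate that the
quantitation and classification machinery is correct and that the published
group separation is recoverable under those conditions. They do not
demonstrate robustness to the things the phantom omits: anatomical
variability, cardiac/respiratory motion, attenuation and scatter artifacts,
partial-volume bias at realistic wall thickness (the default shell is
thick), or reader behavior. Group-mean checks on an 8- or 11-subject cohort
inherit the sampling scatter the study itself had (one SEM ~ 7-10% of the
mean), so stochastic-run comparisons use 1.5-SEM bands and a fixed seed.

## Problem sizes

Default runs use the 64^3 grid, full 34-frame schedule, and printed group
sizes (8 + 11); a full cohort simulation plus analysis takes tens of
seconds on one core. Unit and property tests use the 48^3 grid and small
cohorts.
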